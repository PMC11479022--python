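"""Per-trait Shannon-Wiener diversity of a simulated germplasm collection.

Draws a 288-accession collection at the default (survey-like) conditions and
prints each trait's H' plus the profile summary.  H' is the entropy of the
trait's class frequencies in nats: 0 means every accession shares one class,
ln(k) means an even spread over k classes.
"""

import germeval as g

scheme = g.default_scheme()
table = g.sample_accessions(g.SyntheticConfig(n_accessions=288, seed=1))

results, summary = g.diversity_profile(table, scheme)
for r in results:
    print(f"{r.trait:35s} H' = {r.h_prime:.2f}")
print(f"\nprofile: min {summary['min']:.2f}  max {summary['max']:.2f}  "
      f"mean {summary['mean']:.2f}")
print("traits near 0 are fixed in the collection; the quantitative traits "
      "(10 sigma-bin levels) usually score highest")
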