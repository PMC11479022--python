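"""Variety rules and the two-stage excellent-accession + conservation set.

Stage 1 takes the overall top-14 accessions by composite F.  Because the
stature-based variety rule ('Malabar' below 3 m, 'Mysore'/'Vazhukka' above)
usually leaves the tall type under-represented, stage 2 reruns the whole
evaluation on the tall subset only and adds the 12 best new accessions.
The union of 26 accessions is the conservation proposal; its average trait
diversity is compared with stage 1 alone.
"""

import germeval as g

scheme = g.default_scheme()
table = g.sample_accessions(g.SyntheticConfig(n_accessions=288, seed=1))

labels = g.variety_labels(table)
print(labels["by_height"].value_counts().to_string())
print(f"height/capsule rule agreement: "
      f"{100 * labels.attrs['agreement_rate']:.1f}%\n")

matrix = g.encode_indicators(table, scheme)
model = g.fit_pca(matrix)
scores = g.component_scores(model, matrix)
partition = g.cut_k(g.linkage_average(scores, [0, 1, 2]), 6)

report = g.two_stage_selection(table, scheme, k1=14, k2=12,
                               partition=partition)
print(f"stage 1 (all accessions):   {len(report.stage1_ids)} selected, "
      f"avg H' {report.avg_h_stage1:.2f}")
print(f"stage 2 (tall subset only): {len(report.stage2_ids)} added")
if report.stage2_overlap:
    print(f"  skipped (already selected in stage 1): "
          f"{', '.join(report.stage2_overlap)}")
print(f"union of {len(report.union_ids)}: avg H' {report.avg_h_union:.2f} "
      "(higher = the conservation set carries more trait diversity)")

ok, counts, short = g.coverage_check(report, partition, min_per_group=2)
print(f"per-group counts {counts}; every group represented >= 2x: {ok}")
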