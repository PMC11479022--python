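"""Reference marginal distributions for cultivated cardamom germplasm.

These are the class frequencies observed in a field characterization of 288
cardamom (*Elettaria cardamomum*) accessions from the Northern Transversal
Strip of Guatemala, scored on the 17 IPGRI morphological descriptors of the
default trait scheme.  They serve two purposes:

* default marginal class probabilities for the synthetic accession generator
  (:mod:`germeval.synthetic`), so simulated collections have realistic trait
  frequency structure; and
* worked inputs for the diversity index — entropy of a printed class-count
  vector is a pure function of the counts, so these vectors are sufficient to
  reproduce survey-level Shannon–Wiener indices without the raw per-accession
  data (which was never published).

Counts are per morphological class, in scheme class order; the two
quantitative traits are summarized by mean/SD/min/max and by their observed
counts over the ten sigma-bin levels used for diversity scoring.
"""

from __future__ import annotations

REFERENCE_N: int = 288

#: Observed class counts for the 15 categorical traits (scheme class order).
REFERENCE_CLASS_COUNTS: dict[str, tuple[int, ...]] = {
    "Height of the plant": (2, 167, 119),
    "Number of stems per plant": (45, 106, 83, 54),
    "Stem color": (280, 7, 1),
    "Rhizome color": (32, 168, 86, 1, 1),
    "Shape of the leaf": (11, 272, 5),
    "Pubescence of the leaf": (141, 81, 66),
    "Panicle type": (2, 283, 3),
    "Number of panicles per stem": (17, 257, 14),
    "Number of panicles per plant": (20, 56, 86, 126),
    "Panicle length": (34, 112, 95, 47),
    "Number of clusters per panicle": (90, 181, 17),
    "Panicle branching": (12, 276),
    "Panicle branching pattern": (12, 276),
    "Capsule form": (13, 73, 202),
    "Capsule color": (11, 76, 13, 188),
}

#: Observed counts of the two quantitative traits over the ten sigma-bin
#: levels (level 1 = below mean - 2*SD ... level 10 = at or above mean + 2*SD).
REFERENCE_LEVEL_COUNTS: dict[str, tuple[int, ...]] = {
    "Cluster internodal length": (0, 0, 25, 75, 54, 88, 28, 12, 0, 6),
    "Number of capsules per cluster": (3, 12, 42, 32, 66, 62, 20, 33, 10, 8),
}

#: Summary statistics of the two quantitative traits in the reference survey.
REFERENCE_QUANT_SUMMARY: dict[str, dict[str, float]] = {
    "Cluster internodal length": {"mean": 2.79, "sd": 1.55, "min": 0.5, "max": 18.0},
    "Number of capsules per cluster": {"mean": 10.75, "sd": 3.74, "min": 3.0, "max": 25.0},
}
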