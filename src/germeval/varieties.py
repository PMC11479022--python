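"""Putative-variety classification and the two-stage conservation selection.

Cardamom germplasm is conventionally split into the 'Malabar' type (plants
below 3 m) and the taller 'Mysore'/'Vazhukka' type; capsule color gives an
alternative split (light green / yellow vs green / dark green).  Because a
composite-value ranking over the whole collection tends to favor one stature
type, conservation selection proceeds in two stages: the overall top-k1
accessions, then a fresh evaluation restricted to the tall ('Mysore'/
'Vazhukka') subset to add k2 more, skipping accessions already selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .composite import f_value, membership_rescale, rank_and_select
from .diversity import subset_average_diversity
from .errors import GermevalError
from .pca import component_scores, fit_pca, select_components
from .schema import AccessionTable, TraitScheme, encode_indicators

MALABAR = "Malabar"
MYSORE_VAZHUKKA = "MysoreVazhukka"
UNCLASSIFIED = "Unclassified"

_HEIGHT_TRAIT = "Height of the plant"
_CAPSULE_TRAIT = "Capsule color"
_MALABAR_HEIGHTS = {"<2 m", "2-3 m"}
_MALABAR_CAPSULES = {"Light green", "Yellow"}
_MV_CAPSULES = {"Green", "Dark green"}


def classify_by_height(table: AccessionTable) -> pd.Series:
    """'Malabar' for plants below 3 m, 'MysoreVazhukka' above."""
    col = table.data[_HEIGHT_TRAIT]
    return col.map(lambda c: MALABAR if c in _MALABAR_HEIGHTS
                   else MYSORE_VAZHUKKA).rename("by_height")


def classify_by_capsule(table: AccessionTable) -> pd.Series:
    """'Malabar' for light green/yellow capsules, 'MysoreVazhukka' for
    green/dark green; anything else is left unclassified."""
    def rule(c: str) -> str:
        if c in _MALABAR_CAPSULES:
            return MALABAR
        if c in _MV_CAPSULES:
            return MYSORE_VAZHUKKA
        return UNCLASSIFIED
    return table.data[_CAPSULE_TRAIT].map(rule).rename("by_capsule")


def variety_labels(table: AccessionTable) -> pd.DataFrame:
    """Both classifications side by side, plus their agreement rate."""
    frame = pd.concat([classify_by_height(table),
                       classify_by_capsule(table)], axis=1)
    frame.attrs["agreement_rate"] = float(
        (frame["by_height"] == frame["by_capsule"]).mean())
    return frame


@dataclass(frozen=True)
class ConservationReport:
    """Outcome of the two-stage selection."""

    stage1_ids: tuple[str, ...]
    stage2_ids: tuple[str, ...]          # new accessions only, disjoint
    stage1_f: pd.DataFrame
    stage2_f: pd.DataFrame
    avg_h_stage1: float
    avg_h_union: float
    group_counts: dict[int, int] = field(default_factory=dict)
    stage2_overlap: tuple[str, ...] = ()  # stage-2 top ranks already in stage 1

    @property
    def union_ids(self) -> tuple[str, ...]:
        return self.stage1_ids + self.stage2_ids


def _composite_ranking(table: AccessionTable, scheme: TraitScheme,
                       n_components: int) -> pd.DataFrame:
    """Full fresh pipeline: encode -> PCA -> membership -> F ranking."""
    matrix = encode_indicators(table, scheme)
    model = fit_pca(matrix)
    comps = select_components(model, "top_k",
                              k=min(n_components, model.n_components))
    scores = component_scores(model, matrix)
    u = membership_rescale(scores, comps)
    return f_value(u, model, comps)


def two_stage_selection(table: AccessionTable, scheme: TraitScheme,
                        k1: int = 14, k2: int = 12,
                        partition: dict[str, int] | None = None,
                        n_components: int = 3) -> ConservationReport:
    """Overall top-k1 plus top-k2 new tall-type accessions.

    Stage 1 ranks the whole collection by composite F.  Stage 2 re-runs the
    entire analysis (fresh sigma-binning, PCA, membership) on the
    height-defined 'Mysore'/'Vazhukka' subset and takes the k2 best ids not
    already selected, so the union has exactly k1 + k2 members.
    """
    n = table.n
    if k1 + k2 > n:
        raise GermevalError(f"k1 + k2 = {k1 + k2} exceeds collection size {n}")

    f1 = _composite_ranking(table, scheme, n_components)
    stage1 = tuple(rank_and_select(f1, k1))

    tall_ids = [i for i, v in classify_by_height(table).items()
                if v == MYSORE_VAZHUKKA]
    if not tall_ids:
        raise GermevalError(
            "stage 2 impossible: no 'Mysore'/'Vazhukka' accessions by height")
    overlap_budget = len([i for i in stage1 if i in tall_ids])
    if len(tall_ids) < k2 + overlap_budget:
        raise GermevalError(
            f"stage 2 needs {k2} new tall-type accessions but only "
            f"{len(tall_ids) - overlap_budget} are available")

    sub = table.subset(tall_ids)
    f2 = _composite_ranking(sub, scheme, n_components)
    ranked2 = rank_and_select(f2, len(tall_ids))
    stage2, skipped = [], []
    for aid in ranked2:
        if len(stage2) == k2:
            break
        if aid in stage1:
            skipped.append(aid)
        else:
            stage2.append(aid)

    union = stage1 + tuple(stage2)
    avg1 = subset_average_diversity(table, scheme, stage1)
    avg_union = subset_average_diversity(table, scheme, union)
    counts: dict[int, int] = {}
    if partition is not None:
        for aid in union:
            g = partition[aid]
            counts[g] = counts.get(g, 0) + 1
        counts = dict(sorted(counts.items()))
    return ConservationReport(
        stage1_ids=stage1, stage2_ids=tuple(stage2),
        stage1_f=f1, stage2_f=f2,
        avg_h_stage1=avg1, avg_h_union=avg_union,
        group_counts=counts, stage2_overlap=tuple(skipped),
    )


def coverage_check(report: ConservationReport, partition: dict[str, int],
                   min_per_group: int = 2) -> tuple[bool, dict[int, int], list[int]]:
    """Does every cluster group have >= min_per_group members in the union?

    Returns (ok, per-group counts over all groups, groups falling short).
    """
    counts = {g: 0 for g in sorted(set(partition.values()))}
    for aid in report.union_ids:
        counts[partition[aid]] += 1
    short = [g for g, c in counts.items() if c < min_per_group]
    return (not short, counts, short)


def conservation_table(report: ConservationReport,
                       labels: pd.Series | None = None,
                       partition: dict[str, int] | None = None
                       ) -> pd.DataFrame:
    """Flat per-accession view of the conservation set (CSV-ready)."""
    rows = []
    for stage, ids, f in (("stage1", report.stage1_ids, report.stage1_f),
                          ("stage2", report.stage2_ids, report.stage2_f)):
        for aid in ids:
            rows.append({
                "accession": aid,
                "stage": stage,
                "cultivar_by_height": labels[aid] if labels is not None else "",
                "F": round(float(f.at[aid, "F"]), 4),
                "rank_in_stage": int(f.at[aid, "rank"]),
                "cluster_group": partition[aid] if partition else "",
            })
    return pd.DataFrame(rows)
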