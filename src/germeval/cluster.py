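"""Hierarchical germplasm grouping on principal-component scores.

Accessions are clustered by unweighted average linkage (UPGMA, the
"between-groups" method) on plain Euclidean distances over the selected
score columns.  Rows are canonicalized by ascending accession id before
linkage, so the dendrogram and every cut are exactly invariant to the input
row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .diversity import shannon_index
from .errors import GermevalError
from .schema import (AccessionTable, TraitScheme, assign_level, level_labels,
                     make_binning)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus the (sorted) leaf ids."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def linkage_average(scores: pd.DataFrame,
                    components: list[int] | None = None) -> Dendrogram:
    """Average-linkage dendrogram on Euclidean distances of score columns."""
    if scores.shape[0] < 2:
        raise GermevalError("clustering needs at least 2 accessions")
    cols = scores.columns if components is None else scores.columns[components]
    ordered = scores[cols].sort_index(key=lambda ix: ix.astype(str))
    dist = pdist(ordered.to_numpy(dtype=float), metric="euclidean")
    Z = linkage(dist, method="average")
    return Dendrogram(merges=Z, leaf_ids=tuple(str(i) for i in ordered.index))


def cut_k(d: Dendrogram, k: int) -> dict[str, int]:
    """Cut into exactly k groups, labeled 1..k by first leaf appearance."""
    n = d.n_leaves
    if not 1 <= k <= n:
        raise GermevalError(f"k must be in [1, {n}], got {k}")
    raw = fcluster(d.merges, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise GermevalError(f"could not produce exactly {k} groups")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    return {aid: relabel[lab] for aid, lab in zip(d.leaf_ids, raw)}


def group_sizes(partition: dict[str, int]) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for g in partition.values():
        sizes[g] = sizes.get(g, 0) + 1
    return dict(sorted(sizes.items()))


def partition_diversity(partition: dict[str, int]) -> float:
    """Shannon-Wiener index of the group-size distribution."""
    return shannon_index(list(group_sizes(partition).values()))


def group_profile(partition: dict[str, int], table: AccessionTable,
                  scheme: TraitScheme, dominance: float = 80.0
                  ) -> pd.DataFrame:
    """Within-group class percentages with dominance flags.

    One row per (group, trait, class); ``percent`` is the share of the
    group's members carrying that class and ``dominant`` flags shares at or
    above the threshold (default 80%).  Quantitative traits are profiled over
    their ten sigma-bin levels (bins fit on the full table).
    """
    missing = [i for i in table.ids if i not in partition]
    if missing:
        raise GermevalError(f"partition does not cover accessions: {missing}")
    bins = {}
    for t in scheme.quantitative:
        vals = table.data[t.name].to_numpy(dtype=float)
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            bins[t.name] = make_binning(vals)
    labels = pd.Series({i: partition[i] for i in table.ids})
    rows = []
    for g in sorted(set(labels)):
        members = labels.index[labels == g]
        sub = table.data.loc[members]
        for trait in scheme:
            if trait.is_quantitative:
                classes = level_labels()
                vals = sub[trait.name].to_numpy(dtype=float)
                if trait.name in bins:
                    levels = np.atleast_1d(
                        assign_level(vals, bins[trait.name]))
                else:
                    # constant trait across the table: single central level
                    levels = np.full(len(vals), 6)
                values = pd.Series([f"L{v}" for v in levels])
            else:
                classes = list(trait.classes)
                values = sub[trait.name]
            for cls in classes:
                pct = 100.0 * float((values == cls).sum()) / len(members)
                rows.append({
                    "group": g, "n": len(members), "trait": trait.name,
                    "class": cls, "percent": pct,
                    "dominant": pct >= dominance,
                })
    return pd.DataFrame(rows)


def to_newick(d: Dendrogram) -> str:
    """Newick string with merge heights as node depths (branch lengths)."""
    n = d.n_leaves
    heights = {i: 0.0 for i in range(n)}
    trees = {i: d.leaf_ids[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(d.merges):
        a, b = int(a), int(b)
        node = n + step
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        trees[node] = f"({trees[a]}:{la:.6g},{trees[b]}:{lb:.6g})"
        heights[node] = h
    return trees[n + len(d.merges) - 1] + ";"
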