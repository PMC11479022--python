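"""Shannon-Wiener diversity of trait class distributions.

The index is the entropy ``H' = -sum_i P_i ln P_i`` (natural log, nats) of a
trait's class frequency distribution over accessions; quantitative traits are
first stratified into their ten sigma-bin levels.  Higher H' means class
membership is spread more evenly across more classes; a trait fixed in one
class has H' = 0 and a trait uniform over k classes attains the maximum ln k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GermevalError
from .schema import (AccessionTable, BinningScheme, TraitScheme, assign_level,
                     fit_binnings, level_labels, make_binning)


@dataclass(frozen=True)
class DiversityResult:
    """Per-trait class counts, frequencies and Shannon-Wiener index."""

    trait: str
    classes: tuple[str, ...]
    counts: tuple[int, ...]
    h_prime: float

    @property
    def frequencies(self) -> tuple[float, ...]:
        total = sum(self.counts)
        return tuple(c / total for c in self.counts)


def shannon_index(counts: Sequence[float]) -> float:
    """Shannon-Wiener index of a class-count vector, in nats.

    Zero-count classes contribute nothing (the usual ``0 ln 0 := 0``
    convention).  Raises on an all-zero or negative vector.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or (arr < 0).any():
        raise GermevalError("counts must be a non-empty non-negative vector")
    total = float(arr.sum())
    if total <= 0:
        raise GermevalError("cannot compute diversity of an empty distribution")
    terms = [(-(c / total) * math.log(c / total)) for c in arr if c > 0]
    return float(math.fsum(terms))


def _trait_counts(table: AccessionTable, scheme: TraitScheme,
                  bins: Mapping[str, BinningScheme]) -> list[DiversityResult]:
    results = []
    for trait in scheme:
        if trait.is_quantitative:
            classes = tuple(level_labels())
            values = table.data[trait.name].to_numpy(dtype=float)
            if trait.name in bins:
                levels = np.asarray(assign_level(values, bins[trait.name]))
            else:
                # Degenerate subset (constant trait): everything in one level.
                levels = np.full(len(values), 6)
            counts = tuple(int((levels == k).sum()) for k in range(1, 11))
        else:
            classes = trait.classes
            col = table.data[trait.name]
            counts = tuple(int((col == c).sum()) for c in classes)
        results.append(DiversityResult(trait.name, classes, counts,
                                       shannon_index(counts)))
    return results


def _safe_binnings(table: AccessionTable, scheme: TraitScheme
                   ) -> dict[str, BinningScheme]:
    bins: dict[str, BinningScheme] = {}
    for t in scheme.quantitative:
        values = table.data[t.name].to_numpy(dtype=float)
        if len(values) >= 2 and np.std(values, ddof=1) > 0:
            bins[t.name] = make_binning(values)
    return bins


def diversity_profile(table: AccessionTable, scheme: TraitScheme,
                      bins: Mapping[str, BinningScheme] | None = None
                      ) -> tuple[list[DiversityResult], dict[str, float]]:
    """Per-trait diversity plus a (min, max, mean) summary over traits.

    ``bins`` defaults to sigma-binnings fit on the table itself; a constant
    quantitative trait collapses to a single level (H' = 0) rather than
    erroring.
    """
    if table.n < 1:
        raise GermevalError("need at least one accession")
    if bins is None:
        bins = _safe_binnings(table, scheme)
    results = _trait_counts(table, scheme, bins)
    h = np.array([r.h_prime for r in results])
    summary = {"min": float(h.min()), "max": float(h.max()),
               "mean": float(h.mean())}
    return results, summary


def subset_average_diversity(table: AccessionTable, scheme: TraitScheme,
                             subset: Iterable[str]) -> float:
    """Mean over traits of H' computed on the subset only.

    Quantitative bins are refit on the subset, mirroring a from-scratch
    analysis of the selected accessions.
    """
    ids = list(subset)
    if not ids:
        raise GermevalError("subset must be non-empty")
    sub = table.subset(ids)
    results, summary = diversity_profile(sub, scheme)
    return summary["mean"]


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    minimum: float
    maximum: float
    sd: float
    cv_percent: float


def descriptive_stats(values: Sequence[float]) -> DescriptiveStats:
    """Mean / min / max / sample SD / CV% of a quantitative trait.

    ``cv_percent = 100 * sd / mean`` (the standard definition); SD uses the
    n-1 denominator.  A zero mean with nonzero spread leaves CV undefined.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise GermevalError("need >= 2 values for descriptive statistics")
    sd = float(np.std(arr, ddof=1))
    mean = float(np.mean(arr))
    if sd == 0.0:
        cv = 0.0
    elif mean == 0.0:
        raise GermevalError("CV undefined: mean is zero")
    else:
        cv = 100.0 * sd / mean
    return DescriptiveStats(mean=mean, minimum=float(arr.min()),
                            maximum=float(arr.max()), sd=sd, cv_percent=cv)


def diversity_report(table: AccessionTable, scheme: TraitScheme) -> pd.DataFrame:
    """Survey-style diversity report: one row per trait.

    Columns: class counts (semicolon-joined), H', and for quantitative traits
    the mean/min/max/SD/CV of the raw values.
    """
    results, _ = diversity_profile(table, scheme)
    rows = []
    for r in results:
        row: dict[str, object] = {
            "trait": r.trait,
            "counts": ";".join(str(c) for c in r.counts),
            "h_prime": round(r.h_prime, 4),
            "mean": "", "min": "", "max": "", "sd": "", "cv_percent": "",
        }
        trait = scheme[r.trait]
        if trait.is_quantitative:
            st = descriptive_stats(table.data[r.trait].to_numpy(dtype=float))
            row.update(mean=round(st.mean, 3), min=st.minimum, max=st.maximum,
                       sd=round(st.sd, 3), cv_percent=round(st.cv_percent, 2))
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
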