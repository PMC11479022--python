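"""Membership-function composite evaluation (F-value) and ranking.

Each selected principal-component score column is rescaled to [0, 1] by the
min-max membership function ``u = (S - min S) / (max S - min S)``, and the
composite value of an accession is the weighted sum ``F = sum_j w_j u_j``
with weights proportional to the selected components' contribution rates.
F always lies in [0, 1]; higher F = more favorable composite morphology.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import GermevalError
from .pca import PCAModel


def membership_rescale(scores: pd.DataFrame,
                       components: list[int]) -> pd.DataFrame:
    """Min-max membership values per selected component.

    A degenerate component (all scores equal) maps to 0.5 everywhere, with a
    warning.
    """
    if scores.shape[0] < 2:
        raise GermevalError("membership rescaling needs >= 2 accessions")
    cols = scores.columns[components]
    sub = scores[cols].to_numpy(dtype=float)
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    span = hi - lo
    u = np.empty_like(sub)
    for j in range(sub.shape[1]):
        if span[j] == 0:
            warnings.warn(
                f"component {cols[j]} is degenerate (max == min); "
                "membership set to 0.5", stacklevel=2)
            u[:, j] = 0.5
        else:
            u[:, j] = (sub[:, j] - lo[j]) / span[j]
    return pd.DataFrame(u, index=scores.index, columns=cols)


def f_value(u: pd.DataFrame, model: PCAModel, components: list[int],
            normalize_over: str = "selected") -> pd.DataFrame:
    """Weighted composite F per accession, with a deterministic ranking.

    Weights are the selected components' contribution rates normalized over
    the selection (default) or over all components (``normalize_over="all"``,
    in which case F no longer spans the full [0, 1]).  Returns a DataFrame
    with columns ``F`` and ``rank`` (1 = best; ties broken by ascending
    accession id so the ranking is a permutation).
    """
    if not components:
        raise GermevalError("empty component set")
    contrib = model.contribution_rate[components]
    if normalize_over == "selected":
        weights = contrib / contrib.sum()
    elif normalize_over == "all":
        weights = contrib / 100.0
    else:
        raise GermevalError(f"unknown normalize_over {normalize_over!r}")
    f = u.to_numpy(dtype=float) @ weights
    out = pd.DataFrame({"F": f}, index=u.index)
    order = sorted(out.index, key=lambda i: (-out.at[i, "F"], str(i)))
    out["rank"] = pd.Series({aid: r + 1 for r, aid in enumerate(order)})
    return out


def rank_and_select(f: pd.DataFrame, k: int) -> list[str]:
    """Top-k accession ids by descending F (ascending-id tie-break)."""
    n = len(f)
    if not 1 <= k <= n:
        raise GermevalError(f"k must be in [1, {n}], got {k}")
    order = sorted(f.index, key=lambda i: (-f.at[i, "F"], str(i)))
    return [str(i) for i in order[:k]]
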