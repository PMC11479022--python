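"""Stepwise OLS regression of composite F-values on trait indicators.

The search alternates forward entry and backward removal driven by partial-F
tests, mirroring the classic stepwise procedure: at each forward step the
candidate with the smallest partial-F p-value enters if that p-value is below
``entry_alpha``; after every entry, any included term whose partial-F p-value
exceeds ``removal_alpha`` is removed (worst first).  The result is a compact
"selection equation" F ~ intercept + sum(coefficient * indicator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GermevalError

_RSS_TOL = 1e-12


@dataclass(frozen=True)
class StepwiseModel:
    """Final stepwise fit: intercept, ordered terms, and fit quality."""

    intercept: float
    terms: tuple[tuple[str, str, float], ...]  # (trait, class, coefficient)
    r: float
    r2: float
    entry_alpha: float
    removal_alpha: float

    def equation(self) -> str:
        """The fitted equation in y = a + b1*x1 ... display form."""
        parts = [f"{self.intercept:+.4f}".lstrip("+")]
        for i, (trait, cls, coef) in enumerate(self.terms, start=1):
            parts.append(f"{'+' if coef >= 0 else '-'} {abs(coef):.4f}*x{i}")
        legend = "; ".join(
            f"x{i} = [{trait}: {cls}]"
            for i, (trait, cls, _) in enumerate(self.terms, start=1)
        )
        return "y = " + " ".join(parts) + ("\nwhere " + legend if legend else "")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefficients, RSS)."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else \
        np.ones((len(y), 1))
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def _partial_f_pvalue(rss_small: float, rss_big: float, df_resid_big: int
                      ) -> float:
    """P-value for adding one term (RSS comparison, F(1, df) distribution)."""
    if df_resid_big <= 0:
        return 1.0
    num = max(rss_small - rss_big, 0.0)
    if rss_big <= _RSS_TOL * max(rss_small, 1.0):
        return 0.0 if num > _RSS_TOL else 1.0
    f = num / (rss_big / df_resid_big)
    return float(stats.f.sf(f, 1, df_resid_big))


def fit_stepwise(design: pd.DataFrame, response: np.ndarray | pd.Series,
                 entry_alpha: float = 0.05,
                 removal_alpha: float = 0.10) -> StepwiseModel:
    """Stepwise selection of indicator columns explaining the response.

    ``design`` is an indicator matrix (two-level (trait, class) columns or
    plain column labels); all columns are candidates.  Perfectly collinear
    candidates (no rank increase) are dropped with a warning.  If no
    candidate passes entry the intercept-only model is returned.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n != design.shape[0]:
        raise GermevalError("response length does not match design rows")
    if not np.all(np.isfinite(y)):
        raise GermevalError("response must be finite")

    columns = list(design.columns)
    X_all = design.to_numpy(dtype=float)
    included: list[int] = []
    dropped: set[int] = set()

    _, tss = _ols(np.empty((n, 0)), y)

    max_steps = 4 * len(columns) + 4
    for _ in range(max_steps):
        changed = False
        _, rss_cur = _ols(X_all[:, included], y)

        # Stop entering once the current fit is numerically perfect.
        if rss_cur > _RSS_TOL * max(tss, 1.0):
            best_p, best_j, best_rss = 1.0, None, None
            for j in range(len(columns)):
                if j in included or j in dropped:
                    continue
                trial = included + [j]
                Xt = X_all[:, trial]
                if np.linalg.matrix_rank(np.column_stack(
                        [np.ones(n), Xt])) <= len(included) + 1:
                    dropped.add(j)
                    warnings.warn(
                        f"candidate {columns[j]} is collinear with the "
                        "included terms; dropped", stacklevel=2)
                    continue
                _, rss_t = _ols(Xt, y)
                p = _partial_f_pvalue(rss_cur, rss_t, n - len(trial) - 1)
                if p < best_p or (p == best_p and best_j is None):
                    best_p, best_j, best_rss = p, j, rss_t
            if best_j is not None and best_p < entry_alpha:
                included.append(best_j)
                changed = True

        # Backward removal: worst included term while p > removal_alpha.
        while len(included) > 0:
            _, rss_full = _ols(X_all[:, included], y)
            worst_p, worst_j = -1.0, None
            for j in included:
                rest = [i for i in included if i != j]
                _, rss_rest = _ols(X_all[:, rest], y)
                p = _partial_f_pvalue(rss_rest, rss_full,
                                      n - len(included) - 1)
                if p > worst_p:
                    worst_p, worst_j = p, j
            if worst_j is not None and worst_p > removal_alpha:
                included.remove(worst_j)
                changed = True
            else:
                break

        if not changed:
            break

    beta, rss = _ols(X_all[:, included], y)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    terms = []
    for pos, j in enumerate(included, start=1):
        col = columns[j]
        if isinstance(col, tuple):
            trait, cls = str(col[0]), str(col[1])
        else:
            trait, cls = str(col), ""
        terms.append((trait, cls, float(beta[pos])))
    return StepwiseModel(intercept=float(beta[0]), terms=tuple(terms),
                         r=float(np.sqrt(r2)), r2=float(r2),
                         entry_alpha=entry_alpha, removal_alpha=removal_alpha)


def predict(model: StepwiseModel, design: pd.DataFrame) -> np.ndarray:
    """Apply the selection equation to an indicator matrix."""
    yhat = np.full(design.shape[0], model.intercept, dtype=float)
    for trait, cls, coef in model.terms:
        key = (trait, cls) if cls else trait
        if key not in design.columns:
            raise GermevalError(f"design is missing model column {key!r}")
        yhat += coef * design[key].to_numpy(dtype=float)
    return yhat


def equation_report(model: StepwiseModel) -> dict:
    """JSON-ready summary of the selection equation."""
    return {
        "intercept": model.intercept,
        "terms": [
            {"x": f"x{i}", "trait": t, "class": c, "coefficient": b}
            for i, (t, c, b) in enumerate(model.terms, start=1)
        ],
        "r": model.r,
        "r2": model.r2,
        "entry_alpha": model.entry_alpha,
        "removal_alpha": model.removal_alpha,
    }
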