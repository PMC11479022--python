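"""Covariance-matrix PCA of trait indicator matrices.

The decomposition works on the raw 0/1 indicator columns without correlation
scaling: the sample covariance matrix (n-1 denominator) is eigendecomposed,
eigenvalues are sorted descending, and each eigenvector's sign is fixed so
that its largest-magnitude loading is positive.  An eigenvalue's contribution
rate is its percentage share of the total variance (the covariance trace).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import GermevalError


@dataclass(frozen=True)
class PCAModel:
    """Fitted covariance PCA.

    ``loadings`` is columns x components (unit-norm eigenvectors, one column
    per PC), ``eigenvalues`` is non-increasing, and ``contribution_rate`` /
    ``cumulative_rate`` are in percent of total variance.
    """

    column_means: pd.Series
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    contribution_rate: np.ndarray
    cumulative_rate: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-|.| entry is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit_pca(matrix: pd.DataFrame) -> PCAModel:
    """Eigendecompose the sample covariance of an indicator matrix.

    Requires at least two rows and two columns.  Tiny negative eigenvalues
    from floating-point roundoff are clipped to zero.
    """
    if matrix.shape[0] < 2:
        raise GermevalError("PCA needs at least 2 accessions")
    if matrix.shape[1] < 2:
        raise GermevalError("PCA needs at least 2 indicator columns")
    X = matrix.to_numpy(dtype=float)
    means = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = scipy.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _fix_signs(eigvecs[:, order])
    total = float(eigvals.sum())
    contrib = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    comp_names = [f"PC{j + 1}" for j in range(len(eigvals))]
    return PCAModel(
        column_means=pd.Series(means, index=matrix.columns),
        eigenvalues=eigvals,
        loadings=pd.DataFrame(eigvecs, index=matrix.columns, columns=comp_names),
        contribution_rate=contrib,
        cumulative_rate=np.cumsum(contrib),
    )


def component_scores(model: PCAModel, matrix: pd.DataFrame) -> pd.DataFrame:
    """Project (centered) indicator rows onto the eigenvectors.

    On the training matrix, each score column has mean 0 and sample variance
    equal to its eigenvalue.
    """
    if list(matrix.columns) != list(model.loadings.index):
        raise GermevalError("indicator columns do not match the fitted model")
    centered = matrix.to_numpy(dtype=float) - model.column_means.to_numpy()
    scores = centered @ model.loadings.to_numpy()
    return pd.DataFrame(scores, index=matrix.index,
                        columns=model.loadings.columns)


def select_components(model: PCAModel, policy: str = "min_contribution",
                      k: int | None = None,
                      threshold: float = 6.0) -> list[int]:
    """Pick component indices (0-based) by policy.

    ``top_k`` returns the first ``k`` components; ``min_contribution``
    returns the leading run whose contribution rates are all >= ``threshold``
    percent.
    """
    if policy == "top_k":
        if k is None or k < 1 or k > model.n_components:
            raise GermevalError(
                f"top_k requires 1 <= k <= {model.n_components}, got {k}"
            )
        return list(range(k))
    if policy == "min_contribution":
        selected: list[int] = []
        for j, c in enumerate(model.contribution_rate):
            if c >= threshold:
                selected.append(j)
            else:
                break
        return selected
    raise GermevalError(f"unknown component-selection policy {policy!r}")


def loadings_table(model: PCAModel, n_components: int | None = None
                   ) -> pd.DataFrame:
    """Loadings with eigenvalue / contribution / cumulative footer rows."""
    k = n_components or model.n_components
    table = model.loadings.iloc[:, :k].copy()
    table.index = [f"{t}|{c}" for t, c in table.index]
    footer = pd.DataFrame(
        [model.eigenvalues[:k], model.contribution_rate[:k],
         model.cumulative_rate[:k]],
        index=["Eigenvalue", "Contribution rate (%)",
               "Cumulative contribution rate (%)"],
        columns=table.columns,
    )
    return pd.concat([table, footer])
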