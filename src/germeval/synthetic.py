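"""Synthetic accession-table generator.

Stands in for unpublished field data: categorical traits are drawn from the
reference survey's marginal class frequencies (288 Guatemalan cardamom
accessions), quantitative traits from truncated normals matching the survey's
mean/SD/min/max, rounded to recording precision.  An optional latent-group
mode draws group-specific class-probability vectors around the marginals
(Dirichlet with a concentration parameter), inducing the between-accession
correlation structure that makes PCA and clustering non-trivial and providing
a planted ground truth for clustering-recovery experiments.

What it does NOT emulate: between-trait dependence within a group beyond the
shared group identity, geographic structure, and measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GermevalError
from .reference import (REFERENCE_CLASS_COUNTS, REFERENCE_N,
                        REFERENCE_QUANT_SUMMARY)
from .schema import AccessionTable, TraitScheme, default_scheme, validate_table


def default_class_probabilities() -> dict[str, np.ndarray]:
    """Reference-survey marginal class probabilities per categorical trait."""
    return {
        trait: np.asarray(counts, dtype=float) / REFERENCE_N
        for trait, counts in REFERENCE_CLASS_COUNTS.items()
    }


def default_quantitative_params() -> dict[str, dict[str, float]]:
    return {t: dict(p) for t, p in REFERENCE_QUANT_SUMMARY.items()}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults reproduce the reference survey conditions.

    ``group_concentration`` scales the Dirichlet prior around the marginal
    probabilities in multi-group mode: large values keep groups close to the
    marginals, small values (< ~5) produce strongly diverged groups.
    """

    n_accessions: int = 288
    seed: int = 0
    class_probabilities: dict[str, np.ndarray] = field(
        default_factory=default_class_probabilities)
    quantitative_params: dict[str, dict[str, float]] = field(
        default_factory=default_quantitative_params)
    n_latent_groups: int = 1
    group_concentration: float = 50.0

    def validate(self, scheme: TraitScheme) -> None:
        if self.n_accessions < 0:
            raise GermevalError("n_accessions must be >= 0")
        if self.n_latent_groups < 1:
            raise GermevalError("n_latent_groups must be >= 1")
        if self.n_latent_groups > max(self.n_accessions, 1):
            raise GermevalError("more latent groups than accessions")
        if self.group_concentration <= 0:
            raise GermevalError("group_concentration must be positive")
        for trait in scheme.categorical:
            p = np.asarray(self.class_probabilities.get(trait.name, ()),
                           dtype=float)
            if p.size != len(trait.classes):
                raise GermevalError(
                    f"class probabilities for {trait.name!r} must have "
                    f"{len(trait.classes)} entries")
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise GermevalError(
                    f"class probabilities for {trait.name!r} must be a "
                    "probability vector")
        for trait in scheme.quantitative:
            q = self.quantitative_params.get(trait.name)
            if q is None:
                raise GermevalError(f"no quantitative params for {trait.name!r}")
            if not q["min"] < q["max"]:
                raise GermevalError(
                    f"{trait.name!r}: min must be below max")
            if q["sd"] <= 0:
                raise GermevalError(f"{trait.name!r}: sd must be positive")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled normal draws constrained to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), size - filled)
        out[filled:filled + take] = keep[:take]
        filled += take
    return out


def _sample(cfg: SyntheticConfig, scheme: TraitScheme
            ) -> tuple[AccessionTable, np.ndarray]:
    cfg.validate(scheme)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_accessions

    labels = (np.zeros(n, dtype=int) if cfg.n_latent_groups == 1
              else rng.integers(0, cfg.n_latent_groups, size=n))

    columns: dict[str, object] = {}
    for trait in scheme:
        if trait.is_quantitative:
            q = cfg.quantitative_params[trait.name]
            vals = _truncated_normal(rng, q["mean"], q["sd"], q["min"],
                                     q["max"], n)
            columns[trait.name] = np.round(vals, trait.decimals)
        else:
            marginal = np.asarray(cfg.class_probabilities[trait.name])
            if cfg.n_latent_groups == 1:
                group_p = marginal[None, :]
            else:
                alpha = cfg.group_concentration * marginal + 1e-6
                group_p = rng.dirichlet(alpha, size=cfg.n_latent_groups)
            cells = np.empty(n, dtype=object)
            for g in range(cfg.n_latent_groups):
                mask = labels == g
                k = int(mask.sum())
                if k:
                    idx = rng.choice(len(trait.classes), size=k, p=group_p[g])
                    cells[mask] = np.asarray(trait.classes)[idx]
            columns[trait.name] = cells
    ids = [f"SYN-{i + 1:06d}" for i in range(n)]
    frame = pd.DataFrame(columns, index=pd.Index(ids, name="accession_id"))
    if n == 0:
        frame = pd.DataFrame({t.name: pd.Series(dtype=object) for t in scheme},
                             index=pd.Index([], name="accession_id"))
        return AccessionTable(frame), labels
    return validate_table(frame, scheme), labels


def sample_accessions(cfg: SyntheticConfig,
                      scheme: TraitScheme | None = None) -> AccessionTable:
    """Draw a reproducible synthetic accession table for the scheme."""
    return _sample(cfg, scheme or default_scheme())[0]


def planted_truth(cfg: SyntheticConfig,
                  scheme: TraitScheme | None = None) -> np.ndarray:
    """Latent group label per accession (multi-group mode only)."""
    if cfg.n_latent_groups == 1:
        raise GermevalError("planted_truth requires n_latent_groups > 1")
    return _sample(cfg, scheme or default_scheme())[1]


def sample_with_truth(cfg: SyntheticConfig, scheme: TraitScheme | None = None
                      ) -> tuple[AccessionTable, np.ndarray]:
    """Table and latent labels from a single draw (same as the pair of
    :func:`sample_accessions` / :func:`planted_truth` at equal config)."""
    return _sample(cfg, scheme or default_scheme())
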