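"""End-to-end orchestration: one call from table (or generator config) to reports.

``run_pipeline`` executes the full analysis — diversity profile, covariance
PCA, component selection, composite F ranking, stepwise selection equation,
UPGMA grouping, variety labels and the two-stage conservation selection — and
writes the report bundle to an output directory:

* ``diversity_report.csv``  — per-trait counts, H', quantitative summaries
* ``pca_loadings.csv``      — loadings with eigenvalue/contribution footers
* ``f_ranking.csv``         — per-accession F-value and rank
* ``group_profile.csv``     — within-group class percentages with dominance flags
* ``conservation_report.csv`` / ``.json`` — the two-stage selection
* ``selection_equation.txt`` / ``.json`` — the stepwise equation
* ``dendrogram.nwk``        — Newick export of the UPGMA tree
* ``run_log.txt``           — versions, seed, config hash

Outputs are byte-identical under a fixed seed and config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (cut_k, group_profile, group_sizes, linkage_average,
                      partition_diversity, to_newick)
from .composite import f_value, membership_rescale
from .diversity import diversity_report
from .errors import PipelineStageError
from .pca import (component_scores, fit_pca, loadings_table,
                  select_components)
from .schema import (AccessionTable, TraitScheme, default_scheme,
                     encode_indicators, load_accession_table)
from .stepwise import equation_report, fit_stepwise
from .synthetic import SyntheticConfig, sample_accessions
from .varieties import (classify_by_height, conservation_table,
                        coverage_check, two_stage_selection, variety_labels)


@dataclass
class PipelineConfig:
    """Knobs for the full analysis (defaults follow the reference study design)."""

    component_policy: str = "min_contribution"  # or "top_k"
    min_contribution: float = 6.0               # percent
    fallback_k: int = 3                         # if the leading run is empty
    k_groups: int = 6
    k1: int = 14
    k2: int = 12
    entry_alpha: float = 0.05
    removal_alpha: float = 0.10
    dominance: float = 80.0
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    table: AccessionTable
    diversity: pd.DataFrame
    pca_model: object
    components: list[int]
    f_table: pd.DataFrame
    stepwise_model: object
    dendrogram: object
    partition: dict[str, int]
    profile: pd.DataFrame
    conservation: object
    coverage: tuple
    artifacts: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False
    return _Ctx()


def run_pipeline(source: str | Path | AccessionTable | SyntheticConfig,
                 cfg: PipelineConfig | None = None,
                 outdir: str | Path | None = None,
                 scheme: TraitScheme | None = None) -> PipelineResult:
    """Run every analysis stage and (optionally) write the report bundle.

    ``source`` may be a CSV/TSV path, a validated table, or a
    :class:`SyntheticConfig` to simulate one.
    """
    cfg = cfg or PipelineConfig()
    scheme = scheme or default_scheme()

    with _stage("load"):
        if isinstance(source, AccessionTable):
            table = source
        elif isinstance(source, SyntheticConfig):
            table = sample_accessions(source, scheme)
        else:
            table = load_accession_table(source, scheme)

    with _stage("diversity"):
        div = diversity_report(table, scheme)

    with _stage("encode"):
        matrix = encode_indicators(table, scheme)

    with _stage("pca"):
        model = fit_pca(matrix)
        comps = select_components(model, cfg.component_policy,
                                  k=cfg.fallback_k,
                                  threshold=cfg.min_contribution)
        if not comps:
            comps = select_components(model, "top_k", k=cfg.fallback_k)
        scores = component_scores(model, matrix)

    with _stage("composite"):
        u = membership_rescale(scores, comps)
        f_table = f_value(u, model, comps)

    with _stage("stepwise"):
        sw = fit_stepwise(matrix, f_table["F"].to_numpy(),
                          entry_alpha=cfg.entry_alpha,
                          removal_alpha=cfg.removal_alpha)

    with _stage("cluster"):
        dendro = linkage_average(scores, comps)
        partition = cut_k(dendro, cfg.k_groups)
        profile = group_profile(partition, table, scheme,
                                dominance=cfg.dominance)

    with _stage("two_stage_selection"):
        report = two_stage_selection(table, scheme, k1=cfg.k1, k2=cfg.k2,
                                     partition=partition,
                                     n_components=max(len(comps), 1))
        coverage = coverage_check(report, partition)

    result = PipelineResult(
        table=table, diversity=div, pca_model=model, components=comps,
        f_table=f_table, stepwise_model=sw, dendrogram=dendro,
        partition=partition, profile=profile, conservation=report,
        coverage=coverage,
    )

    if outdir is not None:
        with _stage("write_reports"):
            result.artifacts = _write_reports(result, cfg, scheme,
                                              Path(outdir))
    return result


def _write_reports(res: PipelineResult, cfg: PipelineConfig,
                   scheme: TraitScheme, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        paths[name] = path

    save("diversity_report.csv", lambda p: res.diversity.to_csv(p))
    save("pca_loadings.csv",
         lambda p: loadings_table(res.pca_model,
                                  max(len(res.components), 3)).to_csv(p))
    save("f_ranking.csv",
         lambda p: res.f_table.sort_values("rank").to_csv(
             p, index_label="accession"))
    save("group_profile.csv",
         lambda p: res.profile.assign(
             percent=res.profile["percent"].round(2)).to_csv(p, index=False))

    labels = classify_by_height(res.table)
    save("conservation_report.csv",
         lambda p: conservation_table(res.conservation, labels,
                                      res.partition).to_csv(p, index=False))
    cons = res.conservation
    cov_ok, cov_counts, cov_short = res.coverage
    save("conservation_report.json", lambda p: p.write_text(json.dumps({
        "stage1_ids": list(cons.stage1_ids),
        "stage2_ids": list(cons.stage2_ids),
        "union_ids": list(cons.union_ids),
        "stage2_overlap_skipped": list(cons.stage2_overlap),
        "avg_h_stage1": cons.avg_h_stage1,
        "avg_h_union": cons.avg_h_union,
        "group_counts": {str(g): c for g, c in cons.group_counts.items()},
        "coverage_ok": bool(cov_ok),
        "coverage_counts": {str(g): c for g, c in cov_counts.items()},
        "groups_under_represented": list(cov_short),
    }, indent=2)))

    save("selection_equation.txt",
         lambda p: p.write_text(res.stepwise_model.equation() + "\n"))
    save("selection_equation.json", lambda p: p.write_text(
        json.dumps(equation_report(res.stepwise_model), indent=2)))
    save("dendrogram.nwk", lambda p: p.write_text(to_newick(res.dendrogram)))

    sizes = group_sizes(res.partition)
    log = "\n".join([
        f"germeval {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {cfg.seed}",
        f"config_hash {cfg.digest()}",
        f"n_accessions {res.table.n}",
        f"n_indicator_columns {scheme.n_indicator_columns}",
        f"components {[c + 1 for c in res.components]}",
        f"group_sizes {sizes}",
        f"group_label_diversity {partition_diversity(res.partition):.4f}",
        f"stepwise_terms {len(res.stepwise_model.terms)} "
        f"r2 {res.stepwise_model.r2:.6f}",
        f"conservation_union {len(res.conservation.union_ids)}",
    ]) + "\n"
    save("run_log.txt", lambda p: p.write_text(log))
    return paths
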