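"""End-to-end orchestration with a YAML config and a resolved manifest.

``run_discovery`` executes harmonize -> RPCA -> ICA -> component selection
and orientation -> network inference -> master-regulator analysis ->
gradient -> survival association, persisting every intermediate artifact.
``run_projection`` applies a fitted gradient model to a new cohort.  Every
tunable threshold lives in :class:`PipelineConfig`; a run writes the fully
resolved configuration next to its outputs so results are reproducible from
the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


import pandas as pd
import yaml

from ._log import get_logger
from . import io as mio

from .gradient import GradientScore, compute_gradient, project_gradient
from .lrica import fit_ica, orient_component, rpca_decompose, select_components
from .mra import master_regulator_analysis
from .regnet import apply_dpi, assign_modes, infer_candidate_edges
from .survival import cox_fit, optimal_cutpoint

log = get_logger("pipeline")

__all__ = ["PipelineConfig", "run_discovery", "run_projection"]


@dataclass
class PipelineConfig:
    """All stage parameters in one place; unknown keys are rejected."""

    expression_paths: list[str] = field(default_factory=list)
    survival_path: str | None = None
    gene_sets_path: str | None = None
    tf_list_path: str | None = None
    model_path: str | None = None        # for projection runs
    output_dir: str = "mrgradient_out"
    seed: int = 0
    normalize: str = "quantile"
    rpca_lambda: float | None = None
    rpca_tol: float = 1e-7
    rpca_max_iter: int = 500
    n_components: int | None = None
    n_restarts: int = 5
    ica_contrast: str = "spline"
    kurtosis_min: float = 3.0
    fdr_max: float = 0.05
    gsea_n_perm: int = 1000
    gsea_weight_p: float = 1.0
    net_n_perm: int = 1000
    net_alpha: float = 0.01
    dpi_tolerance: float = 0.0
    mra_sd_mult: float = 2.0
    mra_p_max: float = 0.01
    mra_des_min: float = 1.0
    projection_min_overlap: float = 0.5
    cutpoint_min_frac: float = 0.1
    # score the gradient on the RPCA low-rank matrix: the sparse part holds
    # outlying entries that otherwise leak straight into the weighted sum
    gradient_on_lowrank: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def manifest(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(config: PipelineConfig, out: Path, extra: dict) -> None:
    manifest = {"config": config.manifest(), **extra}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def _load_cohorts(config: PipelineConfig) -> mio.ExpressionMatrix:
    if not config.expression_paths:
        raise ValueError("stage harmonize: no expression paths configured")
    cohorts = []
    for p in config.expression_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"stage harmonize: expression file {p!r} not found")
        cohorts.append(mio.read_expression_matrix(p))
    return mio.harmonize_cohorts(cohorts, method=config.normalize)


def run_discovery(config: PipelineConfig) -> Path:
    """Full discovery pipeline; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage harmonize: %d cohorts", len(config.expression_paths))
    expr = _load_cohorts(config)
    mio.write_expression_matrix(expr, out / "harmonized.tsv")

    log.info("stage rpca")
    dec = rpca_decompose(expr.values.to_numpy(), lam=config.rpca_lambda,
                         tol=config.rpca_tol, max_iter=config.rpca_max_iter)
    pd.DataFrame(dec.L, index=expr.gene_ids, columns=expr.sample_ids).to_csv(
        out / "L.tsv", sep="\t")
    pd.DataFrame(dec.S, index=expr.gene_ids, columns=expr.sample_ids).to_csv(
        out / "S.tsv", sep="\t")

    log.info("stage ica")
    decomp = fit_ica(
        pd.DataFrame(dec.L, index=expr.gene_ids, columns=expr.sample_ids),
        n_components=config.n_components, n_restarts=config.n_restarts,
        seed=config.seed, contrast=config.ica_contrast,
    )
    decomp.contributions.to_csv(out / "contributions.tsv", sep="\t")
    decomp.mixing.to_csv(out / "mixing.tsv", sep="\t")

    log.info("stage select")
    if config.gene_sets_path is None:
        raise ValueError("stage select: gene_sets_path not configured")
    gene_sets = mio.read_gene_sets(config.gene_sets_path)
    annotations = select_components(
        decomp, gene_sets, kurtosis_min=config.kurtosis_min,
        fdr_max=config.fdr_max, n_perm=config.gsea_n_perm, seed=config.seed,
    )
    annotations = [
        orient_component(
            ann,
            gene_sets[max(ann.enrichments, key=lambda e: abs(e[1]))[0]],
            decomp,
        ) if ann.selected else ann
        for ann in annotations
    ]
    with open(out / "annotations.json", "w") as fh:
        json.dump([dataclasses.asdict(a) for a in annotations], fh, indent=1)
    selected = [a for a in annotations if a.selected]
    if not selected:
        raise ValueError("stage select: no component passed selection")

    log.info("stage survival-filter")
    if config.survival_path is None:
        raise ValueError("stage survival: survival_path not configured")
    surv = mio.read_survival(config.survival_path)
    cox_by_comp = cox_fit(
        decomp.mixing.iloc[:, [a.component_index for a in selected]]
        .set_axis([f"comp{a.component_index}" for a in selected], axis=1),
        surv, mode="univariate",
    )
    prognostic = min(zip(selected, cox_by_comp), key=lambda t: t[1].p_value)
    ann_prog, cox_prog = prognostic
    log.info("prognosis-relevant component: %d (p=%.3g)",
             ann_prog.component_index, cox_prog.p_value)

    log.info("stage network")
    if config.tf_list_path is None:
        raise ValueError("stage network: tf_list_path not configured")
    tf_list = [
        line.strip() for line in open(config.tf_list_path)
        if line.strip() and line.strip() in set(expr.gene_ids)
    ]
    edges = infer_candidate_edges(
        expr, tf_list, n_perm=config.net_n_perm, alpha=config.net_alpha,
        seed=config.seed,
    )
    edges = apply_dpi(edges, tolerance=config.dpi_tolerance)
    network = assign_modes(expr, edges)
    network.params = {
        "n_perm": config.net_n_perm, "alpha": config.net_alpha,
        "dpi_tolerance": config.dpi_tolerance, "seed": config.seed,
    }
    with open(out / "network.json", "w") as fh:
        json.dump(network.to_dict(), fh)

    log.info("stage mra")
    contrib = decomp.contributions.iloc[:, ann_prog.component_index]
    selected_mrs, tested = master_regulator_analysis(
        network, contrib, f"comp{ann_prog.component_index}",
        sd_mult=config.mra_sd_mult, p_max=config.mra_p_max,
        des_min=config.mra_des_min, weight_p=config.gsea_weight_p,
    )
    pd.DataFrame([dataclasses.asdict(m) for m in tested]).to_csv(
        out / "mrs.tsv", sep="\t", index=False)
    if not selected_mrs:
        raise ValueError("stage mra: no master regulator selected")

    log.info("stage gradient")
    if config.gradient_on_lowrank:
        score_expr = mio.ExpressionMatrix(
            pd.DataFrame(dec.L, index=expr.gene_ids, columns=expr.sample_ids),
            cohort_labels=expr.cohort_labels,
        )
    else:
        score_expr = expr
    score = compute_gradient(score_expr, selected_mrs)
    score.values.rename("gradient").to_csv(out / "scores.tsv", sep="\t")
    model = {
        "mr_weights": score.mr_weights,
        "component": f"comp{ann_prog.component_index}",
        "min_overlap_frac": config.projection_min_overlap,
    }
    with open(out / "model.json", "w") as fh:
        json.dump(model, fh, indent=1)

    log.info("stage survival")
    cox = cox_fit(score.values.to_frame("gradient"), surv)[0]
    cut = optimal_cutpoint(score, surv, min_frac=config.cutpoint_min_frac)
    surv_report = {
        "cox": dataclasses.asdict(cox),
        "cutpoint": dataclasses.asdict(cut),
    }
    with open(out / "survival.json", "w") as fh:
        json.dump(surv_report, fh, indent=1)

    _write_manifest(config, out, {
        "selected_components": [a.component_index for a in selected],
        "prognostic_component": ann_prog.component_index,
        "n_master_regulators": len(selected_mrs),
        "gradient_cox_hr_per_sd": cox.hazard_ratio,
    })
    return out


def run_projection(config: PipelineConfig) -> Path:
    """Project a fitted gradient model onto a new cohort."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.model_path is None:
        raise ValueError("stage project: model_path not configured")
    with open(config.model_path) as fh:
        model = json.load(fh)
    expr = _load_cohorts(config)
    if config.gradient_on_lowrank:
        log.info("stage rpca (projection cohort)")
        dec = rpca_decompose(expr.values.to_numpy(), lam=config.rpca_lambda,
                             tol=config.rpca_tol,
                             max_iter=config.rpca_max_iter)
        expr = mio.ExpressionMatrix(
            pd.DataFrame(dec.L, index=expr.gene_ids, columns=expr.sample_ids),
            cohort_labels=expr.cohort_labels,
        )
    template = GradientScore(
        values=pd.Series(dtype=float),
        mr_weights={k: float(v) for k, v in model["mr_weights"].items()},
        scale_mean=0.0, scale_sd=1.0,
    )
    score = project_gradient(
        expr, template,
        min_overlap_frac=model.get("min_overlap_frac",
                                   config.projection_min_overlap),
    )
    score.values.rename("gradient").to_csv(out / "scores.tsv", sep="\t")
    extra: dict = {"n_model_regulators": len(template.mr_weights)}
    if config.survival_path:
        surv = mio.read_survival(config.survival_path)
        cox = cox_fit(score.values.to_frame("gradient"), surv)[0]
        with open(out / "survival.json", "w") as fh:
            json.dump({"cox": dataclasses.asdict(cox)}, fh, indent=1)
        extra["gradient_cox_hr_per_sd"] = cox.hazard_ratio
    _write_manifest(config, out, extra)
    return out
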