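"""The master-regulator gradient: a continuous per-patient prognostic score.

For patient j the raw score is ``sum_i dES_i * GE_ij`` over the selected
master regulators i present in the expression matrix, i.e. each regulator's
expression weighted by its two-tailed enrichment score; the cohort scores
are then standardized to mean 0, SD 1 ("scaled summation").  Since the
two-tailed enrichment yields one dES per regulator, the weight is constant
across patients; a regulator selected in several components contributes the
sum of its per-component weights.

A fitted score model can be projected onto a new cohort by applying the same
weights to the shared regulators and re-standardizing within that cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._log import get_logger
from .io import ExpressionMatrix
from .lrica import ICADecomposition
from .mra import MasterRegulator

log = get_logger("gradient")

__all__ = ["GradientScore", "compute_gradient", "project_gradient",
           "match_phenotype_component"]


@dataclass
class GradientScore:
    values: pd.Series            # per-sample scaled score
    mr_weights: dict[str, float]  # regulator -> dES weight
    scale_mean: float
    scale_sd: float
    scaled: bool = True

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def _combined_weights(mrs: list[MasterRegulator]) -> dict[str, float]:
    weights: dict[str, float] = {}
    for mr in mrs:
        weights[mr.regulator] = weights.get(mr.regulator, 0.0) + mr.dES
    return weights


def compute_gradient(
    expr: ExpressionMatrix, mrs: list[MasterRegulator] | dict[str, float]
) -> GradientScore:
    """Weighted regulator-expression sum, standardized across the cohort."""
    weights = mrs if isinstance(mrs, dict) else _combined_weights(mrs)
    if not weights:
        raise ValueError("no master-regulator weights given")
    if all(w == 0 for w in weights.values()):
        raise ValueError("degenerate weight vector: all weights zero")
    present = {g: w for g, w in weights.items() if g in set(expr.gene_ids)}
    if not present:
        raise ValueError("no master regulator overlaps the expression genes")
    dropped = sorted(set(weights) - set(present))
    if dropped:
        log.info("%d master regulators absent from matrix: %s",
                 len(dropped), dropped[:10])
    genes = sorted(present)
    w = np.array([present[g] for g in genes])
    ge = expr.values.loc[genes].to_numpy()
    raw = w @ ge
    if len(raw) < 2:
        log.warning("single sample: gradient returned unscaled")
        return GradientScore(
            pd.Series(raw, index=expr.sample_ids), present, 0.0, 1.0, scaled=False
        )
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if sd == 0:
        raise ValueError("gradient has zero variance across samples")
    return GradientScore(
        pd.Series((raw - mean) / sd, index=expr.sample_ids), present, mean, sd
    )


def project_gradient(
    new_expr: ExpressionMatrix,
    score_model: GradientScore,
    min_overlap_frac: float = 0.5,
) -> GradientScore:
    """Apply a fitted weight vector to a new cohort.

    Regulators with non-zero weight must overlap the new cohort's genes by at
    least ``min_overlap_frac``; the score is re-standardized within the new
    cohort and the retained |weight| fraction logged.
    """
    active = {g: w for g, w in score_model.mr_weights.items() if w != 0}
    genes = set(new_expr.gene_ids)
    shared = {g: w for g, w in active.items() if g in genes}
    if len(shared) < min_overlap_frac * len(active):
        missing = sorted(set(active) - set(shared))
        raise ValueError(
            f"only {len(shared)}/{len(active)} model regulators present "
            f"(floor {min_overlap_frac:.0%}); missing: {missing[:10]}"
        )
    frac_w = sum(abs(w) for w in shared.values()) / sum(abs(w) for w in active.values())
    log.info("projection retains %d/%d regulators (%.1f%% of |weight|)",
             len(shared), len(active), 100 * frac_w)
    return compute_gradient(new_expr, shared)


def match_phenotype_component(
    decomp: ICADecomposition, score: GradientScore
) -> tuple[int, float, float]:
    """Component whose per-sample mixing best matches the gradient.

    Returns ``(component index, spearman r, p)`` for the column of the
    mixing matrix maximizing |Spearman r| against the score.
    """
    if list(decomp.sample_ids) != list(score.sample_ids):
        if set(decomp.sample_ids) != set(score.sample_ids):
            raise ValueError("sample mismatch between decomposition and score")
        mixing = decomp.mixing.loc[score.sample_ids]
    else:
        mixing = decomp.mixing
    best = (-1, 0.0, 1.0)
    for c in range(decomp.n_components):
        res = spearmanr(mixing.iloc[:, c], score.values)
        if abs(res.statistic) > abs(best[1]):
            best = (c, float(res.statistic), float(res.pvalue))
    return best
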