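"""Auxiliary omics layers correlated with the gradient.

Stroma and immune cell abundance is scored from bulk expression as the log2
geometric mean of cell-type marker genes (the mean of log2 values), and a
cell type is tied to a phenotype axis when its Spearman correlation passes
both an effect-size and a significance threshold (|r| > 0.2, p < 0.05 by
default).  DNA methylation is profiled by running ICA on logit-transformed
beta values, picking the component best correlated with the gradient, and
summarizing the outlying CpGs (|contribution| >= 3 SD) as a per-patient
median beta.  Lipidomic intensities are collapsed to per-sample subfamily
medians and correlated with the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._log import get_logger
from .gradient import GradientScore
from .io import ExpressionMatrix
from .lrica import fit_ica

log = get_logger("omics")

__all__ = [
    "AbundanceScore",
    "MethylationMatrix",
    "marker_score",
    "correlate_with_axis",
    "methyl_component_profile",
    "lipid_subfamily_summary",
]


@dataclass
class AbundanceScore:
    cell_type: str
    scores: pd.Series      # per-sample, log2 scale
    markers_used: list[str]


@dataclass
class MethylationMatrix:
    """CpG x sample matrix of methylation fractions (beta values)."""

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        b = self.beta
        if b.index.duplicated().any() or b.columns.duplicated().any():
            raise ValueError("duplicate CpG or sample ids")
        arr = b.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or arr.min() < 0 or arr.max() > 1:
            raise ValueError("beta values must be finite and within [0, 1]")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


def marker_score(
    expr: ExpressionMatrix, marker_sets: dict[str, list[str]]
) -> list[AbundanceScore]:
    """Per-sample abundance score per cell type: mean log2 expression of the
    present markers (the log2 geometric mean of linear-scale values).

    Cell types with no marker in the matrix are omitted with a warning;
    missing markers within a type are logged and skipped.
    """
    genes = set(expr.gene_ids)
    out = []
    for cell_type, markers in marker_sets.items():
        present = [m for m in dict.fromkeys(markers) if m in genes]
        absent = [m for m in markers if m not in genes]
        if not present:
            log.warning("cell type %s: no marker present; omitted", cell_type)
            continue
        if absent:
            log.info("cell type %s: %d markers absent: %s",
                     cell_type, len(absent), absent[:5])
        scores = expr.values.loc[present].mean(axis=0)
        out.append(AbundanceScore(cell_type, scores, present))
    return out


def axis_selected(r: float, p: float, r_min: float = 0.2,
                  p_max: float = 0.05) -> bool:
    """Selection rule for axis association: |r| above the effect-size floor
    AND p below the significance ceiling (both strict)."""
    return bool(abs(r) > r_min and p < p_max)


def correlate_with_axis(
    scores: pd.Series,
    axis: pd.Series,
    r_min: float = 0.2,
    p_max: float = 0.05,
) -> tuple[float, float, bool]:
    """Spearman association of a per-sample score with a phenotype axis.

    Returns (r, p, selected) with selected iff |r| > r_min and p < p_max.
    """
    s = pd.Series(scores)
    a = pd.Series(axis)
    if set(s.index) != set(a.index):
        raise ValueError("sample sets differ between scores and axis")
    a = a.loc[s.index]
    if len(s) < 5:
        raise ValueError("need at least 5 samples")
    if s.nunique() == 1 or a.nunique() == 1:
        raise ValueError("constant input; correlation undefined")
    res = spearmanr(s, a)
    r, p = float(res.statistic), float(res.pvalue)
    return r, p, axis_selected(r, p, r_min, p_max)


def methyl_component_profile(
    beta: MethylationMatrix,
    gradient: GradientScore,
    sd_mult: float = 3.0,
    n_components: int | None = None,
    seed: int = 0,
    eps: float = 0.01,
) -> tuple[set[str], pd.Series | None, float]:
    """Methylation component tracking the gradient.

    Beta values are logit-transformed (clamped to [eps, 1-eps]), decomposed
    by ICA over CpGs, and the component whose per-sample mixing best
    correlates with the gradient is chosen.  CpGs with |contribution| at
    least ``sd_mult`` SD are selected and their per-patient median beta is
    returned with its Spearman r against the gradient.  An empty selection
    is flagged by ``(set(), None, nan)``.
    """
    shared = [s for s in gradient.sample_ids if s in set(beta.sample_ids)]
    if len(shared) < 5:
        raise ValueError("need at least 5 samples shared with the gradient")
    b = beta.beta[shared]
    if float(b.to_numpy().std()) == 0:
        raise ValueError("constant beta matrix; no variance to decompose")
    logit = np.log(np.clip(b, eps, 1 - eps) / (1 - np.clip(b, eps, 1 - eps)))
    decomp = fit_ica(
        logit - logit.to_numpy().mean(), n_components=n_components,
        seed=seed, n_restarts=3,
    )
    grad = gradient.values.loc[shared]
    best_c, best_r = 0, 0.0
    for c in range(decomp.n_components):
        r = spearmanr(decomp.mixing.iloc[:, c], grad).statistic
        if abs(r) > abs(best_r):
            best_c, best_r = c, float(r)
    contrib = decomp.contributions.iloc[:, best_c]
    dev = np.abs(contrib - contrib.mean())
    selected = set(contrib.index[dev >= sd_mult * contrib.std()])
    if not selected:
        log.warning("no CpG passes the %.1f SD contribution threshold", sd_mult)
        return set(), None, float("nan")
    median_beta = b.loc[sorted(selected)].median(axis=0)
    r = float(spearmanr(median_beta, grad).statistic)
    return selected, median_beta, r


def lipid_subfamily_summary(
    intensities: pd.DataFrame,
    subfamily_map: dict[str, str],
    gradient: GradientScore,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-sample subfamily medians and their gradient association.

    Returns a DataFrame indexed by subfamily with columns ``r``, ``p`` and
    ``selected`` (p < p_max); per-sample median profiles are attached as
    ``.attrs['profiles']``.  Every metabolite must be mapped.
    """
    unmapped = [m for m in intensities.index if m not in subfamily_map]
    if unmapped:
        raise ValueError(f"unmapped metabolites: {unmapped[:10]}")
    shared = [s for s in gradient.sample_ids if s in set(intensities.columns)]
    if len(shared) < 5:
        raise ValueError("need at least 5 samples shared with the gradient")
    grad = gradient.values.loc[shared]
    groups = pd.Series({m: subfamily_map[m] for m in intensities.index})
    profiles = {}
    rows = []
    for fam in sorted(groups.unique()):
        members = groups.index[groups == fam]
        med = intensities.loc[members, shared].median(axis=0)
        profiles[fam] = med
        if med.nunique() == 1:
            log.warning("subfamily %s has a constant median profile", fam)
            r, p = float("nan"), float("nan")
        else:
            res = spearmanr(med, grad)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "subfamily": fam,
            "n_metabolites": len(members),
            "r": r,
            "p": p,
            "selected": bool(p < p_max),
        })
    out = pd.DataFrame(rows).set_index("subfamily")
    out.attrs["profiles"] = pd.DataFrame(profiles).T
    return out
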