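"""Outcome association: log-rank tests, optimal cutpoints, Cox models.

The continuous gradient is associated with overall survival either directly
(Cox proportional hazards on the standardized score, Efron tie handling) or
by dichotomizing at the cutpoint with the best log-rank separation.  Because
scanning cutpoints inflates the nominal log-rank p, the maximally-selected
rank statistic correction of Lausen & Schumacher (1992) is reported
alongside the nominal value, and is the recommended one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import norm
from sklearn.decomposition import PCA

from ._log import get_logger
from .gradient import GradientScore
from .io import SurvivalTable

log = get_logger("survival")

__all__ = ["CoxResult", "CutpointResult", "km_logrank", "optimal_cutpoint",
           "cox_fit", "pca_cox"]


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_samples: int
    n_events: int


@dataclass
class CutpointResult:
    threshold: float
    logrank_p: float          # nominal p of the best split (anti-conservative)
    corrected_p: float        # maximally-selected-statistic correction
    group_sizes: tuple[int, int]
    statistic: float


def km_logrank(
    groups: pd.Series | dict, surv: SurvivalTable
) -> tuple[float, float]:
    """K-group log-rank test; returns (chi2 statistic, p)."""
    g = pd.Series(groups)
    aligned = surv.aligned(list(g.index))
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 1).any():
        raise ValueError("every group needs at least one sample")
    if aligned["event"].sum() == 0:
        log.warning("no events in any group; log-rank undefined, p set to 1")
        return 0.0, 1.0
    res = multivariate_logrank_test(
        aligned["time"], g.to_numpy(), aligned["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def _logrank_scan(
    score: np.ndarray, time: np.ndarray, event: np.ndarray, min_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized log-rank z for every admissible split (low = score <= c).

    Vectorized over cutpoints: samples are put in score order, and for each
    event time the size of the low-score risk set is a cumulative count.
    """
    n = len(score)
    order = np.argsort(score, kind="mergesort")
    time = time[order]
    event = event[order]
    lo = int(np.ceil(min_frac * n))
    ks = np.arange(lo, n - lo + 1)
    if ks.size == 0:
        raise ValueError("min_frac leaves no admissible cutpoint")
    O = np.zeros(ks.size)
    E = np.zeros(ks.size)
    V = np.zeros(ks.size)
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        nj = at_risk.sum()
        dj = dead.sum()
        n1 = np.cumsum(at_risk)[ks - 1]
        d1 = np.cumsum(dead)[ks - 1]
        O += d1
        E += dj * n1 / nj
        if nj > 1:
            V += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    z = (O - E) / np.sqrt(np.maximum(V, 1e-300))
    z[V <= 0] = 0.0
    return ks, z


def _maxstat_p(b: float, eps_low: float, eps_high: float) -> float:
    """Lausen-Schumacher tail bound for the maximally selected log-rank
    statistic over the quantile range [eps_low, eps_high]."""
    b = abs(b)
    if b < 1e-8:
        return 1.0
    logt = np.log((eps_high * (1 - eps_low)) / (eps_low * (1 - eps_high)))
    p = 4 * norm.pdf(b) / b + norm.pdf(b) * (b - 1 / b) * logt
    return float(min(1.0, p))


def optimal_cutpoint(
    score: GradientScore | pd.Series,
    surv: SurvivalTable,
    min_frac: float = 0.1,
) -> CutpointResult:
    """Best log-rank split of a continuous score, with multiplicity
    correction.

    Scans every threshold leaving at least ``min_frac`` of the cohort on each
    side and returns the one minimizing the log-rank p.  ``logrank_p`` is the
    nominal (anti-conservative) minimum; ``corrected_p`` applies the
    maximally-selected rank statistic adjustment and is the value to report.
    """
    s = score.values if isinstance(score, GradientScore) else pd.Series(score)
    if len(s) < 10:
        raise ValueError("need at least 10 samples for cutpoint selection")
    if not 0 < min_frac < 0.5:
        raise ValueError("min_frac must lie in (0, 0.5)")
    aligned = surv.aligned(list(s.index))
    time = aligned["time"].to_numpy(dtype=float)
    event = aligned["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events; cutpoint selection undefined")
    vals = s.to_numpy(dtype=float)
    ks, z = _logrank_scan(vals, time, event, min_frac)
    best = int(np.argmax(np.abs(z)))
    b = float(z[best])
    k = int(ks[best])
    svals = np.sort(vals, kind="mergesort")
    threshold = 0.5 * (svals[k - 1] + svals[k]) if k < len(svals) else svals[-1]
    nominal = float(2 * norm.sf(abs(b)))
    corrected = _maxstat_p(b, min_frac, 1 - min_frac)
    return CutpointResult(
        threshold=float(threshold),
        logrank_p=nominal,
        corrected_p=corrected,
        group_sizes=(k, len(vals) - k),
        statistic=b,
    )


def cox_fit(
    covariates: pd.DataFrame,
    surv: SurvivalTable,
    mode: str = "univariate",
) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron ties); HRs are per SD of
    each covariate.

    ``'univariate'`` fits one model per column; ``'multivariate'`` fits a
    joint model.  Constant or collinear covariates raise.
    """
    if mode not in {"univariate", "multivariate"}:
        raise ValueError(f"unknown mode {mode!r}")
    aligned = surv.aligned(list(covariates.index))
    if not np.isfinite(covariates.to_numpy()).all():
        raise ValueError("covariates must be finite")
    n_events = int(aligned["event"].sum())
    if n_events < 10:
        log.warning("only %d events; Cox estimates will be unstable", n_events)
    sds = covariates.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"constant covariates: {bad}")
    Xs = (covariates - covariates.mean()) / sds
    if mode == "multivariate" and Xs.shape[1] > 1:
        corr = np.corrcoef(Xs.to_numpy().T)
        if np.linalg.matrix_rank(corr) < Xs.shape[1]:
            raise ValueError("collinear covariates in multivariate mode")

    def _fit(df_cov: pd.DataFrame) -> list[CoxResult]:
        df = df_cov.copy()
        df["time"] = aligned["time"].to_numpy()
        df["event"] = aligned["event"].to_numpy()
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # lifelines ConvergenceError and friends
            raise ValueError(f"Cox fit failed: {exc}") from exc
        out = []
        for name in df_cov.columns:
            out.append(CoxResult(
                covariate=str(name),
                hazard_ratio=float(np.exp(cph.params_[name])),
                ci_low=float(np.exp(cph.confidence_intervals_.loc[name].iloc[0])),
                ci_high=float(np.exp(cph.confidence_intervals_.loc[name].iloc[1])),
                p_value=float(cph.summary.loc[name, "p"]),
                n_samples=len(df),
                n_events=n_events,
            ))
        return out

    if mode == "multivariate":
        return _fit(Xs)
    results = []
    for col in Xs.columns:
        results.extend(_fit(Xs[[col]]))
    return results


def pca_cox(
    component_scores: pd.DataFrame, surv: SurvivalTable
) -> tuple[list[CoxResult], int, dict[str, float]]:
    """PCA of per-sample component scores, then Cox per dimension coordinate.

    Returns (per-dimension results, index of the dimension with the lowest p,
    squared-loading contribution of each input component to that dimension).
    """
    if component_scores.shape[1] < 2:
        raise ValueError("need at least 2 components")
    if component_scores.shape[0] < component_scores.shape[1]:
        raise ValueError("fewer samples than components")
    pca = PCA(n_components=component_scores.shape[1])
    coords = pca.fit_transform(
        (component_scores - component_scores.mean()).to_numpy()
    )
    dims = pd.DataFrame(
        coords, index=component_scores.index,
        columns=[f"dim{i + 1}" for i in range(coords.shape[1])],
    )
    usable = [c for c in dims.columns if dims[c].std(ddof=1) > 1e-12]
    results = cox_fit(dims[usable], surv, mode="univariate")
    best = int(usable[int(np.argmin([r.p_value for r in results]))][3:]) - 1
    load = pca.components_[best] ** 2
    contributions = {
        str(comp): float(100 * l / load.sum())
        for comp, l in zip(component_scores.columns, load)
    }
    return results, best, contributions
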