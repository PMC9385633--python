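"""Low-Rank ICA: robust PCA split followed by independent component analysis.

The expression matrix is first decomposed by principal component pursuit
(RPCA) into a low-rank part L capturing the shared structure of the cohort
and a sparse part S absorbing outlying entries, by minimizing
``||L||_* + lambda * ||S||_1`` subject to ``L + S = M`` with an inexact
augmented-Lagrangian iteration.  L is then deconvoluted into statistically
independent gene-contribution components: after whitening, an orthogonal
rotation is sought that maximizes non-Gaussianity under a smoothed-density
contrast (a tilted-Gaussian log-density fitted by penalized Poisson spline
regression, so the score function adapts to each component's distribution);
a logcosh fixed-point contrast is available as a fallback.  Components are
annotated by excess kurtosis and gene-set enrichment of their contribution
vectors, and reproducibility across random restarts is summarized by
greedy correlation clustering with a centrotype consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from ._log import get_logger
from .enrichment import gsea_collection
from .io import GeneSetCollection

log = get_logger("lrica")

__all__ = [
    "LowRankDecomposition",
    "ICADecomposition",
    "ComponentAnnotation",
    "rpca_decompose",
    "fit_ica",
    "component_kurtosis",
    "select_components",
    "orient_component",
    "stability_cluster",
    "amari_index",
]


@dataclass
class LowRankDecomposition:
    L: np.ndarray
    S: np.ndarray
    lam: float
    iterations: int
    converged: bool
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ICADecomposition:
    """Gene-contribution matrix and per-sample mixing of an ICA fit.

    ``contributions`` columns have unit variance (fixed scaling convention);
    ``mixing`` maps samples to component scores so that
    ``L_centered ~ contributions @ mixing.T``.
    """

    contributions: pd.DataFrame  # genes x components
    mixing: pd.DataFrame         # samples x components
    n_components: int
    restart_stability: np.ndarray

    @property
    def gene_ids(self) -> list[str]:
        return list(self.contributions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mixing.index)


@dataclass
class ComponentAnnotation:
    component_index: int
    excess_kurtosis: float
    enrichments: list[tuple[str, float, float]]  # (set, NES, FDR)
    orientation: int = 1
    label: str = ""
    selected: bool = False


# ---------------------------------------------------------------------------
# robust PCA (principal component pursuit, inexact ALM)


def _svd_shrink(X: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep], float(s.sum())


def rpca_decompose(
    M: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> LowRankDecomposition:
    """Split ``M`` into low-rank L plus sparse S by principal component pursuit.

    ``lam`` defaults to ``1/sqrt(max(n, m))``.  Convergence is declared when
    ``||M - L - S||_F / ||M||_F <= tol``; non-convergence within ``max_iter``
    returns the current iterate with ``converged=False`` and a warning.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or min(M.shape) < 2:
        raise ValueError("RPCA needs a 2-D matrix with >= 2 rows and columns")
    if not np.isfinite(M).all():
        raise ValueError("RPCA input must be finite")
    if lam is None:
        lam = 1.0 / np.sqrt(max(M.shape))
    if lam <= 0:
        raise ValueError("lambda must be positive")
    norm_f = np.linalg.norm(M)
    if norm_f == 0:
        return LowRankDecomposition(
            np.zeros_like(M), np.zeros_like(M), lam, 0, True
        )
    norm_2 = np.linalg.norm(M, 2)
    mu = 1.25 / norm_2
    rho = 1.5
    Y = M / max(norm_2, np.abs(M).max() / lam)
    S = np.zeros_like(M)
    objective = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        L, nuclear = _svd_shrink(M - S + Y / mu, 1.0 / mu)
        S = M - L + Y / mu
        S = np.sign(S) * np.maximum(np.abs(S) - lam / mu, 0.0)
        Z = M - L - S
        Y = Y + mu * Z
        mu = min(mu * rho, 1e7 / norm_2)
        # merit of the feasible pair (L, M - L): an upper bound on the
        # constrained optimum that decreases monotonically along the iteration
        objective.append(nuclear + lam * np.abs(M - L).sum())
        if np.linalg.norm(Z) / norm_f <= tol:
            converged = True
            break
    if not converged:
        log.warning("RPCA did not converge within %d iterations", max_iter)
    return LowRankDecomposition(L, S, lam, it, converged, np.asarray(objective))


# ---------------------------------------------------------------------------
# smoothed-density contrast


def _spline_log_density_score(
    s: np.ndarray, n_grid: int = 120, n_basis: int = 30, lam: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Score psi = (log f)' and psi' at the data, for f = phi * exp(g).

    g is a cubic B-spline fitted to binned counts by penalized Poisson
    regression (second-difference penalty, default lambda = n**(1/3)); the
    Gaussian carrier makes the fitted density integrable with linear
    log-density tails, so the score is well behaved where data are sparse.
    """
    n = len(s)
    lo, hi = s.min(), s.max()
    pad = 0.1 * (hi - lo) + 1e-12
    a, b = lo - pad, hi + pad
    edges = np.linspace(a, b, n_grid + 1)
    t = 0.5 * (edges[:-1] + edges[1:])
    delta = edges[1] - edges[0]
    y = np.histogram(s, bins=edges)[0].astype(float)
    k = 3
    knots = np.concatenate([[a] * k, np.linspace(a, b, n_basis - k + 1), [b] * k])
    B = BSpline.design_matrix(t, knots, k).toarray()
    D = np.diff(np.eye(B.shape[1]), 2, axis=0)
    P = D.T @ D
    if lam is None:
        lam = float(n) ** (1.0 / 3.0)
    offset = np.log(n * delta) - 0.5 * t**2 - 0.5 * np.log(2 * np.pi)
    beta = np.zeros(B.shape[1])
    for _ in range(40):
        eta = offset + B @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        z = (B @ beta) + (y - mu) / np.maximum(mu, 1e-10)
        H = (B.T * mu) @ B + lam * P
        beta_new = np.linalg.solve(H, B.T @ (mu * z))
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    g = BSpline(knots, beta, k)
    sc = np.clip(s, a, b)
    return -sc + g(sc, 1), -1.0 + g(sc, 2)


def _logcosh_score(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.tanh(s)
    return t, 1.0 - t**2


_CONTRASTS = {"spline": _spline_log_density_score, "logcosh": _logcosh_score}


def _ica_rotation(
    Z: np.ndarray, n_comp: int, rng: np.random.Generator,
    contrast: str, max_iter: int, tol: float,
) -> np.ndarray:
    """Fixed-point search for the orthogonal unmixing rotation on whitened Z.

    The smoothed-density contrast is applied as a two-stage estimator: a
    robust logcosh fixed point locates the separating rotation globally,
    then the adaptive spline score refines it.  Refinement recovers the
    efficiency of a density-adapted score while avoiding the spurious
    attractors a data-driven score can create for spike-at-zero sources.
    """
    W = np.linalg.qr(rng.normal(size=(n_comp, n_comp)))[0]
    stages = ["logcosh"] if contrast == "logcosh" else ["logcosh", "spline"]
    for stage in stages:
        W = _fixed_point(Z, W, _CONTRASTS[stage], max_iter, tol)
    return W


def _fixed_point(
    Z: np.ndarray, W: np.ndarray, score, max_iter: int, tol: float
) -> np.ndarray:
    n, n_comp = Z.shape[0], W.shape[0]
    for _ in range(max_iter):
        S = Z @ W.T
        S = S / np.maximum(S.std(axis=0), 1e-12)
        G = np.empty_like(W)
        beta = np.empty(n_comp)
        for c in range(n_comp):
            psi, dpsi = score(S[:, c])
            G[c] = psi @ Z / n
            beta[c] = dpsi.mean()
        W1 = G - beta[:, None] * W
        u, _, vt = np.linalg.svd(W1)
        W1 = u @ vt
        delta = np.max(np.abs(np.abs((W1 * W).sum(axis=1)) - 1.0))
        W = W1
        if delta < tol:
            break
    return W


def _n_components_80pct(d: np.ndarray) -> int:
    var = d**2
    frac = np.cumsum(var) / var.sum()
    return int(np.searchsorted(frac, 0.80) + 1)


def fit_ica(
    L: np.ndarray | pd.DataFrame,
    n_components: int | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    contrast: str = "spline",
    max_iter: int = 200,
    tol: float = 1e-6,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> ICADecomposition:
    """ICA of a genes x samples matrix into gene-space components.

    Rows (genes) are the observations; each sample profile is modeled as a
    mixture of independent gene-contribution sources.  ``n_components``
    defaults to the number of principal components explaining 80% of the
    variance of L.  Restart ``r`` is seeded with ``seed + r`` and restarts
    are aggregated by :func:`stability_cluster`.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    if isinstance(L, pd.DataFrame):
        gene_ids = gene_ids or list(L.index)
        sample_ids = sample_ids or list(L.columns)
        L = L.to_numpy(dtype=float)
    L = np.asarray(L, dtype=float)
    n_genes, n_samples = L.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]

    X = L - L.mean(axis=0, keepdims=True)
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(d > d[0] * max(n_genes, n_samples) * np.finfo(float).eps))
    if n_components is None:
        n_components = max(2, min(_n_components_80pct(d[:rank]), rank))
    if n_components > min(n_genes, n_samples):
        raise ValueError("n_components exceeds matrix dimensions")
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds numerical rank {rank}"
        )
    # whitening: Z = X @ K.T has identity covariance over genes
    K = (Vt[:n_components] / d[:n_components, None]) * np.sqrt(n_genes)
    Z = X @ K.T

    runs = []
    for r in range(max(1, n_restarts)):
        rng = np.random.default_rng(seed + r)
        W = _ica_rotation(Z, n_components, rng, contrast, max_iter, tol)
        contrib = Z @ W.T  # genes x components, unit variance by construction
        contrib = contrib / np.maximum(contrib.std(axis=0), 1e-12)
        mix = np.linalg.lstsq(contrib, X, rcond=None)[0].T  # samples x comps
        runs.append(
            ICADecomposition(
                pd.DataFrame(contrib, index=gene_ids),
                pd.DataFrame(mix, index=sample_ids),
                n_components,
                np.ones(n_components),
            )
        )
    return stability_cluster(runs)


def component_kurtosis(scores: np.ndarray) -> float:
    """Excess kurtosis: fourth standardized central moment minus 3
    (population definition)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 4:
        raise ValueError("kurtosis needs at least 4 values")
    x = x - x.mean()
    var = np.mean(x**2)
    if var == 0:
        raise ValueError("zero variance; kurtosis undefined")
    return float(np.mean(x**4) / var**2 - 3.0)


def select_components(
    decomp: ICADecomposition,
    gene_sets: GeneSetCollection,
    kurtosis_min: float = 3.0,
    fdr_max: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[ComponentAnnotation]:
    """Annotate components; select those that are both heavy-tailed and
    biologically enriched.

    A component is selected iff ``|excess kurtosis| >= kurtosis_min`` and at
    least one gene set reaches ``FDR <= fdr_max`` in pre-ranked enrichment of
    its contribution vector.
    """
    if len(gene_sets) == 0:
        raise ValueError("empty gene-set collection")
    universe = set(decomp.gene_ids)
    if not any(g in universe for members in gene_sets.sets.values() for g in members):
        raise ValueError("no overlap between gene sets and decomposition genes")
    annotations = []
    for c in range(decomp.n_components):
        contrib = decomp.contributions.iloc[:, c]
        kurt = component_kurtosis(contrib.to_numpy())
        enr: list[tuple[str, float, float]] = []
        if abs(kurt) >= kurtosis_min:
            results = gsea_collection(
                contrib, gene_sets, n_perm=n_perm, seed=seed + 7919 * c
            )
            enr = [(r.set_name, r.NES, r.fdr) for r in results]
        selected = abs(kurt) >= kurtosis_min and any(q <= fdr_max for _, _, q in enr)
        annotations.append(
            ComponentAnnotation(c, kurt, enr, selected=selected)
        )
        log.info(
            "component %d: kurtosis=%.2f selected=%s", c, kurt, selected
        )
    return annotations


def orient_component(
    annotation: ComponentAnnotation,
    reference_set: list[str],
    decomp: ICADecomposition,
    weight_p: float = 1.0,
) -> ComponentAnnotation:
    """Flip a component's sign so the reference set's enrichment is positive.

    Negation is applied in place to the decomposition's contribution and
    mixing columns; the annotation records the resulting orientation.
    Applying the operation twice equals applying it once.
    """
    from .enrichment import _running_es, _sorted_ranking

    c = annotation.component_index
    contrib = decomp.contributions.iloc[:, c]
    s = _sorted_ranking(contrib)
    members = [g for g in reference_set if g in set(s.index)]
    if not members:
        raise ValueError("reference set has no gene in the decomposition")
    ap = np.abs(s.to_numpy()) ** weight_p
    hits = np.isin(s.index, members).astype(float)
    es, _ = _running_es(ap, hits)
    if es == 0:
        log.warning("reference-set ES is zero; orientation left at +1")
        return replace(annotation, orientation=1)
    if es < 0:
        decomp.contributions.iloc[:, c] *= -1.0
        decomp.mixing.iloc[:, c] *= -1.0
        flipped = [(name, -nes, q) for name, nes, q in annotation.enrichments]
        return replace(annotation, orientation=-annotation.orientation or -1,
                       enrichments=flipped)
    return replace(annotation, orientation=annotation.orientation or 1)


def stability_cluster(
    restart_decomps: list[ICADecomposition],
    min_similarity: float = 0.0,
) -> ICADecomposition:
    """Aggregate ICA restarts by greedy |correlation| matching.

    Components are matched across restarts to the first restart's components
    by maximal absolute Pearson correlation of contribution vectors (greedy
    assignment, ties broken by component index).  The consensus component is
    the centrotype — the member with the highest mean within-cluster |r| —
    and ``restart_stability`` is that mean.  Clusters below
    ``min_similarity`` are kept but logged.
    """
    if len(restart_decomps) < 2:
        out = restart_decomps[0]
        out.restart_stability = np.ones(out.n_components)
        return out
    k = restart_decomps[0].n_components
    if any(d.n_components != k for d in restart_decomps):
        raise ValueError("restarts have differing component counts")
    ref = restart_decomps[0]
    clusters: list[list[tuple[int, int]]] = [[(0, c)] for c in range(k)]
    for r, dec in enumerate(restart_decomps[1:], start=1):
        C = np.abs(np.corrcoef(
            ref.contributions.to_numpy().T, dec.contributions.to_numpy().T
        )[:k, k:])
        taken_ref: set[int] = set()
        taken_new: set[int] = set()
        # greedy: repeatedly take the largest remaining correlation
        order = np.dstack(np.unravel_index(np.argsort(-C, axis=None), C.shape))[0]
        for i, j in order:
            if i in taken_ref or j in taken_new:
                continue
            clusters[i].append((r, int(j)))
            taken_ref.add(int(i))
            taken_new.add(int(j))
            if len(taken_ref) == k:
                break

    members_mat = []
    stability = np.empty(k)
    centro_cols = []
    for ci, cluster in enumerate(clusters):
        vecs = np.column_stack([
            restart_decomps[r].contributions.iloc[:, j].to_numpy()
            for r, j in cluster
        ])
        A = np.abs(np.corrcoef(vecs.T))
        mean_r = (A.sum(axis=1) - 1.0) / max(len(cluster) - 1, 1)
        best = int(np.argmax(mean_r))
        stability[ci] = float(mean_r.mean()) if len(cluster) > 1 else 1.0
        if stability[ci] < min_similarity:
            log.warning("component cluster %d stability %.3f below %.3f",
                        ci, stability[ci], min_similarity)
        r_best, j_best = cluster[best]
        centro_cols.append((r_best, j_best))
        members_mat.append(vecs)

    contrib = pd.DataFrame(
        np.column_stack([
            restart_decomps[r].contributions.iloc[:, j].to_numpy()
            for r, j in centro_cols
        ]),
        index=ref.gene_ids,
    )
    mixing = pd.DataFrame(
        np.column_stack([
            restart_decomps[r].mixing.iloc[:, j].to_numpy()
            for r, j in centro_cols
        ]),
        index=ref.sample_ids,
    )
    return ICADecomposition(contrib, mixing, k, stability)


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Permutation/scale-invariant distance between unmixing W and mixing A.

    Zero when ``W @ A`` is a scaled permutation; normalized to [0, 1].
    """
    P = np.abs(np.asarray(W) @ np.asarray(A))
    m = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("Amari index needs square W @ A")
    r = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    c = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((r.sum() + c.sum()) / (2 * m * (m - 1)))
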