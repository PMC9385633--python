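"""Pre-ranked gene-set enrichment and the two-tailed regulon variant.

The enrichment statistic is the classic weighted Kolmogorov-Smirnov running
sum: walking down the ranking, hits increment the sum proportionally to
``|score|**weight_p`` (normalized to 1 over the set) and misses decrement it
uniformly; the enrichment score (ES) is the signed extreme deviation.
Significance comes from gene-label permutation (random sets of the same
size), with the normalized score NES = ES / mean(|ES*|) over same-sign
permutation scores, and Benjamini-Hochberg FDR across a collection.

The two-tailed variant scores a regulon's positively and negatively
regulated targets separately and reports dES = ES+ - ES-, the weight a
master regulator carries in the gradient: a regulator whose activated
targets sit at the top of the ranking and whose repressed targets sit at the
bottom approaches dES = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._log import get_logger

if TYPE_CHECKING:  # pragma: no cover
    from .io import GeneSetCollection
    from .regnet import Regulon

log = get_logger("enrichment")

__all__ = [
    "EnrichmentResult",
    "TwoTailResult",
    "preranked_gsea",
    "gsea_collection",
    "gsea2t_des",
    "bh_fdr",
]


@dataclass
class EnrichmentResult:
    set_name: str
    ES: float
    NES: float
    p_value: float
    fdr: float
    leading_edge: list[str]
    n_hits: int = 0


@dataclass
class TwoTailResult:
    regulator: str
    ES_pos: float
    ES_neg: float
    dES: float
    one_sided: bool = False  # set when one mode had no targets in the ranking


def _sorted_ranking(ranking: Mapping[str, float] | pd.Series) -> pd.Series:
    s = pd.Series(ranking, dtype=float)
    if s.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    if s.nunique() <= 1:
        raise ValueError("all ranking scores equal; no ranking exists")
    # descending by score, ties broken by stable gene-id order
    s = s.sort_index(kind="mergesort")
    return s.sort_values(ascending=False, kind="mergesort")


def _running_es(
    abs_scores_p: np.ndarray, hits: np.ndarray
) -> tuple[float, int]:
    """Signed extreme of the running sum; returns (ES, argmax position)."""
    n = len(hits)
    n_hit = int(hits.sum())
    hit_w = abs_scores_p * hits
    if hit_w.sum() == 0:
        # all hit scores are zero under this weighting; fall back to equal hits
        hit_w = hits.astype(float)
    ch = np.cumsum(hit_w)
    # dividing by the final cumulative value keeps the running sum exactly 1
    # at the last hit when the whole set leads the ranking
    run = ch / ch[-1] - np.cumsum(1.0 - hits) / (n - n_hit)
    imax = int(np.argmax(run))
    imin = int(np.argmin(run))
    if abs(run[imax]) >= abs(run[imin]):
        return float(run[imax]), imax
    return float(run[imin]), imin


def _es_many(abs_scores_p: np.ndarray, hit_matrix: np.ndarray) -> np.ndarray:
    """Vectorized ES for many same-size sets (rows of ``hit_matrix``)."""
    n = abs_scores_p.shape[0]
    n_hit = hit_matrix[0].sum()
    hw = abs_scores_p[None, :] * hit_matrix
    ch = np.cumsum(hw, axis=1)
    denom = ch[:, -1:].copy()
    denom[denom == 0] = 1.0
    run = ch / denom - np.cumsum(1.0 - hit_matrix, axis=1) / (n - n_hit)
    hi = run.max(axis=1)
    lo = run.min(axis=1)
    return np.where(np.abs(hi) >= np.abs(lo), hi, lo)


def preranked_gsea(
    ranking: Mapping[str, float] | pd.Series,
    gene_set: list[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "set",
) -> EnrichmentResult:
    """Weighted-KS enrichment of ``gene_set`` in a pre-ranked list.

    NES normalizes ES by the mean |ES*| of same-sign gene-label permutation
    scores; the permutation null also yields the p-value.  Deterministic
    under a fixed ``seed``.
    """
    s = _sorted_ranking(ranking)
    universe = s.index
    members = [g for g in dict.fromkeys(gene_set) if g in set(universe)]
    if not members:
        raise ValueError(f"gene set {set_name!r} has no member in the ranking")
    if len(members) >= len(universe):
        raise ValueError(
            f"gene set {set_name!r} covers the whole ranked universe; "
            "enrichment is undefined"
        )
    ap = np.abs(s.to_numpy()) ** weight_p
    hits = np.isin(universe, members).astype(float)
    es, iext = _running_es(ap, hits)

    rng = np.random.default_rng(seed)
    k = len(members)
    n = len(universe)
    es_null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e6 // max(n, 1)) or 1))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        hm = np.zeros((m, n))
        for r in range(m):
            hm[r, rng.choice(n, size=k, replace=False)] = 1.0
        es_null[done:done + m] = _es_many(ap, hm)
        done += m
    if es >= 0:
        same = es_null[es_null >= 0]
        p = (1.0 + np.sum(same >= es)) / (1.0 + len(same))
        nes = es / same.mean() if len(same) else np.nan
    else:
        same = es_null[es_null < 0]
        p = (1.0 + np.sum(same <= es)) / (1.0 + len(same))
        nes = es / np.abs(same).mean() if len(same) else np.nan

    if es >= 0:
        leading = [g for g in universe[: iext + 1] if g in set(members)]
    else:
        leading = [g for g in universe[iext:] if g in set(members)]
    return EnrichmentResult(
        set_name=set_name, ES=es, NES=float(nes), p_value=float(p),
        fdr=float(p), leading_edge=leading, n_hits=k,
    )


def gsea_collection(
    ranking: Mapping[str, float] | pd.Series,
    collection: "GeneSetCollection",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 2,
) -> list[EnrichmentResult]:
    """Run pre-ranked enrichment for every set and apply BH FDR across sets."""
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    results = []
    universe = set(pd.Series(ranking, dtype=float).index)
    for i, (name, members) in enumerate(sorted(collection.sets.items())):
        present = [g for g in members if g in universe]
        if len(present) < min_size or len(present) >= len(universe):
            log.debug("skipping gene set %s (%d usable members)", name, len(present))
            continue
        results.append(
            preranked_gsea(ranking, present, weight_p=weight_p,
                           n_perm=n_perm, seed=seed + i, set_name=name)
        )
    if not results:
        raise ValueError("no gene set overlaps the ranked universe")
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.fdr = float(q)
    return results


def gsea2t_des(
    ranking: Mapping[str, float] | pd.Series,
    regulon: "Regulon",
    weight_p: float = 1.0,
) -> TwoTailResult:
    """Two-tailed regulon enrichment: dES = ES(positive) - ES(negative).

    If one mode has no target in the ranking the result is computed one-sided
    (dES is the present mode's ES, sign-adjusted) and flagged.
    """
    s = _sorted_ranking(ranking)
    universe = set(s.index)
    pos = [g for g, _, m in regulon.targets if m > 0 and g in universe]
    neg = [g for g, _, m in regulon.targets if m < 0 and g in universe]
    if not pos and not neg:
        raise ValueError(
            f"regulon {regulon.regulator!r} has no target in the ranking"
        )
    ap = np.abs(s.to_numpy()) ** weight_p
    idx = s.index

    def _es(members: list[str]) -> float:
        hits = np.isin(idx, members).astype(float)
        return _running_es(ap, hits)[0]

    if pos and neg:
        es_pos = _es(pos)
        es_neg = _es(neg)
        return TwoTailResult(regulon.regulator, es_pos, es_neg, es_pos - es_neg)
    log.warning(
        "regulon %s: only %s-mode targets in ranking; one-sided dES",
        regulon.regulator, "positive" if pos else "negative",
    )
    if pos:
        es_pos = _es(pos)
        return TwoTailResult(regulon.regulator, es_pos, np.nan, es_pos, one_sided=True)
    es_neg = _es(neg)
    return TwoTailResult(regulon.regulator, np.nan, es_neg, -es_neg, one_sided=True)


def bh_fdr(p_values: list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
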