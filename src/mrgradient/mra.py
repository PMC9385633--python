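"""Master-regulator analysis.

A component's target set is the genes with outlying loadings (beyond
``sd_mult`` standard deviations of the contribution vector).  Each regulon
is tested for overlap with that set by a one-sided hypergeometric tail, and
weighted by the two-tailed enrichment score dES of its signed targets along
the component ranking.  Regulators pass selection when the enrichment p is
below ``p_max`` (default 0.01) and ``|dES|`` is at least ``des_min``
(default 1), the thresholds used to assemble the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._log import get_logger
from .enrichment import gsea2t_des
from .regnet import RegulatoryNetwork, Regulon

log = get_logger("mra")

__all__ = [
    "MasterRegulator",
    "high_contribution_genes",
    "regulon_enrichment_test",
    "select_master_regulators",
    "master_regulator_analysis",
]


@dataclass
class MasterRegulator:
    regulator: str
    component: str
    enrichment_p: float
    dES: float
    selected: bool


def high_contribution_genes(
    contributions: pd.Series, sd_mult: float = 2.0
) -> set[str]:
    """Genes whose loading deviates from the mean by more than
    ``sd_mult`` standard deviations."""
    x = contributions.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 loadings")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance loadings")
    mask = np.abs(x - x.mean()) > sd_mult * sd
    return set(contributions.index[mask])


def regulon_enrichment_test(
    regulon: Regulon, target_set: set[str], universe: list[str]
) -> float:
    """One-sided hypergeometric tail P(overlap >= observed)."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not target_set:
        raise ValueError("empty target set")
    targets = {g for g, _, _ in regulon.targets} & uni
    tset = target_set & uni
    overlap = len(targets & tset)
    return float(hypergeom.sf(overlap - 1, len(uni), len(targets), len(tset)))


def select_master_regulators(
    tests: list[MasterRegulator],
    p_max: float = 0.01,
    des_min: float = 1.0,
) -> list[MasterRegulator]:
    """Keep regulators with ``p < p_max`` and ``|dES| >= des_min``,
    sorted by |dES| descending."""
    out = []
    for mr in tests:
        if not 0 < mr.enrichment_p <= 1:
            raise ValueError(f"p-value out of (0,1] for {mr.regulator!r}")
        sel = mr.enrichment_p < p_max and abs(mr.dES) >= des_min
        out.append(MasterRegulator(mr.regulator, mr.component,
                                   mr.enrichment_p, mr.dES, sel))
    out.sort(key=lambda m: (-abs(m.dES), m.regulator))
    return [m for m in out if m.selected]


def master_regulator_analysis(
    network: RegulatoryNetwork,
    contributions: pd.Series,
    component_name: str,
    sd_mult: float = 2.0,
    p_max: float = 0.01,
    des_min: float = 1.0,
    weight_p: float = 1.0,
) -> tuple[list[MasterRegulator], list[MasterRegulator]]:
    """Full analysis of one component: returns (selected, all tested).

    The component contribution vector supplies both the outlier target set
    (hypergeometric test) and the ranking on which each regulon's two-tailed
    dES is computed.
    """
    target_set = high_contribution_genes(contributions, sd_mult)
    if not target_set:
        raise ValueError("no high-contribution genes at this sd threshold")
    universe = list(contributions.index)
    tested = []
    for reg in network.regulons:
        p = regulon_enrichment_test(reg, target_set, universe)
        try:
            des = gsea2t_des(contributions, reg, weight_p=weight_p).dES
        except ValueError:
            log.warning("regulon %s has no target in ranking; skipped",
                        reg.regulator)
            continue
        tested.append(MasterRegulator(reg.regulator, component_name, p, des, False))
    selected = select_master_regulators(tested, p_max=p_max, des_min=des_min)
    chosen = {m.regulator for m in selected}
    for m in tested:
        m.selected = m.regulator in chosen
    log.info("component %s: %d / %d regulators selected as MRs",
             component_name, len(selected), len(tested))
    return selected, tested
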