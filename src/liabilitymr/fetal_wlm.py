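"""Adjustment of maternal SNP-outcome associations for fetal genotype.

A maternal variant is transmitted to the fetus with probability 1/2, so a
marginal maternal GWAS effect M mixes the direct maternal effect a with
half of any direct fetal effect b, and vice versa for the marginal fetal
GWAS effect F:

    M = a + b/2,    F = b + a/2.

Solving for the direct maternal effect gives the weighted linear model

    a = (4M − 2F) / 3,
    var(a) = (16 var(M) + 4 var(F) − 16 cov(M, F)) / 9,

with cov(M, F) = 0 when the two GWAS come from independent samples.  The
coefficient set is isolated in ``WLM_COEFFICIENTS`` so an alternative
weighting can be swapped in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .estimators import MRResult, InsufficientInstrumentsError, ivw
from .harmonize import HarmonizedSet

logger = logging.getLogger(__name__)

#: (c_m, c_f, denom): a = (c_m * M + c_f * F) / denom.
WLM_COEFFICIENTS = (4.0, -2.0, 3.0)


@dataclass(frozen=True)
class DuoAssociation:
    """Marginal maternal (M) and fetal (F) GWAS effects for one variant."""

    rsid: str
    beta_maternal_marginal: float
    se_m: float
    beta_fetal_marginal: float
    se_f: float
    cov_mf: float = 0.0

    def __post_init__(self) -> None:
        if not (self.se_m > 0 and self.se_f > 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


@dataclass(frozen=True)
class AdjustedAssociation:
    """Direct maternal effect after removing the fetal contribution."""

    rsid: str
    beta_maternal_direct: float
    se_a: float

    def __post_init__(self) -> None:
        if not (self.se_a > 0):
            raise ValueError(f"{self.rsid}: se_a must be > 0")


def wlm_adjust(
    duo: DuoAssociation,
    coefficients: tuple[float, float, float] = WLM_COEFFICIENTS,
) -> AdjustedAssociation:
    """Solve the transmission model for the direct maternal effect."""
    c_m, c_f, denom = coefficients
    a = (c_m * duo.beta_maternal_marginal + c_f * duo.beta_fetal_marginal) / denom
    var_a = (
        c_m**2 * duo.se_m**2
        + c_f**2 * duo.se_f**2
        + 2.0 * c_m * c_f * duo.cov_mf
    ) / denom**2
    if var_a <= 0:
        raise ValueError(
            f"{duo.rsid}: non-positive adjusted variance; check cov_mf = {duo.cov_mf}"
        )
    return AdjustedAssociation(rsid=duo.rsid, beta_maternal_direct=a, se_a=math.sqrt(var_a))


def mr_with_fetal_adjustment(
    pairs: HarmonizedSet,
    duos: Iterable[DuoAssociation] | Mapping[str, DuoAssociation],
) -> MRResult:
    """IVW on WLM-adjusted outcome associations.

    Each covered SNP's (beta_out, se_out) is replaced by the fetal-adjusted
    direct maternal effect; instruments without a duo record are dropped
    with a logged count.  Needs >= 2 covered SNPs.
    """
    duo_map = duos if isinstance(duos, Mapping) else {d.rsid: d for d in duos}
    adjusted = []
    dropped = 0
    for p in pairs:
        duo = duo_map.get(p.rsid)
        if duo is None:
            dropped += 1
            continue
        adj = wlm_adjust(duo)
        adjusted.append(replace(p, beta_out=adj.beta_maternal_direct, se_out=adj.se_a))
    if dropped:
        logger.info(
            "%s-%s: dropped %d instrument(s) without fetal-duo coverage",
            pairs.condition_id,
            pairs.outcome_id,
            dropped,
        )
    if len(adjusted) < 2:
        raise InsufficientInstrumentsError(
            f"fetal adjustment needs >= 2 covered SNPs, got {len(adjusted)}"
        )
    subset = HarmonizedSet(
        condition_id=pairs.condition_id,
        outcome_id=pairs.outcome_id,
        pairs=adjusted,
        outcome_binary=pairs.outcome_binary,
    )
    result = ivw(subset)
    return replace(result, note="fetal-adjusted")
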