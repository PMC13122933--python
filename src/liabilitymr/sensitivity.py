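"""Sensitivity loops around the main IVW analysis.

Four families of checks probe the instrumental-variable assumptions:

* **Steiger filtering** removes instruments that explain significantly more
  variance in the outcome than in the exposure (evidence the variant's
  primary phenotype is the outcome, i.e. potential reverse causation).
* **Leave-one-SNP-out** re-estimates after omitting each instrument in turn
  to expose single-variant leverage.
* **Leave-one-study-out** re-meta-analyzes the outcome association across
  the remaining contributing studies before re-estimating, exposing
  single-cohort leverage.
* **HLA exclusion** reruns without variants in the long-range-LD,
  highly pleiotropic HLA region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .estimators import InsufficientInstrumentsError, MRResult, ivw, wald_ratio
from .harmonize import HarmonizedPair, HarmonizedSet, harmonize
from .instruments import HLA_REGION, InstrumentSet, _norm_chrom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SteigerRecord:
    """Per-SNP directionality audit: variance explained on each side."""

    rsid: str
    r2_exp: float | None
    r2_out: float | None
    direction_ok: bool
    steiger_pval: float | None
    evaluable: bool = True
    removed: bool = False

    def __post_init__(self) -> None:
        for r2 in (self.r2_exp, self.r2_out):
            if r2 is not None and not (0 <= r2 < 1):
                raise ValueError("r2 must lie in [0, 1)")


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Result after omitting one SNP or one study."""

    omitted_id: str
    result: MRResult
    delta_vs_full: float
    influential: bool = False


def _z_to_r(z: float, n: float) -> float:
    """Correlation implied by a z-statistic at sample size n: r = z/sqrt(z²+n)."""
    return z / math.sqrt(z * z + n)


def steiger_filter(
    pairs: HarmonizedSet,
    alpha: float = 0.05,
) -> tuple[HarmonizedSet, list[SteigerRecord]]:
    """Remove instruments explaining significantly more outcome than exposure variance.

    Per SNP, each side's trait correlation is proxied by r = z/sqrt(z² + n)
    from that side's z = beta/se; the SNP is removed iff r²_out > r²_exp
    *and* the one-sided two-sample Fisher-z comparison,
    z = (atanh(r_exp) − atanh(r_out)) / sqrt(1/(n_exp−3) + 1/(n_out−3)),
    is significant at ``alpha``.  SNPs whose sample sizes are missing or
    <= 3 on either side are retained and flagged unevaluable.
    """
    records: list[SteigerRecord] = []
    kept_rsids: list[str] = []
    for p in pairs:
        if p.n_exp is None or p.n_out is None or p.n_exp <= 3 or p.n_out <= 3:
            logger.warning("%s: Steiger unevaluable (missing or tiny n); retained", p.rsid)
            records.append(
                SteigerRecord(p.rsid, None, None, direction_ok=True,
                              steiger_pval=None, evaluable=False)
            )
            kept_rsids.append(p.rsid)
            continue
        r_exp = _z_to_r(p.beta_exp / p.se_exp, p.n_exp)
        r_out = _z_to_r(p.beta_out / p.se_out, p.n_out)
        r2_exp, r2_out = r_exp**2, r_out**2
        z = (math.atanh(abs(r_exp)) - math.atanh(abs(r_out))) / math.sqrt(
            1.0 / (p.n_exp - 3) + 1.0 / (p.n_out - 3)
        )
        # One-sided p for the wrong direction (outcome variance exceeding
        # exposure variance); small when the exposure side is clearly weaker.
        pval = float(stats.norm.cdf(z))
        direction_ok = r2_exp >= r2_out
        removed = (not direction_ok) and pval < alpha
        records.append(
            SteigerRecord(p.rsid, r2_exp, r2_out, direction_ok, pval, removed=removed)
        )
        if not removed:
            kept_rsids.append(p.rsid)
    return pairs.subset(kept_rsids), records


def steiger_filtered_estimate(
    pairs: HarmonizedSet,
    alpha: float = 0.05,
) -> tuple[MRResult | None, list[SteigerRecord]]:
    """Steiger-filter then re-estimate: IVW with >= 2 SNPs, Wald ratio with 1."""
    filtered, records = steiger_filter(pairs, alpha=alpha)
    if filtered.n_snp >= 2:
        return ivw(filtered), records
    if filtered.n_snp == 1:
        return (
            wald_ratio(filtered.pairs[0], filtered.condition_id, filtered.outcome_id,
                       binary_outcome=filtered.outcome_binary),
            records,
        )
    return None, records


def leave_one_snp_out(
    pairs: HarmonizedSet,
    influence_fraction: float = 0.5,
) -> list[LeaveOneOutResult]:
    """IVW after omitting each SNP in turn.

    A SNP is flagged influential when its omission flips the sign of the
    estimate or shifts it by more than ``influence_fraction`` of the
    full-set magnitude.
    """
    if pairs.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-SNP-out needs >= 3 instruments, got {pairs.n_snp}"
        )
    full = ivw(pairs)
    out: list[LeaveOneOutResult] = []
    for omit in [p.rsid for p in pairs]:
        sub = pairs.subset([p.rsid for p in pairs if p.rsid != omit])
        res = ivw(sub) if sub.n_snp >= 2 else wald_ratio(
            sub.pairs[0], sub.condition_id, sub.outcome_id,
            binary_outcome=sub.outcome_binary,
        )
        delta = res.beta - full.beta
        sign_flip = np.sign(res.beta) != np.sign(full.beta) and full.beta != 0
        big_shift = abs(delta) > influence_fraction * abs(full.beta)
        out.append(
            LeaveOneOutResult(
                omitted_id=omit,
                result=res,
                delta_vs_full=delta,
                influential=bool(sign_flip or big_shift),
            )
        )
    return out


def fixed_effect_meta(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Fixed-effect inverse-variance meta-analysis of one SNP across studies."""
    betas = np.asarray(betas, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    return float(np.sum(w * betas) / np.sum(w)), float(np.sum(w) ** -0.5)


def pool_studies(
    per_study_outcomes: Mapping[str, "SummaryDataset"],
    exposure_instruments: InstrumentSet,
    omit: str | None = None,
    outcome_id: str | None = None,
    palindromic_maf_threshold: float = 0.42,
) -> HarmonizedSet:
    """Harmonize each study to the instruments, then meta-analyze per SNP.

    SNPs covered by no retained study are dropped.  ``omit`` removes one
    study before pooling (the leave-one-study-out replicate).
    """
    labels = [s for s in per_study_outcomes if s != omit]
    if not labels:
        raise ValueError("no studies left to pool")
    harmonized = {
        label: harmonize(
            exposure_instruments.to_dataset(),
            per_study_outcomes[label],
            condition_id=exposure_instruments.condition_id,
            palindromic_maf_threshold=palindromic_maf_threshold,
        )
        for label in labels
    }
    any_binary = any(
        per_study_outcomes[label].trait_type == "binary" for label in labels
    )
    outcome_id = outcome_id or per_study_outcomes[labels[0]].trait_id
    pairs: list[HarmonizedPair] = []
    for v in exposure_instruments:
        per_study = [
            hs_pair
            for label in labels
            for hs_pair in harmonized[label].pairs
            if hs_pair.rsid == v.rsid
        ]
        if not per_study:
            continue
        beta, se = fixed_effect_meta(
            [p.beta_out for p in per_study], [p.se_out for p in per_study]
        )
        template = per_study[0]
        n_out = sum(p.n_out for p in per_study if p.n_out is not None) or None
        pairs.append(
            HarmonizedPair(
                rsid=v.rsid,
                effect_allele=template.effect_allele,
                other_allele=template.other_allele,
                beta_exp=template.beta_exp,
                se_exp=template.se_exp,
                pval_exp=template.pval_exp,
                eaf_exp=template.eaf_exp,
                n_exp=template.n_exp,
                beta_out=beta,
                se_out=se,
                n_out=n_out,
                chrom=template.chrom,
                pos=template.pos,
                disposition=template.disposition,
            )
        )
    return HarmonizedSet(
        condition_id=exposure_instruments.condition_id,
        outcome_id=outcome_id,
        pairs=pairs,
        outcome_binary=any_binary,
    )


def leave_one_study_out(
    per_study_outcomes: Mapping[str, "SummaryDataset"],
    exposure_instruments: InstrumentSet,
    outcome_id: str | None = None,
) -> list[LeaveOneOutResult]:
    """Re-meta-analyze the outcome omitting each study in turn, then IVW."""
    if len(per_study_outcomes) < 2:
        raise ValueError("leave-one-study-out needs >= 2 studies")
    full_set = pool_studies(per_study_outcomes, exposure_instruments, outcome_id=outcome_id)
    full = ivw(full_set)
    out: list[LeaveOneOutResult] = []
    for label in per_study_outcomes:
        subset = pool_studies(
            per_study_outcomes, exposure_instruments, omit=label, outcome_id=outcome_id
        )
        if subset.n_snp >= 2:
            res = ivw(subset)
        elif subset.n_snp == 1:
            res = wald_ratio(subset.pairs[0], subset.condition_id, subset.outcome_id,
                             binary_outcome=subset.outcome_binary)
        else:
            continue
        out.append(
            LeaveOneOutResult(
                omitted_id=label, result=res, delta_vs_full=res.beta - full.beta
            )
        )
    return out


def rerun_without_hla(
    pairs: HarmonizedSet,
    region: tuple[str, int, int] = HLA_REGION,
) -> MRResult | None:
    """Re-estimate on the non-HLA subset; None when no non-HLA SNPs remain."""
    chrom, start, end = region
    chrom = _norm_chrom(chrom)
    keep = [
        p.rsid
        for p in pairs
        if not (
            p.chrom is not None
            and p.pos is not None
            and _norm_chrom(p.chrom) == chrom
            and start <= p.pos <= end
        )
    ]
    subset = pairs.subset(keep)
    if subset.n_snp >= 2:
        return ivw(subset)
    if subset.n_snp == 1:
        return wald_ratio(subset.pairs[0], subset.condition_id, subset.outcome_id,
                          binary_outcome=subset.outcome_binary)
    return None
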