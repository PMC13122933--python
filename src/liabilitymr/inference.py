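"""Result triage: follow-up selection, FDR under dependence, robustness tiers.

A condition-outcome estimate is selected for sensitivity follow-up when
either (i) p < 0.05, or (ii) the per-doubling odds ratio exceeds 1.05 or
falls below 0.95 with p < 0.10 — a two-tier rule reflecting that modest
effects on rare but clinically important outcomes matter even at looser
statistical support.  Multiple-testing correction across the analysis grid
uses the Benjamini–Yekutieli step-up procedure, which controls the false
discovery rate under arbitrary dependence (conditions share risk loci and
outcomes are correlated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .estimators import PER_DOUBLING, MRResult
from .sensitivity import LeaveOneOutResult


@dataclass(frozen=True)
class SelectionDecision:
    """Two-tier follow-up triage of one condition-outcome IVW estimate."""

    condition_id: str
    outcome_id: str
    or_scaled: float | None  # per-doubling odds ratio (binary outcomes)
    beta: float
    pval: float
    criterion_i: bool  # p < 0.05
    criterion_ii: bool  # OR > 1.05 or OR < 0.95, with p < 0.10
    by_adjusted_p: float
    passes_fdr: bool

    @property
    def selected(self) -> bool:
        return self.criterion_i or self.criterion_ii

    def __post_init__(self) -> None:
        if self.by_adjusted_p < self.pval - 1e-12:
            raise ValueError("BY-adjusted p cannot be below the raw p")


def by_fdr(
    pvals: Sequence[float],
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Yekutieli adjusted p-values and rejection flags.

    With c(m) = Σ 1/i and order statistics p_(1) <= ... <= p_(m), the raw
    adjusted value is p_(i)·m·c(m)/i, made monotone by a cumulative minimum
    from the largest rank down and capped at 1; rejections are adjusted
    values <= ``alpha``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("by_fdr needs at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_by")
    return adjusted, reject


def select_for_followup(
    results: Sequence[MRResult],
    alpha_fdr: float = 0.05,
    p_strict: float = 0.05,
    p_loose: float = 0.10,
    or_margin: float = 0.05,
) -> list[SelectionDecision]:
    """Apply the two-tier follow-up rule across a per-doubling result grid.

    All results must be on the per-doubling scale; the BY adjustment is
    computed over the full grid passed in (the multiple-testing family).
    Returns one decision per result, sorted by condition then outcome.
    """
    if not results:
        raise ValueError("no results to triage")
    if any(r.scale != PER_DOUBLING for r in results):
        raise ValueError("select_for_followup expects per-doubling results only")
    ordered = sorted(results, key=lambda r: (r.condition_id, r.outcome_id))
    adjusted, reject = by_fdr([r.pval for r in ordered], alpha=alpha_fdr)
    decisions = []
    for r, adj, rej in zip(ordered, adjusted, reject):
        odds = math.exp(r.beta) if r.binary_outcome else None
        crit_i = bool(r.pval < p_strict)
        crit_ii = bool(
            odds is not None
            and (odds > 1 + or_margin or odds < 1 - or_margin)
            and r.pval < p_loose
        )
        decisions.append(
            SelectionDecision(
                condition_id=r.condition_id,
                outcome_id=r.outcome_id,
                or_scaled=odds,
                beta=r.beta,
                pval=r.pval,
                criterion_i=crit_i,
                criterion_ii=crit_ii,
                by_adjusted_p=float(min(adj, 1.0)),
                passes_fdr=bool(rej),
            )
        )
    return decisions


@dataclass(frozen=True)
class RobustnessSummary:
    """Directional-concordance verdict across a pair's sensitivity bundle."""

    condition_id: str
    outcome_id: str
    tier: str  # "robust" | "uncertain"
    discordant: tuple[str, ...] = ()
    unevaluable: tuple[str, ...] = ()


def summarize_robustness(
    decision: SelectionDecision,
    sensitivity_bundle: Mapping[str, object],
) -> RobustnessSummary:
    """Tier a selected result by directional concordance of its sensitivity runs.

    The bundle maps analysis labels to an ``MRResult``, a list of results
    (e.g. leave-one-out replicates), or ``None`` for analyses that could
    not be run.  "robust" requires every available estimate to share the
    main estimate's direction; missing analyses are recorded as
    unevaluable, never as failures.  This codifies a narrative judgment as
    an explicit rule, so the tier is advisory.
    """
    if not sensitivity_bundle:
        raise ValueError("empty sensitivity bundle")
    main_sign = np.sign(decision.beta)
    discordant: list[str] = []
    unevaluable: list[str] = []
    for label, entry in sensitivity_bundle.items():
        if entry is None:
            unevaluable.append(label)
            continue
        results = entry if isinstance(entry, (list, tuple)) else [entry]
        if not results:
            unevaluable.append(label)
            continue
        for item in results:
            res = item.result if isinstance(item, LeaveOneOutResult) else item
            if np.sign(res.beta) != main_sign:
                discordant.append(label)
                break
    tier = "robust" if not discordant else "uncertain"
    return RobustnessSummary(
        condition_id=decision.condition_id,
        outcome_id=decision.outcome_id,
        tier=tier,
        discordant=tuple(discordant),
        unevaluable=tuple(unevaluable),
    )
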