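"""Core two-sample MR estimators on harmonized summary statistics.

Given per-variant exposure effects β_xj (se_xj) and outcome effects β_yj
(se_yj) aligned to the same allele, the causal effect θ of the exposure on
the outcome is estimated by:

* the Wald ratio β_yj / β_xj for a single instrument;
* the random-effects inverse-variance-weighted (IVW) mean of the Wald
  ratios, with first-order weights w_j = β_xj² / se_yj², Cochran's Q for
  heterogeneity, and a multiplicative overdispersion factor
  max(1, sqrt(Q / (k − 1))) inflating the fixed-effect standard error;
* MR-Egger: weighted least squares of β_yj on β_xj *with* an intercept,
  whose slope is robust to directional pleiotropy under the InSIDE
  assumption and whose intercept estimates the mean pleiotropic effect;
* the weighted median of the Wald ratios, consistent when instruments
  carrying at least half of the weight are valid.

Binary exposures put θ on a per-unit-log-odds liability scale;
``scale_to_doubling`` rescales estimates by ln 2 so they read as the effect
of doubling the odds of the exposure condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair, HarmonizedSet

LN2 = math.log(2.0)
Z95 = 1.96

PER_LOGODDS = "per_logodds"
PER_DOUBLING = "per_doubling"


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal estimate for one condition-outcome pair."""

    condition_id: str
    outcome_id: str
    method: str  # wald | ivw_re | egger | weighted_median
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    q: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    scale: str = PER_LOGODDS
    binary_outcome: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")
        if self.q is not None and self.q < -1e-12:
            raise ValueError("Q must be non-negative")
        if not (0 < self.pval <= 1):
            raise ValueError("pval must lie in (0, 1]")
        if self.scale not in (PER_LOGODDS, PER_DOUBLING):
            raise ValueError(f"unknown scale {self.scale!r}")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _norm_two_sided_p(z: float) -> float:
    p = 2.0 * stats.norm.sf(abs(z))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def _usable_pairs(pairs: HarmonizedSet) -> list[HarmonizedPair]:
    usable = [p for p in pairs if p.beta_exp != 0]
    n_zero = pairs.n_snp - len(usable)
    if n_zero:
        import logging

        logging.getLogger(__name__).warning(
            "%s-%s: excluded %d pair(s) with zero exposure effect",
            pairs.condition_id,
            pairs.outcome_id,
            n_zero,
        )
    return usable


def wald_ratio(pair: HarmonizedPair, condition_id: str = "", outcome_id: str = "",
               binary_outcome: bool = True) -> MRResult:
    """Single-instrument causal estimate β_y / β_x with first-order SE."""
    if pair.beta_exp == 0:
        raise ZeroDivisionError(f"{pair.rsid}: Wald ratio undefined for beta_exp = 0")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MRResult(
        condition_id=condition_id,
        outcome_id=outcome_id,
        method="wald",
        n_snp=1,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_norm_two_sided_p(beta / se),
        binary_outcome=binary_outcome,
    )


def ivw(pairs: HarmonizedSet) -> MRResult:
    """Multiplicative random-effects IVW estimate over >= 2 instruments.

    Weights are first-order: w_j = β_xj² / se_yj².  The point estimate is
    the weighted mean of the Wald ratios (equivalently the slope of a
    zero-intercept weighted regression of β_y on β_x); the fixed-effect SE
    (Σw)^(−1/2) is inflated by max(1, sqrt(Q/(k−1))).
    """
    usable = _usable_pairs(pairs)
    k = len(usable)
    if k < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments with nonzero exposure effect, got {k}; "
            "use wald_ratio for a single instrument"
        )
    bx = np.array([p.beta_exp for p in usable])
    by = np.array([p.beta_out for p in usable])
    sy = np.array([p.se_out for p in usable])
    theta = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5
    q = float(np.sum(w * (theta - beta) ** 2))
    q_df = k - 1
    q_pval = float(stats.chi2.sf(q, q_df))
    se = se_fixed * max(1.0, math.sqrt(q / q_df))
    return MRResult(
        condition_id=pairs.condition_id,
        outcome_id=pairs.outcome_id,
        method="ivw_re",
        n_snp=k,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_norm_two_sided_p(beta / se),
        q=q,
        q_df=q_df,
        q_pval=q_pval,
        binary_outcome=pairs.outcome_binary,
    )


def egger(pairs: HarmonizedSet) -> MRResult:
    """MR-Egger regression over >= 3 instruments.

    Every pair is first oriented so β_x > 0; β_y is then regressed on β_x
    with an intercept by weighted least squares (weights 1/se_y²).  Both
    standard errors carry the residual overdispersion factor
    max(1, sqrt(RSS_w/(k−2))), and p-values use the t distribution with
    k − 2 degrees of freedom.  The intercept estimates the average
    directional pleiotropic effect; the slope is the pleiotropy-adjusted
    causal estimate.
    """
    usable = _usable_pairs(pairs)
    k = len(usable)
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {k}")
    bx = np.array([p.beta_exp for p in usable])
    by = np.array([p.beta_out for p in usable])
    sy = np.array([p.se_out for p in usable])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    df = k - 2
    phi = max(1.0, math.sqrt(rss_w / df))
    cov_unit = np.linalg.inv(xtwx)
    se_coef = phi * np.sqrt(np.diag(cov_unit))

    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(se_coef[0]), float(se_coef[1])
    tq = float(stats.t.ppf(0.975, df))

    def t_p(est, se):
        return float(min(max(2.0 * stats.t.sf(abs(est / se), df), np.nextafter(0, 1)), 1.0))

    return MRResult(
        condition_id=pairs.condition_id,
        outcome_id=pairs.outcome_id,
        method="egger",
        n_snp=k,
        beta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=t_p(slope, se_slope),
        q=rss_w,
        q_df=df,
        q_pval=float(stats.chi2.sf(rss_w, df)),
        intercept=intercept,
        intercept_se=se_int,
        intercept_pval=t_p(intercept, se_int),
        binary_outcome=pairs.outcome_binary,
    )


def _weighted_median_estimate(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: θ at cumulative-weight midpoint 0.5."""
    order = np.argsort(theta)
    theta, weights = theta[order], weights[order]
    weights = weights / weights.sum()
    cum = np.cumsum(weights)
    mid = cum - weights / 2.0
    return float(np.interp(0.5, mid, theta))


def weighted_median(
    pairs: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Weights follow the IVW convention (β_x²/se_y², normalized).  The SE is
    the standard deviation of the estimate over ``n_boot`` parametric
    resamples of (β_x, β_y) about their observed values; ``seed`` makes it
    reproducible.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for its bootstrap")
    usable = _usable_pairs(pairs)
    k = len(usable)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 instruments, got {k}"
        )
    bx = np.array([p.beta_exp for p in usable])
    by = np.array([p.beta_out for p in usable])
    sx = np.array([p.se_exp for p in usable])
    sy = np.array([p.se_out for p in usable])

    beta = _weighted_median_estimate(by / bx, bx**2 / sy**2)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        ok = bxb != 0
        boot[b] = _weighted_median_estimate(byb[ok] / bxb[ok], bxb[ok] ** 2 / sy[ok] ** 2)
    se = float(np.std(boot, ddof=1))
    return MRResult(
        condition_id=pairs.condition_id,
        outcome_id=pairs.outcome_id,
        method="weighted_median",
        n_snp=k,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=_norm_two_sided_p(beta / se),
        binary_outcome=pairs.outcome_binary,
    )


def scale_to_doubling(result: MRResult) -> MRResult:
    """Rescale a per-log-odds liability estimate to per-doubling of odds.

    Multiplies the estimate and its standard error by ln 2 and recomputes
    the 95% interval on the scaled values; the z-statistic, and hence the
    p-value, is unchanged.  Heterogeneity and intercept diagnostics are
    carried over untouched (the Egger intercept lives on the outcome scale).
    """
    if result.scale == PER_DOUBLING:
        raise ValueError("result is already on the per-doubling scale")
    beta = result.beta * LN2
    se = result.se * LN2
    return replace(
        result,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        scale=PER_DOUBLING,
    )


def estimate(
    pairs: HarmonizedSet,
    methods: Sequence[str] = ("ivw_re", "egger", "weighted_median"),
    seed: int | None = None,
    per_doubling: bool = True,
) -> list[MRResult]:
    """Run the requested estimators on one harmonized set.

    Falls back to the Wald ratio when a single instrument is available and
    an IVW-family method was requested.  Methods whose instrument-count
    preconditions are unmet are silently omitted from the output.
    """
    out: list[MRResult] = []
    for method in methods:
        try:
            if method in ("ivw", "ivw_re"):
                if pairs.n_snp == 1:
                    res = wald_ratio(
                        pairs.pairs[0], pairs.condition_id, pairs.outcome_id,
                        binary_outcome=pairs.outcome_binary,
                    )
                else:
                    res = ivw(pairs)
            elif method == "egger":
                res = egger(pairs)
            elif method in ("weighted_median", "wmedian"):
                res = weighted_median(pairs, seed=seed)
            elif method == "wald":
                res = wald_ratio(
                    pairs.pairs[0], pairs.condition_id, pairs.outcome_id,
                    binary_outcome=pairs.outcome_binary,
                )
            else:
                raise ValueError(f"unknown method {method!r}")
        except InsufficientInstrumentsError:
            continue
        out.append(scale_to_doubling(res) if per_doubling else res)
    return out
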