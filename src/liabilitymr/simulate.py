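"""Synthetic two-sample GWAS summary statistics with known ground truth.

Effects are generated directly at the summary-statistic level — the level
this analysis consumes — rather than from individual genotypes.  For each
instrument j:

* a minor-allele frequency maf_j ~ Uniform(maf_range);
* a true exposure effect γ_j = |Normal(0, exposure_effect_sd²)| (the effect
  allele is oriented to the liability-increasing allele), rejection-sampled
  until γ_j / se_γj clears the genome-wide-significance z threshold
  (≈5.45), so selected instruments genuinely pass p < 5e-8; the observed
  effect is conditioned on passing too;
* se_γj = 1 / sqrt(2 maf_j (1 − maf_j) n_exp φ(1 − φ)) with φ the case
  fraction for a binary trait (φ(1 − φ) → 1 for continuous traits);
* a pleiotropic effect α_j, zero for valid instruments and
  Normal(μ_α, σ_α²) for a configurable invalid fraction, drawn
  independently of γ_j (the InSIDE condition);
* a true outcome effect θ·γ_j + α_j, observed with analogous noise at the
  outcome sample size.

Allele corruption (orientation swaps with beta negation, strand
complements, palindromic allele pairs) is layered onto the outcome dataset
so the harmonization stage has real repairs to perform.  Mother-child duo
associations and multi-study outcome splits support the fetal-adjustment
and leave-one-study-out loops.  All draws come from one seeded generator:
the same seed reproduces the datasets bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .fetal_wlm import DuoAssociation
from .harmonize import COMPLEMENT
from .summary_data import SummaryDataset, VariantAssociation

#: z threshold equivalent to the two-sided genome-wide p < 5e-8.
GWS_Z = float(stats.norm.isf(2.5e-8))

_MAX_PROPOSALS = 1_000_000

# Non-palindromic allele pairs to assign by default.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic summary-statistics generator.

    Defaults emulate a well-powered autoimmune-condition exposure GWAS
    (binary, ~20% cases among 100k) against a large binary pregnancy-outcome
    meta-analysis (~5% cases among 200k), with a modest liability-scale
    causal effect and no pleiotropy or allele corruption unless asked for.
    """

    seed: int
    k: int = 100
    theta: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.45)
    exposure_effect_sd: float = 0.15
    n_exp: int = 100_000
    exp_case_fraction: float = 0.2
    n_out: int = 200_000
    out_case_fraction: float = 0.05
    outcome_binary: bool = True
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    fetal_direct_sd: float = 0.0
    duo_n: int = 25_000
    n_studies: int = 3
    allele_swap_rate: float = 0.0
    strand_flip_rate: float = 0.0
    palindromic_rate: float = 0.0
    condition_id: str = "sim_condition"
    outcome_id: str = "sim_outcome"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo < hi < 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5)")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        for rate in (self.allele_swap_rate, self.strand_flip_rate, self.palindromic_rate):
            if not (0 <= rate <= 1):
                raise ValueError("corruption rates must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth behind one simulated exposure-outcome pair."""

    theta: float
    gamma: np.ndarray  # true exposure effects
    alpha: np.ndarray  # pleiotropic outcome effects
    maternal_direct: np.ndarray  # true SNP-outcome effects a_j = theta*gamma + alpha
    fetal_direct: np.ndarray | None = None  # b_j, filled by simulate_duos
    rsids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.gamma) == len(self.alpha) == len(self.maternal_direct)):
            raise ValueError("truth arrays must share one length")


def _variance_factor(binary: bool, case_fraction: float) -> float:
    return case_fraction * (1 - case_fraction) if binary else 1.0


def _se_for(maf: float, n: float, v: float) -> float:
    return 1.0 / math.sqrt(2.0 * maf * (1.0 - maf) * n * v)


def _two_sided_p(z: float) -> float:
    return float(min(max(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1)), 1.0))


def simulate_pair(config: SimConfig) -> tuple[SummaryDataset, SummaryDataset, SimTruth]:
    """Generate one exposure dataset, one outcome dataset, and their truth."""
    rng = np.random.default_rng(config.seed)
    v_exp = _variance_factor(True, config.exp_case_fraction)
    v_out = _variance_factor(config.outcome_binary, config.out_case_fraction)

    k = config.k
    n_invalid = int(round(config.invalid_fraction * k))
    invalid = np.zeros(k, dtype=bool)
    if n_invalid:
        invalid[rng.choice(k, size=n_invalid, replace=False)] = True

    mafs = rng.uniform(*config.maf_range, size=k)
    # Palindromic variants are only inserted with clearly informative
    # frequencies (minor-allele frequency well below the 0.42 ambiguity
    # threshold), so harmonization can always resolve their orientation.
    make_palindromic = rng.random(k) < config.palindromic_rate
    lo = config.maf_range[0]
    pal_cap = min(config.maf_range[1], 0.38)
    mafs[make_palindromic] = lo + (pal_cap - lo) * rng.random(int(make_palindromic.sum()))
    gamma = np.empty(k)
    beta_x = np.empty(k)
    se_x = np.empty(k)
    for j in range(k):
        se_x[j] = _se_for(mafs[j], config.n_exp, v_exp)
        threshold = GWS_Z * se_x[j]
        # Condition jointly: the true effect clears the significance
        # threshold and so does the observed one — mirroring the fact that
        # only variants whose *measured* association passes p < 5e-8 enter
        # an instrument list.
        # Effect alleles are taken as the liability-increasing alleles, so
        # true instrument effects are half-normal (positive).
        for _ in range(_MAX_PROPOSALS):
            g = abs(rng.normal(0.0, config.exposure_effect_sd))
            if g <= threshold:
                continue
            b = rng.normal(g, se_x[j])
            if abs(b) > threshold:
                gamma[j], beta_x[j] = g, b
                break
        else:
            raise ValueError(
                "could not draw a genome-wide-significant exposure effect in "
                f"{_MAX_PROPOSALS} proposals; increase n_exp or exposure_effect_sd"
            )
    alpha = np.where(
        invalid, rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=k), 0.0
    )
    a_true = config.theta * gamma + alpha
    se_y = np.array([_se_for(m, config.n_out, v_out) for m in mafs])
    beta_y = rng.normal(a_true, se_y)

    # Allele assignment: palindromic pairs only where requested, with
    # clearly informative frequencies so harmonization can resolve them.
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=k)
    eaf_out_noise = rng.normal(0.0, 0.005, size=k)
    swap = rng.random(k) < config.allele_swap_rate
    strand = rng.random(k) < config.strand_flip_rate

    rsids = [f"rs{j + 1}" for j in range(k)]
    exp_variants: list[VariantAssociation] = []
    out_variants: list[VariantAssociation] = []
    n_case_out = round(config.n_out * config.out_case_fraction) if config.outcome_binary else None
    for j in range(k):
        if make_palindromic[j]:
            ea, oa = _PALINDROMIC_PAIRS[pal_idx[j]]
        else:
            ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        chrom = str(j % 22 + 1)
        pos = 1_000_000 + (j // 22) * 20_000_000
        eaf = float(mafs[j])
        exp_variants.append(
            VariantAssociation(
                rsid=rsids[j],
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=eaf,
                beta=float(beta_x[j]),
                se=float(se_x[j]),
                pval=_two_sided_p(beta_x[j] / se_x[j]),
                n=config.n_exp,
                n_case=round(config.n_exp * config.exp_case_fraction),
                n_control=config.n_exp - round(config.n_exp * config.exp_case_fraction),
                trait_id=config.condition_id,
                trait_type="binary",
            )
        )
        o_ea, o_oa = ea, oa
        o_beta, o_eaf = float(beta_y[j]), float(np.clip(eaf + eaf_out_noise[j], 0.01, 0.99))
        if swap[j] and not make_palindromic[j]:
            o_ea, o_oa = o_oa, o_ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        if strand[j] and not make_palindromic[j]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        out_variants.append(
            VariantAssociation(
                rsid=rsids[j],
                chrom=chrom,
                pos=pos,
                effect_allele=o_ea,
                other_allele=o_oa,
                eaf=o_eaf,
                beta=o_beta,
                se=float(se_y[j]),
                pval=_two_sided_p(beta_y[j] / se_y[j]),
                n=config.n_out,
                n_case=n_case_out,
                n_control=None if n_case_out is None else config.n_out - n_case_out,
                trait_id=config.outcome_id,
                trait_type="binary" if config.outcome_binary else "continuous",
            )
        )

    exposure = SummaryDataset.from_variants(
        config.condition_id, exp_variants, trait_type="binary", provenance="simulated"
    )
    outcome = SummaryDataset.from_variants(
        config.outcome_id,
        out_variants,
        trait_type="binary" if config.outcome_binary else "continuous",
        provenance="simulated",
    )
    truth = SimTruth(
        theta=config.theta,
        gamma=gamma,
        alpha=alpha,
        maternal_direct=a_true,
        rsids=rsids,
    )
    return exposure, outcome, truth


def simulate_duos(
    config: SimConfig,
    truth: SimTruth,
    noise: bool = True,
) -> list[DuoAssociation]:
    """Mother-child duo GWAS pairs implied by the truth's SNP-outcome effects.

    Direct fetal effects b_j ~ Normal(0, fetal_direct_sd²) combine with the
    maternal direct effects a_j through the transmission model
    M = a + b/2, F = b + a/2; observed values carry sampling noise at the
    duo sample size unless ``noise=False`` (the exact-recovery limit).
    Fills ``truth.fetal_direct`` in place.
    """
    rng = np.random.default_rng([config.seed, 104729])
    k = len(truth.maternal_direct)
    b = rng.normal(0.0, config.fetal_direct_sd, size=k) if config.fetal_direct_sd > 0 else np.zeros(k)
    truth.fetal_direct = b
    a = truth.maternal_direct
    m_true = a + b / 2.0
    f_true = b + a / 2.0
    v_out = _variance_factor(config.outcome_binary, config.out_case_fraction)
    duos = []
    for j in range(k):
        # Duo SEs use a generic mid-range maf; precision differences across
        # SNPs matter less than the maternal/fetal contrast being tested.
        se = _se_for(0.25, config.duo_n, v_out)
        m_obs = rng.normal(m_true[j], se) if noise else m_true[j]
        f_obs = rng.normal(f_true[j], se) if noise else f_true[j]
        duos.append(
            DuoAssociation(
                rsid=truth.rsids[j] if truth.rsids else f"rs{j + 1}",
                beta_maternal_marginal=float(m_obs),
                se_m=se,
                beta_fetal_marginal=float(f_obs),
                se_f=se,
            )
        )
    return duos


def split_studies(
    outcome: SummaryDataset,
    n_studies: int = 3,
    weights: Sequence[float] | None = None,
    seed: int = 0,
) -> dict[str, SummaryDataset]:
    """Split a pooled outcome dataset into per-study replicates.

    Study s receives se_s = se / sqrt(w_s) (precision proportional to its
    weight) and betas drawn about the pooled value but constrained so the
    fixed-effect meta-analysis of the splits reproduces the pooled beta and
    SE exactly.
    """
    if n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    if weights is None:
        weights = [1.0 / n_studies] * n_studies
    weights = list(weights)
    if len(weights) != n_studies:
        raise ValueError("weights length must equal n_studies")
    if any(w <= 0 for w in weights):
        raise ValueError("study weights must be positive")
    total = sum(weights)
    weights = [w / total for w in weights]

    rng = np.random.default_rng([seed, 224737])
    labels = [f"study_{s + 1}" for s in range(n_studies)]
    studies: dict[str, list[VariantAssociation]] = {label: [] for label in labels}
    for v in outcome:
        ses = [v.se / math.sqrt(w) for w in weights]
        draws = rng.normal(0.0, ses)
        prec = np.array([1.0 / s**2 for s in ses])
        centered = draws - float(np.sum(prec * draws) / np.sum(prec))
        for label, se_s, d in zip(labels, ses, centered):
            z = (v.beta + d) / se_s
            studies[label].append(
                replace(
                    v,
                    beta=float(v.beta + d),
                    se=se_s,
                    pval=_two_sided_p(z),
                    n=None if v.n is None else v.n * weights[labels.index(label)],
                    n_case=None,
                    n_control=None,
                )
            )
    return {
        label: SummaryDataset.from_variants(
            f"{outcome.trait_id}", variants, trait_type=outcome.trait_type,
            provenance=f"simulated split {label}",
        )
        for label, variants in studies.items()
    }
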