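"""Instrument selection and instrument-level diagnostics.

Instruments are genome-wide-significant variants (p < 5e-8) pruned to
LD-independence by greedy p-value-ranked clumping (r² < 0.001 within a
10,000-kb window by default).  The module also computes the mean pseudo-F
instrument-strength statistic, flags variants inside the long-range-LD HLA
region (chr6:28,477,797-33,448,354, GRCh37), and screens how correlated two
conditions' instrument effects are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .harmonize import harmonize
from .summary_data import LDMatrix, SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

#: HLA region on GRCh37, 1-based inclusive on both ends.
HLA_REGION = ("6", 28_477_797, 33_448_354)

DEFAULT_PVAL_THRESHOLD = 5e-8
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000


def _chrom_key(chrom: str | None) -> tuple[int, str]:
    """Sort key placing numeric chromosomes first, in numeric order."""
    if chrom is None:
        return (2, "")
    label = str(chrom).removeprefix("chr")
    try:
        return (0, f"{int(label):02d}")
    except ValueError:
        return (1, label)


def _norm_chrom(chrom: str | None) -> str | None:
    return None if chrom is None else str(chrom).removeprefix("chr")


@dataclass
class InstrumentSet:
    """LD-independent genome-wide-significant instruments for one condition."""

    condition_id: str
    variants: list[VariantAssociation]
    pval_threshold: float = DEFAULT_PVAL_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_window_kb: float = DEFAULT_CLUMP_WINDOW_KB
    hla_flags: list[bool] = field(default_factory=list)
    externally_supplied: bool = False

    def __post_init__(self) -> None:
        if not self.hla_flags:
            self.hla_flags = flag_hla(self.variants)
        if len(self.hla_flags) != len(self.variants):
            raise ValueError("hla_flags length must match variants")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def mean_pseudo_f(self) -> float:
        return mean_pseudo_f(self)

    def without_hla(self) -> "InstrumentSet":
        kept = [v for v, flag in zip(self.variants, self.hla_flags) if not flag]
        return InstrumentSet(
            condition_id=self.condition_id,
            variants=kept,
            pval_threshold=self.pval_threshold,
            clump_r2=self.clump_r2,
            clump_window_kb=self.clump_window_kb,
            externally_supplied=self.externally_supplied,
        )

    def to_dataset(self) -> SummaryDataset:
        return SummaryDataset.from_variants(self.condition_id, self.variants)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, flag in zip(self.variants, self.hla_flags):
            rows.append(
                {
                    "rsid": v.rsid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "effect_allele": v.effect_allele,
                    "other_allele": v.other_allele,
                    "eaf": v.eaf,
                    "beta": v.beta,
                    "se": v.se,
                    "pval": v.pval,
                    "n": v.n,
                    "hla_flag": flag,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_dataset(cls, condition_id: str, dataset: SummaryDataset, **kwargs) -> "InstrumentSet":
        """Build directly from an externally curated instrument list (no selection).

        Mirrors the path where a source study publishes only its independent
        hits (e.g. conditional/joint analysis output) rather than full
        summary statistics.
        """
        variants = sorted(dataset, key=lambda v: (_chrom_key(v.chrom), v.pos or 0))
        return cls(
            condition_id=condition_id,
            variants=variants,
            externally_supplied=True,
            **kwargs,
        )


def select_instruments(
    exposure: SummaryDataset,
    ld: LDMatrix | None = None,
    pval_threshold: float = DEFAULT_PVAL_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> InstrumentSet:
    """Select LD-independent genome-wide-significant instruments.

    Greedy p-value-ranked clumping: candidates below ``pval_threshold`` are
    ranked by ascending p (ties broken by rsid), the best remaining
    candidate is accepted, and every candidate on the same chromosome within
    ``clump_window_kb`` with r² >= ``clump_r2`` against it is discarded.
    Pairs the LD matrix does not cover are treated as correlated
    (discarded), degrading to distance-only pruning with a logged warning.
    An empty candidate list yields an empty set with a warning, not an error.
    """
    candidates = [v for v in exposure if v.pval < pval_threshold]
    if not candidates:
        logger.warning(
            "%s: no variants below p < %.3g; returning an empty instrument set",
            exposure.trait_id,
            pval_threshold,
        )
        return InstrumentSet(
            condition_id=exposure.trait_id,
            variants=[],
            pval_threshold=pval_threshold,
            clump_r2=clump_r2,
            clump_window_kb=clump_window_kb,
        )
    candidates.sort(key=lambda v: (v.pval, v.rsid))
    window_bp = clump_window_kb * 1000
    warned_missing_ld = False

    accepted: list[VariantAssociation] = []
    remaining = candidates
    while remaining:
        best, rest = remaining[0], remaining[1:]
        accepted.append(best)
        survivors = []
        for v in rest:
            same_chrom = (
                best.chrom is not None
                and v.chrom is not None
                and _norm_chrom(best.chrom) == _norm_chrom(v.chrom)
            )
            in_window = (
                same_chrom
                and best.pos is not None
                and v.pos is not None
                and abs(v.pos - best.pos) <= window_bp
            )
            if not in_window:
                survivors.append(v)
                continue
            r2 = None if ld is None else ld.lookup(best.rsid, v.rsid)
            if r2 is None:
                if not warned_missing_ld:
                    logger.warning(
                        "%s: LD unavailable for some candidate pairs; "
                        "clumping degrades to distance-only pruning",
                        exposure.trait_id,
                    )
                    warned_missing_ld = True
                r2 = 1.0
            if r2 < clump_r2:
                survivors.append(v)
        remaining = survivors

    accepted.sort(key=lambda v: (_chrom_key(v.chrom), v.pos or 0, v.rsid))
    return InstrumentSet(
        condition_id=exposure.trait_id,
        variants=accepted,
        pval_threshold=pval_threshold,
        clump_r2=clump_r2,
        clump_window_kb=clump_window_kb,
    )


def mean_pseudo_f(instruments: InstrumentSet | Iterable[VariantAssociation]) -> float:
    """Mean pseudo-F statistic across instruments: mean of (beta/se)²."""
    variants = list(instruments)
    if not variants:
        raise ValueError("mean pseudo-F is undefined for an empty instrument set")
    return float(np.mean([(v.beta / v.se) ** 2 for v in variants]))


def flag_hla(
    variants: Sequence[VariantAssociation],
    region: tuple[str, int, int] = HLA_REGION,
) -> list[bool]:
    """Flag variants inside the HLA region (1-based inclusive interval)."""
    chrom, start, end = region
    chrom = _norm_chrom(chrom)
    flags = []
    for v in variants:
        flags.append(
            v.chrom is not None
            and v.pos is not None
            and _norm_chrom(v.chrom) == chrom
            and start <= v.pos <= end
        )
    return flags


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation of instrument effects between two conditions."""

    condition_a: str
    condition_b: str
    n_shared_snps: int
    pearson_r: float | None
    alignment: str = (
        "effects oriented so each shared allele increases condition-a liability"
    )

    def __post_init__(self) -> None:
        if self.pearson_r is not None:
            if abs(self.pearson_r) > 1 + 1e-12:
                raise ValueError("|pearson_r| must be <= 1")
            if self.n_shared_snps < 2:
                raise ValueError("pearson_r requires >= 2 shared SNPs")


def cross_condition_correlation(
    instruments_a: InstrumentSet,
    effects_on_b: SummaryDataset,
) -> CorrelationReport:
    """Correlate condition-a instrument effects with their effects on condition b.

    Condition b's associations are first harmonized to condition a's
    effect alleles; each shared SNP is then oriented so its effect allele
    increases condition-a liability before taking the Pearson correlation.
    """
    aligned = harmonize(
        instruments_a.to_dataset(),
        effects_on_b,
        condition_id=instruments_a.condition_id,
    )
    if aligned.n_snp < 2:
        return CorrelationReport(
            condition_a=instruments_a.condition_id,
            condition_b=effects_on_b.trait_id,
            n_shared_snps=aligned.n_snp,
            pearson_r=None,
        )
    beta_a = np.array([p.beta_exp for p in aligned])
    beta_b = np.array([p.beta_out for p in aligned])
    sign = np.where(beta_a < 0, -1.0, 1.0)
    beta_a, beta_b = beta_a * sign, beta_b * sign
    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(beta_a, beta_b)[0, 1])
    return CorrelationReport(
        condition_a=instruments_a.condition_id,
        condition_b=effects_on_b.trait_id,
        n_shared_snps=aligned.n_snp,
        pearson_r=None if np.isnan(r) else r,
    )
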