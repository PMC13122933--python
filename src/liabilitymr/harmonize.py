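"""Align exposure-instrument and outcome summary statistics to a common
effect allele.

Two-sample MR requires each variant's exposure and outcome effects to be
expressed per copy of the same allele.  Sources may report the opposite
allele (orientation swap), the opposite strand (A<->T, C<->G complement),
or both.  Palindromic variants (allele pair A/T or C/G) are strand-ambiguous
by construction, so their orientation is inferred from allele frequencies,
and dropped when frequencies are uninformative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .summary_data import ConfigurationError, SummaryDataset, VariantAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

KEPT = "kept"
FLIPPED = "flipped"
STRAND_CORRECTED = "strand_corrected"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"
MISSING = "missing"

RETAINED_DISPOSITIONS = (KEPT, FLIPPED, STRAND_CORRECTED)
ALL_DISPOSITIONS = RETAINED_DISPOSITIONS + (DROPPED_PALINDROMIC, DROPPED_MISMATCH, MISSING)


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """True when the allele pair is its own strand complement (A/T or C/G)."""
    return COMPLEMENT.get(allele_a) == allele_b


def _complement_pair(a1: str, a2: str) -> tuple[str, str] | None:
    c1, c2 = COMPLEMENT.get(a1), COMPLEMENT.get(a2)
    if c1 is None or c2 is None:
        return None
    return c1, c2


@dataclass(frozen=True)
class HarmonizedPair:
    """One instrument aligned to the exposure's effect allele in both datasets."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    disposition: str
    pval_exp: float | None = None
    pval_out: float | None = None
    eaf_exp: float | None = None
    eaf_out: float | None = None
    n_exp: float | None = None
    n_out: float | None = None
    n_case_exp: float | None = None
    n_control_exp: float | None = None
    n_case_out: float | None = None
    n_control_out: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")
        if self.disposition not in ALL_DISPOSITIONS:
            raise ValueError(f"unknown disposition {self.disposition!r}")


@dataclass
class HarmonizedSet:
    """Retained harmonized pairs for one condition-outcome analysis."""

    condition_id: str
    outcome_id: str
    pairs: list[HarmonizedPair] = field(default_factory=list)
    audit: Counter = field(default_factory=Counter)
    outcome_binary: bool = True

    def __post_init__(self) -> None:
        rsids = [p.rsid for p in self.pairs]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsid in harmonized set")
        for p in self.pairs:
            if p.disposition not in RETAINED_DISPOSITIONS:
                raise ValueError(
                    f"{p.rsid}: dropped pairs do not belong in a HarmonizedSet"
                )

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def subset(self, rsids: Iterable[str]) -> "HarmonizedSet":
        keep = set(rsids)
        return HarmonizedSet(
            condition_id=self.condition_id,
            outcome_id=self.outcome_id,
            pairs=[p for p in self.pairs if p.rsid in keep],
            audit=Counter(self.audit),
            outcome_binary=self.outcome_binary,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "condition": self.condition_id,
                    "outcome": self.outcome_id,
                    "rsid": p.rsid,
                    "chrom": p.chrom,
                    "pos": p.pos,
                    "effect_allele": p.effect_allele,
                    "other_allele": p.other_allele,
                    "beta_exp": p.beta_exp,
                    "se_exp": p.se_exp,
                    "pval_exp": p.pval_exp,
                    "eaf_exp": p.eaf_exp,
                    "n_exp": p.n_exp,
                    "beta_out": p.beta_out,
                    "se_out": p.se_out,
                    "pval_out": p.pval_out,
                    "eaf_out": p.eaf_out,
                    "n_out": p.n_out,
                    "disposition": p.disposition,
                }
            )
        return pd.DataFrame(rows)


def _orient_outcome(ov: VariantAssociation, flip: bool) -> tuple[float, float | None]:
    """Outcome beta and eaf expressed on the exposure's effect allele."""
    beta = -ov.beta if flip else ov.beta
    eaf = None if ov.eaf is None else (1 - ov.eaf if flip else ov.eaf)
    return beta, eaf


def _informative(eaf: float | None, threshold: float) -> bool:
    return eaf is not None and min(eaf, 1 - eaf) < threshold and eaf != 0.5


def harmonize(
    exposure: SummaryDataset | Iterable[VariantAssociation],
    outcome: SummaryDataset,
    condition_id: str | None = None,
    outcome_id: str | None = None,
    palindromic_maf_threshold: float = 0.42,
) -> HarmonizedSet:
    """Harmonize exposure instruments against an outcome dataset.

    Per instrument present in the outcome: identical allele pair in the same
    orientation is kept; swapped orientation negates the outcome beta
    (``flipped``); a pair matching only under strand complement is
    complemented first (``strand_corrected``); palindromic pairs are
    resolved by comparing which side of 0.5 each dataset's effect-allele
    frequency falls on, provided both minor-allele frequencies are below
    ``palindromic_maf_threshold``; anything irreconcilable is
    ``dropped_mismatch``.  Instruments absent from the outcome are audited
    as ``missing`` — no proxy search is attempted.
    """
    if not (0 < palindromic_maf_threshold < 0.5):
        raise ValueError("palindromic_maf_threshold must be in (0, 0.5)")
    if isinstance(exposure, SummaryDataset):
        exp_variants = list(exposure)
        condition_id = condition_id or exposure.trait_id
    else:
        exp_variants = list(exposure)
        condition_id = condition_id or (exp_variants[0].trait_id if exp_variants else "")
    outcome_id = outcome_id or outcome.trait_id

    pairs: list[HarmonizedPair] = []
    audit: Counter = Counter({d: 0 for d in ALL_DISPOSITIONS})
    for ev in exp_variants:
        ov = outcome.get(ev.rsid)
        if ov is None:
            audit[MISSING] += 1
            continue
        exp_pair = (ev.effect_allele.upper(), ev.other_allele.upper())
        out_pair = (ov.effect_allele.upper(), ov.other_allele.upper())

        disposition: str
        flip: bool
        if is_palindromic(*exp_pair):
            if out_pair not in (exp_pair, exp_pair[::-1]):
                disposition, flip = DROPPED_MISMATCH, False
            elif _informative(ev.eaf, palindromic_maf_threshold) and _informative(
                ov.eaf, palindromic_maf_threshold
            ):
                same_side = (ev.eaf - 0.5) * (ov.eaf - 0.5) > 0
                disposition = KEPT if same_side else FLIPPED
                flip = not same_side
            else:
                disposition, flip = DROPPED_PALINDROMIC, False
        elif out_pair == exp_pair:
            disposition, flip = KEPT, False
        elif out_pair == exp_pair[::-1]:
            disposition, flip = FLIPPED, True
        else:
            comp = _complement_pair(*out_pair)
            if comp == exp_pair:
                disposition, flip = STRAND_CORRECTED, False
            elif comp == exp_pair[::-1]:
                disposition, flip = STRAND_CORRECTED, True
            else:
                disposition, flip = DROPPED_MISMATCH, False

        audit[disposition] += 1
        if disposition not in RETAINED_DISPOSITIONS:
            continue
        beta_out, eaf_out = _orient_outcome(ov, flip)
        pairs.append(
            HarmonizedPair(
                rsid=ev.rsid,
                effect_allele=exp_pair[0],
                other_allele=exp_pair[1],
                beta_exp=ev.beta,
                se_exp=ev.se,
                pval_exp=ev.pval,
                eaf_exp=ev.eaf,
                n_exp=ev.n,
                n_case_exp=ev.n_case,
                n_control_exp=ev.n_control,
                beta_out=beta_out,
                se_out=ov.se,
                pval_out=ov.pval,
                eaf_out=eaf_out,
                n_out=ov.n,
                n_case_out=ov.n_case,
                n_control_out=ov.n_control,
                chrom=ev.chrom,
                pos=ev.pos,
                disposition=disposition,
            )
        )
    return HarmonizedSet(
        condition_id=condition_id,
        outcome_id=outcome_id,
        pairs=pairs,
        audit=audit,
        outcome_binary=outcome.trait_type == "binary",
    )


# Aliases accepted for each standard column of a pre-harmonized table, so
# both this package's serialization and TwoSampleMR-style exports load
# without a custom column map.
_HARMONIZED_ALIASES: dict[str, tuple[str, ...]] = {
    "condition": ("condition", "exposure", "condition_id", "id.exposure"),
    "outcome": ("outcome", "outcome_id", "id.outcome"),
    "rsid": ("rsid", "SNP", "snp", "variant"),
    "chrom": ("chrom", "chr", "chr.exposure", "chromosome"),
    "pos": ("pos", "position", "pos.exposure", "bp"),
    "effect_allele": ("effect_allele", "effect_allele.exposure", "ea"),
    "other_allele": ("other_allele", "other_allele.exposure", "oa"),
    "beta_exp": ("beta_exp", "beta.exposure", "beta_exposure"),
    "se_exp": ("se_exp", "se.exposure", "se_exposure"),
    "pval_exp": ("pval_exp", "pval.exposure", "p.exposure"),
    "eaf_exp": ("eaf_exp", "eaf.exposure"),
    "n_exp": ("n_exp", "samplesize.exposure", "n.exposure"),
    "beta_out": ("beta_out", "beta.outcome", "beta_outcome"),
    "se_out": ("se_out", "se.outcome", "se_outcome"),
    "pval_out": ("pval_out", "pval.outcome", "p.outcome"),
    "eaf_out": ("eaf_out", "eaf.outcome"),
    "n_out": ("n_out", "samplesize.outcome", "n.outcome"),
}

_REQUIRED_HARMONIZED = ("condition", "outcome", "rsid", "beta_exp", "se_exp", "beta_out", "se_out")


def apply_harmonized_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    binary_outcomes: Iterable[str] | None = None,
) -> list[HarmonizedSet]:
    """Load a pre-harmonized SNP-exposure/SNP-outcome table.

    This is the entry point for reproducing published results from a study's
    released harmonized data: each condition-outcome block becomes one
    :class:`HarmonizedSet` with every row ``kept``, bypassing
    :func:`harmonize`.  ``binary_outcomes``, when given, restricts which
    outcome ids are treated as binary (default: all).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if delimiter is not None:
        sep = delimiter
    df = pd.read_csv(path, sep=sep)

    resolved: dict[str, str] = {}
    cmap = dict(column_map or {})
    for fname, aliases in _HARMONIZED_ALIASES.items():
        if fname in cmap:
            resolved[fname] = cmap[fname]
            continue
        for alias in aliases:
            if alias in df.columns:
                resolved[fname] = alias
                break
    for fname in _REQUIRED_HARMONIZED:
        if fname not in resolved:
            raise ConfigurationError(
                f"{path}: no column found for required field {fname!r}"
            )

    def val(row, fname):
        col = resolved.get(fname)
        if col is None:
            return None
        v = row[col]
        return None if pd.isna(v) else v

    binary = None if binary_outcomes is None else set(binary_outcomes)
    sets: list[HarmonizedSet] = []
    for (cond, out), block in df.groupby([resolved["condition"], resolved["outcome"]], sort=True):
        pairs = []
        for _, row in block.iterrows():
            pos = val(row, "pos")
            pairs.append(
                HarmonizedPair(
                    rsid=str(val(row, "rsid")),
                    effect_allele=str(val(row, "effect_allele") or "N"),
                    other_allele=str(val(row, "other_allele") or "M"),
                    beta_exp=float(val(row, "beta_exp")),
                    se_exp=float(val(row, "se_exp")),
                    pval_exp=None if val(row, "pval_exp") is None else float(val(row, "pval_exp")),
                    eaf_exp=None if val(row, "eaf_exp") is None else float(val(row, "eaf_exp")),
                    n_exp=None if val(row, "n_exp") is None else float(val(row, "n_exp")),
                    beta_out=float(val(row, "beta_out")),
                    se_out=float(val(row, "se_out")),
                    pval_out=None if val(row, "pval_out") is None else float(val(row, "pval_out")),
                    eaf_out=None if val(row, "eaf_out") is None else float(val(row, "eaf_out")),
                    n_out=None if val(row, "n_out") is None else float(val(row, "n_out")),
                    chrom=None if val(row, "chrom") is None else str(val(row, "chrom")),
                    pos=None if pos is None else int(float(pos)),
                    disposition=KEPT,
                )
            )
        audit = Counter({d: 0 for d in ALL_DISPOSITIONS})
        audit[KEPT] = len(pairs)
        sets.append(
            HarmonizedSet(
                condition_id=str(cond),
                outcome_id=str(out),
                pairs=pairs,
                audit=audit,
                outcome_binary=binary is None or str(out) in binary,
            )
        )
    return sets
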