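"""Typed containers and I/O for GWAS summary statistics and LD matrices.

Summary statistics are one row per variant: identifiers, alleles, effect
sizes on the trait scale (log-odds for binary traits, SD units for
continuous ones), precision, and sample sizes.  Files are plain delimited
tables (GWAS-SSF-like field names by default) so heterogeneous upstream
sources can be mapped in via a column map rather than a hard-coded dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("binary", "continuous")

#: Standard field names (GWAS-SSF-like); a column_map translates file headers
#: onto these.
STANDARD_FIELDS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_case",
    "n_control",
)

REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")


class ConfigurationError(ValueError):
    """A column map or configuration value does not match the input."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``: log-odds
    for a binary trait, SD units for a continuous one.  Positions are
    1-based on GRCh37.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None
    trait_id: str = ""
    trait_type: str = "binary"

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.rsid}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.rsid}: eaf must be in [0, 1], got {self.eaf}")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if (
            self.trait_type == "binary"
            and self.n is not None
            and self.n_case is not None
            and self.n_control is not None
            and not math.isclose(self.n_case + self.n_control, self.n, rel_tol=1e-9)
        ):
            raise ValueError(f"{self.rsid}: n_case + n_control != n")

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryDataset:
    """A trait's summary statistics, keyed by rsid (unique within a dataset)."""

    trait_id: str
    trait_type: str = "binary"
    variants: dict[str, VariantAssociation] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.variants.values())

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.variants

    def get(self, rsid: str) -> VariantAssociation | None:
        return self.variants.get(rsid)

    def add(self, variant: VariantAssociation) -> None:
        if variant.rsid in self.variants:
            raise ValueError(f"duplicate rsid {variant.rsid} in {self.trait_id}")
        self.variants[variant.rsid] = variant

    @classmethod
    def from_variants(
        cls,
        trait_id: str,
        variants: Iterable[VariantAssociation],
        trait_type: str = "binary",
        provenance: str = "",
    ) -> "SummaryDataset":
        ds = cls(trait_id=trait_id, trait_type=trait_type, provenance=provenance)
        for v in variants:
            ds.add(replace(v, trait_id=trait_id, trait_type=trait_type))
        return ds

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {f: getattr(v, f) for f in STANDARD_FIELDS} for v in self.variants.values()
        ]
        return pd.DataFrame(rows, columns=list(STANDARD_FIELDS))


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _coerce_float(value) -> float | None:
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    return x if math.isfinite(x) else None


def read_summary_stats(
    path: str | Path,
    trait_id: str,
    trait_type: str = "binary",
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    duplicate_policy: str = "error",
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    ``column_map`` maps standard field names (``rsid``, ``beta``, ...) onto
    the file's column headers; unmapped optional fields are read from
    identically named columns when present.  Rows with unparseable
    beta/se/pval are dropped and counted in the log.  ``duplicate_policy``
    is ``"error"`` (default) or ``"keep_lowest_p"``.
    """
    path = Path(path)
    if duplicate_policy not in ("error", "keep_lowest_p"):
        raise ConfigurationError(f"unknown duplicate_policy {duplicate_policy!r}")
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty summary-statistics file") from exc
    if df.empty:
        raise ValueError(f"{path}: summary-statistics file has no data rows")

    cmap = dict(column_map or {})
    for fname in STANDARD_FIELDS:
        cmap.setdefault(fname, fname)
    for fname in REQUIRED_FIELDS:
        if cmap[fname] not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {cmap[fname]!r} (field {fname!r}) not found"
            )

    dataset = SummaryDataset(trait_id=trait_id, trait_type=trait_type, provenance=str(path))
    dropped = 0
    for _, row in df.iterrows():
        def cell(fname: str):
            col = cmap[fname]
            if col not in df.columns:
                return None
            val = row[col]
            return None if pd.isna(val) else val

        beta = _coerce_float(cell("beta"))
        se = _coerce_float(cell("se"))
        pval = _coerce_float(cell("pval"))
        if beta is None or se is None or se <= 0 or pval is None or not (0 < pval <= 1):
            dropped += 1
            continue
        pos_raw = _coerce_float(cell("pos"))
        variant = VariantAssociation(
            rsid=str(cell("rsid")),
            chrom=None if cell("chrom") is None else str(cell("chrom")),
            pos=None if pos_raw is None else int(pos_raw),
            effect_allele=str(cell("effect_allele")).upper(),
            other_allele=str(cell("other_allele")).upper(),
            eaf=_coerce_float(cell("eaf")),
            beta=beta,
            se=se,
            pval=pval,
            n=_coerce_float(cell("n")),
            n_case=_coerce_float(cell("n_case")),
            n_control=_coerce_float(cell("n_control")),
            trait_id=trait_id,
            trait_type=trait_type,
        )
        if variant.rsid in dataset.variants:
            if duplicate_policy == "error":
                raise ValueError(f"{path}: duplicated rsid {variant.rsid}")
            if variant.pval < dataset.variants[variant.rsid].pval:
                dataset.variants[variant.rsid] = variant
            continue
        dataset.variants[variant.rsid] = variant
    if dropped:
        logger.info("%s: dropped %d rows with unparseable beta/se/pval", path, dropped)
    dataset.n_dropped_rows = dropped  # type: ignore[attr-defined]
    return dataset


RESULT_COLUMNS = (
    "condition",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "or_scaled",
    "or_ci_low",
    "or_ci_high",
    "q",
    "q_df",
    "q_pval",
    "intercept",
    "intercept_se",
    "intercept_pval",
    "scale",
)


def results_to_frame(results: Sequence) -> pd.DataFrame:
    """Flatten a collection of ``MRResult`` into the fixed-column table."""
    rows = []
    for r in results:
        odds = r.scale == "per_doubling" and getattr(r, "binary_outcome", True)
        rows.append(
            {
                "condition": r.condition_id,
                "outcome": r.outcome_id,
                "method": r.method,
                "n_snp": r.n_snp,
                "beta": r.beta,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pval": r.pval,
                "or_scaled": math.exp(r.beta) if odds else np.nan,
                "or_ci_low": math.exp(r.ci_low) if odds else np.nan,
                "or_ci_high": math.exp(r.ci_high) if odds else np.nan,
                "q": np.nan if r.q is None else r.q,
                "q_df": np.nan if r.q_df is None else r.q_df,
                "q_pval": np.nan if r.q_pval is None else r.q_pval,
                "intercept": np.nan if r.intercept is None else r.intercept,
                "intercept_se": np.nan if r.intercept_se is None else r.intercept_se,
                "intercept_pval": np.nan if r.intercept_pval is None else r.intercept_pval,
                "scale": r.scale,
            }
        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Write MR results as a TSV with fixed column order.

    Values round-trip through :func:`read_results_table` at 10 significant
    digits.  An empty collection is an error and no file is created.
    """
    if not results:
        raise ValueError("cannot write an empty results collection")
    frame = results_to_frame(results)
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


@dataclass
class LDMatrix:
    """A square symmetric matrix of squared correlations (r²) between variants."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {self.r2.shape} does not match {k} rsids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValueError("r2 matrix diagonal must be exactly 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}
        if len(self._index) != k:
            raise ValueError("duplicate rsids in LD matrix")

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def lookup(self, rsid_a: str, rsid_b: str) -> float | None:
        ia = self._index.get(rsid_a)
        ib = self._index.get(rsid_b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(Path(path), sep="\t", index_col=0)
        return cls(rsids=[str(r) for r in df.index], r2=df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            Path(path), sep="\t", float_format="%.10g"
        )
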