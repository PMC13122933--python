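"""Orchestration of the full condition-outcome analysis grid.

For every condition-outcome pair the pipeline runs: harmonization (or
ingestion of a pre-harmonized table), the main random-effects IVW estimate
rescaled per doubling of exposure odds, MR-Egger and weighted-median
checks, Steiger-filtered and HLA-excluded reruns, leave-one-SNP-out, and —
when the inputs are supplied — fetal-genotype adjustment and
leave-one-study-out.  The grid of main estimates is then triaged by the
two-tier follow-up rule with Benjamini–Yekutieli FDR, and each selected
pair receives a directional-concordance robustness tier.

Pairs that fail a precondition (no shared SNPs, too few instruments) are
skipped and reported in the run manifest; a partial grid never aborts the
run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .estimators import (
    InsufficientInstrumentsError,
    MRResult,
    egger,
    ivw,
    scale_to_doubling,
    wald_ratio,
    weighted_median,
)
from .fetal_wlm import DuoAssociation, mr_with_fetal_adjustment
from .harmonize import HarmonizedSet, apply_harmonized_table, harmonize
from .inference import select_for_followup, summarize_robustness
from .instruments import InstrumentSet, select_instruments
from .sensitivity import (
    leave_one_snp_out,
    leave_one_study_out,
    rerun_without_hla,
    steiger_filtered_estimate,
)
from .summary_data import SummaryDataset, results_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameterization of one full analysis run."""

    seed: int
    out_dir: str | Path = "results"
    harmonized_table: str | Path | None = None
    exposures: Mapping[str, SummaryDataset] = field(default_factory=dict)
    outcomes: Mapping[str, SummaryDataset] = field(default_factory=dict)
    binary_outcomes: Sequence[str] | None = None
    duos: Mapping[str, Sequence[DuoAssociation]] | None = None
    per_study_outcomes: Mapping[str, Mapping[str, SummaryDataset]] | None = None
    methods: Sequence[str] = ("ivw", "egger", "weighted_median")
    palindromic_maf_threshold: float = 0.42
    pval_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    alpha_fdr: float = 0.05
    steiger_alpha: float = 0.05
    n_boot: int = 1000

    def __post_init__(self) -> None:
        if self.harmonized_table is None and not (self.exposures and self.outcomes):
            raise ValueError(
                "config needs either a harmonized table or at least one exposure "
                "and one outcome"
            )

    def fingerprint(self) -> str:
        payload = {
            "seed": self.seed,
            "harmonized_table": None if self.harmonized_table is None else str(self.harmonized_table),
            "exposures": sorted(self.exposures),
            "outcomes": sorted(self.outcomes),
            "methods": list(self.methods),
            "palindromic_maf_threshold": self.palindromic_maf_threshold,
            "pval_threshold": self.pval_threshold,
            "clump_r2": self.clump_r2,
            "clump_window_kb": self.clump_window_kb,
            "alpha_fdr": self.alpha_fdr,
            "steiger_alpha": self.steiger_alpha,
            "n_boot": self.n_boot,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class RunOutput:
    """In-memory results of one run (also written as TSVs + manifest)."""

    results: list[MRResult]
    decisions: list
    robustness: list
    sensitivity: dict[str, list[MRResult]]
    loo_snp: pd.DataFrame
    manifest: dict


def _main_estimate(pairs: HarmonizedSet) -> MRResult:
    if pairs.n_snp >= 2:
        return ivw(pairs)
    return wald_ratio(
        pairs.pairs[0], pairs.condition_id, pairs.outcome_id,
        binary_outcome=pairs.outcome_binary,
    )


def build_harmonized_sets(config: RunConfig) -> tuple[list[HarmonizedSet], list[dict]]:
    """Resolve the grid of harmonized sets from whichever inputs were given."""
    skips: list[dict] = []
    if config.harmonized_table is not None:
        sets = apply_harmonized_table(
            config.harmonized_table, binary_outcomes=config.binary_outcomes
        )
        return sets, skips
    sets = []
    binary = None if config.binary_outcomes is None else set(config.binary_outcomes)
    for cond_id, exposure in config.exposures.items():
        instruments = select_instruments(
            exposure,
            pval_threshold=config.pval_threshold,
            clump_r2=config.clump_r2,
            clump_window_kb=config.clump_window_kb,
        )
        if len(instruments) == 0:
            skips.append({"condition": cond_id, "outcome": "*", "reason": "no instruments"})
            continue
        for out_id, outcome in config.outcomes.items():
            hs = harmonize(
                instruments.to_dataset(),
                outcome,
                condition_id=cond_id,
                outcome_id=out_id,
                palindromic_maf_threshold=config.palindromic_maf_threshold,
            )
            if binary is not None:
                hs.outcome_binary = out_id in binary
            if hs.n_snp == 0:
                skips.append(
                    {"condition": cond_id, "outcome": out_id, "reason": "no shared SNPs"}
                )
                continue
            sets.append(hs)
    return sets, skips


def run_grid(config: RunConfig) -> RunOutput:
    """Execute the full study graph and write one TSV per stage."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "sensitivity").mkdir(exist_ok=True)

    sets, skips = build_harmonized_sets(config)
    main_results: list[MRResult] = []
    sensitivity: dict[str, list[MRResult]] = {
        "egger": [],
        "weighted_median": [],
        "steiger": [],
        "no_hla": [],
        "fetal_adjusted": [],
        "leave_one_study_out": [],
    }
    loo_rows: list[dict] = []
    bundles: dict[tuple[str, str], dict] = {}
    audit_rows: list[dict] = []

    for hs in sets:
        key = (hs.condition_id, hs.outcome_id)
        for disposition, count in sorted(hs.audit.items()):
            audit_rows.append(
                {
                    "condition": hs.condition_id,
                    "outcome": hs.outcome_id,
                    "disposition": disposition,
                    "count": count,
                }
            )
        try:
            main = scale_to_doubling(_main_estimate(hs))
        except (InsufficientInstrumentsError, ZeroDivisionError) as exc:
            skips.append(
                {"condition": key[0], "outcome": key[1], "reason": str(exc)}
            )
            continue
        main_results.append(main)
        bundle: dict[str, object] = {}

        if "egger" in config.methods:
            try:
                res = scale_to_doubling(egger(hs))
                sensitivity["egger"].append(res)
                bundle["egger"] = res
            except InsufficientInstrumentsError:
                bundle["egger"] = None
        if "weighted_median" in config.methods or "wmedian" in config.methods:
            try:
                res = scale_to_doubling(
                    weighted_median(hs, n_boot=config.n_boot, seed=config.seed)
                )
                sensitivity["weighted_median"].append(res)
                bundle["weighted_median"] = res
            except InsufficientInstrumentsError:
                bundle["weighted_median"] = None

        steiger_res, _records = steiger_filtered_estimate(hs, alpha=config.steiger_alpha)
        if steiger_res is not None:
            steiger_res = scale_to_doubling(steiger_res)
            sensitivity["steiger"].append(steiger_res)
        bundle["steiger"] = steiger_res

        hla_res = rerun_without_hla(hs)
        if hla_res is not None:
            hla_res = scale_to_doubling(hla_res)
            sensitivity["no_hla"].append(hla_res)
        bundle["no_hla"] = hla_res

        if hs.n_snp >= 3:
            loo = leave_one_snp_out(hs)
            bundle["leave_one_snp_out"] = [r.result for r in loo]
            for r in loo:
                loo_rows.append(
                    {
                        "condition": key[0],
                        "outcome": key[1],
                        "omitted_rsid": r.omitted_id,
                        "beta": r.result.beta,
                        "se": r.result.se,
                        "delta_vs_full": r.delta_vs_full,
                        "influential": r.influential,
                    }
                )
        else:
            bundle["leave_one_snp_out"] = None

        if config.duos and key[1] in config.duos:
            try:
                res = scale_to_doubling(mr_with_fetal_adjustment(hs, config.duos[key[1]]))
                sensitivity["fetal_adjusted"].append(res)
                bundle["fetal_adjusted"] = res
            except InsufficientInstrumentsError:
                bundle["fetal_adjusted"] = None

        if config.per_study_outcomes and key[1] in config.per_study_outcomes:
            exposure = config.exposures.get(key[0])
            if exposure is not None:
                inst = InstrumentSet.from_dataset(key[0], exposure)
                loso = leave_one_study_out(
                    config.per_study_outcomes[key[1]], inst, outcome_id=key[1]
                )
                loso_results = [scale_to_doubling(r.result) for r in loso]
                sensitivity["leave_one_study_out"].extend(loso_results)
                bundle["leave_one_study_out"] = loso_results

        bundles[key] = bundle

    if not main_results:
        raise ValueError("no condition-outcome pair could be analyzed")

    decisions = select_for_followup(main_results, alpha_fdr=config.alpha_fdr)
    robustness = [
        summarize_robustness(d, bundles[(d.condition_id, d.outcome_id)])
        for d in decisions
        if d.selected and (d.condition_id, d.outcome_id) in bundles
    ]

    # --- write stage tables ---
    results_to_frame(main_results).to_csv(
        out_dir / "results.tsv", sep="\t", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        [
            {
                "condition": d.condition_id,
                "outcome": d.outcome_id,
                "or_scaled": d.or_scaled,
                "beta": d.beta,
                "pval": d.pval,
                "criterion_i": d.criterion_i,
                "criterion_ii": d.criterion_ii,
                "by_adjusted_p": d.by_adjusted_p,
                "passes_fdr": d.passes_fdr,
                "selected": d.selected,
            }
            for d in decisions
        ]
    ).to_csv(out_dir / "decisions.tsv", sep="\t", index=False, float_format="%.10g")
    for label, results in sensitivity.items():
        if results:
            results_to_frame(results).to_csv(
                out_dir / "sensitivity" / f"{label}.tsv",
                sep="\t",
                index=False,
                float_format="%.10g",
            )
    loo_frame = pd.DataFrame(
        loo_rows,
        columns=["condition", "outcome", "omitted_rsid", "beta", "se",
                 "delta_vs_full", "influential"],
    )
    if not loo_frame.empty:
        loo_frame.to_csv(
            out_dir / "sensitivity" / "leave_one_snp_out.tsv",
            sep="\t", index=False, float_format="%.10g",
        )
    pd.DataFrame(
        [
            {
                "condition": r.condition_id,
                "outcome": r.outcome_id,
                "tier": r.tier,
                "discordant": ";".join(r.discordant),
                "unevaluable": ";".join(r.unevaluable),
            }
            for r in robustness
        ]
    ).to_csv(out_dir / "robustness.tsv", sep="\t", index=False)
    if audit_rows:
        pd.DataFrame(audit_rows).to_csv(
            out_dir / "harmonization_audit.tsv", sep="\t", index=False
        )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.fingerprint(),
        "n_pairs_analyzed": len(main_results),
        "n_selected": int(sum(bool(d.selected) for d in decisions)),
        "skips": skips,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return RunOutput(
        results=main_results,
        decisions=decisions,
        robustness=robustness,
        sensitivity=sensitivity,
        loo_snp=loo_frame,
        manifest=manifest,
    )
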