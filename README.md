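# liabilitymr

Two-sample Mendelian randomization (MR) of **genetic liability to binary
conditions** — autoimmune diseases in the motivating use case — on
**pregnancy outcomes**, working entirely at the GWAS summary-statistic
level.

MR uses genetic variants as instrumental variables: because alleles are
randomly assorted at meiosis, a variant robustly associated with an
exposure provides a comparison that is largely free of the confounding and
reverse causation that afflict observational estimates. In the two-sample
design, per-variant exposure associations β̂_xj (log-odds of the condition)
and outcome associations β̂_yj (log-odds of a binary pregnancy outcome, or
SD units for a continuous one) come from separate GWAS and are combined
per aligned effect allele.

## What the package does

- **Instrument selection** (`instruments`): genome-wide-significant
  variants (p < 5×10⁻⁸) pruned by greedy p-value-ranked LD clumping
  (r² < 0.001 within 10,000 kb against a pluggable LD matrix); mean
  pseudo-F instrument strength, F̄ = mean((β̂_x/se_x)²); HLA-region flags
  (chr6:28,477,797–33,448,354, GRCh37); cross-condition instrument-effect
  correlations.
- **Harmonization** (`harmonize`): aligns exposure and outcome records to
  one effect allele, resolving orientation swaps and strand complements
  and adjudicating palindromic (A/T, C/G) variants by allele frequency;
  pre-harmonized tables can be ingested directly.
- **Estimators** (`estimators`): Wald ratio; random-effects
  inverse-variance-weighted (IVW) mean of the Wald ratios with weights
  w_j = β̂²_xj/se²_yj, Cochran's Q, and a multiplicative overdispersion
  factor max(1, √(Q/(k−1))); MR-Egger (WLS with intercept — the intercept
  estimates directional pleiotropy); weighted median with a seeded
  parametric-bootstrap SE. Estimates are rescaled by ln 2 so they read as
  the effect of **doubling the odds** of the exposure condition.
- **Sensitivity** (`sensitivity`, `fetal_wlm`): Steiger directionality
  filtering; leave-one-SNP-out; leave-one-study-out over per-study outcome
  GWAS (fixed-effect re-meta-analysis); HLA-excluded reruns; and
  adjustment of maternal SNP-outcome effects for fetal genotype through
  the transmission model M = a + b/2, F = b + a/2 ⇒ a = (4M − 2F)/3.
- **Triage** (`inference`): two-tier follow-up selection — (i) p < 0.05,
  or (ii) OR > 1.05 or OR < 0.95 with p < 0.10 — plus Benjamini–Yekutieli
  FDR across the analysis grid and a directional-concordance robustness
  tier.
- **Synthetic data** (`simulate`): a seeded generator producing exposure/
  outcome summary statistics with known causal effect, pleiotropy regime,
  allele corruption, mother–child duos, and multi-study splits, so the
  whole pipeline is testable end to end without any downloads.
- **Pipeline + CLI** (`pipeline`, `cli`): `run_grid` orchestrates the full
  condition × outcome grid and writes one TSV per stage plus a manifest;
  the `mrliability` command exposes `simulate`, `estimate`, `triage`, and
  `run`.

## Worked example

```sh
mrliability simulate --seed 7 --out-prefix demo/sim
mrliability estimate --exposure demo/sim/exposure.tsv \
    --outcome demo/sim/outcome.tsv --seed 7 --out demo/results.tsv
```

prints

```
ivw_re: beta=0.0712 se=0.0064 OR=1.0738 (1.0604, 1.0873) p=8.11e-29 n_snp=100
egger: beta=0.0734 se=0.0176 OR=1.0762 (1.0398, 1.1139) p=6.29e-05 n_snp=100
weighted_median: beta=0.0648 se=0.0094 OR=1.0670 (1.0475, 1.0868) p=5.4e-12 n_snp=100
```

The synthetic pair was generated with a true causal effect of 0.1 per unit
log-odds of the condition; on the reported per-doubling scale that is
0.1 × ln 2 ≈ 0.069, and all three estimators land near it: the outcome's
odds rise by about 7% per doubling of the odds of the condition, with the
pleiotropy-robust MR-Egger and weighted-median estimates agreeing with the
main IVW estimate and an Egger intercept near zero (no directional
pleiotropy was simulated). `mrliability triage` then applies the follow-up
rule and BY-FDR to a grid of such results.

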