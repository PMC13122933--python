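# Methods

## Model

For instrument j, let β_xj be the association with the exposure condition
(log-odds of liability per effect-allele copy) and β_yj the association
with the outcome (log-odds for binary outcomes, SD units for continuous
ones), with standard errors se_xj, se_yj estimated in non-overlapping
samples. Under the instrumental-variable assumptions, each Wald ratio
θ̂_j = β̂_yj/β̂_xj estimates the causal effect θ of exposure liability on
the outcome.

**IVW.** The main estimator is the inverse-variance-weighted mean of the
Wald ratios with first-order weights w_j = β̂²_xj/se²_yj, algebraically the
slope of a zero-intercept weighted regression of β̂_y on β̂_x. Between-
instrument heterogeneity is measured by Cochran's Q = Σ w_j(θ̂_j − θ̂)²
with k − 1 degrees of freedom. The random-effects variant used here is the
multiplicative one: the fixed-effect standard error (Σw)^(−1/2) is
inflated by max(1, √(Q/(k−1))), so heterogeneity can widen but never
tighten intervals. IVW p-values use the normal approximation.

**MR-Egger.** Weighted least squares of β̂_y on β̂_x *with* an intercept
(weights 1/se²_y), after orienting every instrument so β̂_x > 0. The
intercept estimates the mean directional pleiotropic effect; the slope is
a causal estimate that remains consistent under directional pleiotropy
provided pleiotropic effects are independent of instrument strength
(the InSIDE condition). Both standard errors carry the residual factor
max(1, √(RSS_w/(k−2))) and inference uses the t distribution with k − 2
degrees of freedom — the conventional behaviour of the widely used MR
software this package is interoperable with. The normal equations are
solved explicitly; an independent statsmodels WLS fit serves as the test
oracle.

**Weighted median.** Per-SNP ratios sorted by value; the estimate is the
linear interpolation of θ̂ at cumulative-weight midpoint 0.5 (IVW weights,
normalized). It is consistent whenever instruments carrying at least half
the total weight are valid. The standard error comes from a parametric
bootstrap (default 1000 draws) resampling β̂_x and β̂_y about their
observed values; the seed is a required argument so results are exactly
reproducible.

**Per-doubling scaling.** Estimates for binary exposures are multiplied,
together with their standard errors, by ln 2 ≈ 0.693, converting "per unit
log-odds of liability" into "per doubling of the odds of liability"; 95%
intervals use ±1.96 on the scaled values and the p-value is unchanged
(z is invariant under positive scaling). Odds and risks of the rare binary
outcomes are treated as interchangeable; no rare-disease correction is
applied.

## Harmonization rules

Matching is by rsid. Identical allele pairs are kept as-is (same
orientation) or with the outcome beta negated and eaf complemented
(swapped orientation). Pairs that match only under A↔T/C↔G complement are
strand-corrected first. Palindromic pairs (A/T, C/G) cannot be resolved by
allele labels: if both datasets report an effect-allele frequency whose
minor-allele frequency is below 0.42 (configurable), frequencies on the
same side of 0.5 confirm the orientation and opposite sides imply a flip;
otherwise the variant is dropped as ambiguous. Instruments absent from the
outcome dataset are audited as missing — no proxy-variant search is
attempted, so the instrument set stays exactly auditable against its
sources. Every removal is a recorded disposition, never an exception.

## Sensitivity analyses

- **Steiger filtering** removes instruments that explain significantly
  more variance in the outcome than the exposure. Each side's trait
  correlation is proxied by r = z/√(z² + n) from that side's z-statistic
  and sample size — a deliberately symmetric choice that puts binary and
  continuous traits on a common footing (an eaf-aware alternative can be
  plugged in). Because the two GWAS samples are independent, the
  comparison uses the two-sample Fisher z-test,
  z = (atanh r_x − atanh r_y)/√(1/(n_x−3) + 1/(n_y−3)), one-sided at
  α = 0.05. Ties and unevaluable SNPs (missing or tiny n) are retained.
  Downstream estimation uses IVW with ≥ 2 surviving SNPs and the Wald
  ratio with exactly one.
- **Leave-one-SNP-out** recomputes IVW omitting each instrument. The
  "influential" flag has no canonical numeric definition; the default rule
  — omission flips the estimate's sign or moves it by more than 50% of its
  magnitude — is explicit configuration, and all deltas are always
  reported so users can apply their own rule.
- **Leave-one-study-out** re-combines per-SNP outcome associations across
  the remaining studies by fixed-effect inverse-variance meta-analysis and
  reruns IVW; SNPs covered by no remaining study are dropped.
- **HLA exclusion** reruns estimation without variants in
  chr6:28,477,797–33,448,354 (GRCh37, 1-based inclusive), a long-range-LD
  region whose immune-gene pleiotropy can violate the exclusion
  restriction.
- **Fetal-genotype adjustment.** A maternal variant is transmitted to the
  fetus with probability ½, so marginal maternal and fetal GWAS effects
  mix the direct effects a (maternal) and b (fetal): M = a + b/2,
  F = b + a/2. Solving gives a = (4M − 2F)/3 with
  var(a) = (16 se²_M + 4 se²_F − 16 cov(M,F))/9; cov defaults to 0
  (independent samples) and is accepted per SNP. The coefficient set is a
  single configuration point so an alternative weighting can be swapped
  in. IVW is then rerun on the adjusted associations.

## Triage

Condition–outcome results on the per-doubling scale are selected for
follow-up when (i) p < 0.05 or (ii) the odds ratio exceeds 1.05 or falls
below 0.95 with p < 0.10 (strict inequalities; the OR criterion applies to
binary outcomes only). The rationale: in a hypothesis-driven setting with
clinically important but rare outcomes, modest effects with moderate
support still merit scrutiny. Multiplicity is handled by the
Benjamini–Yekutieli step-up procedure (statsmodels implementation,
validated against a brute-force oracle), which controls FDR under
arbitrary dependence — appropriate because conditions share risk loci and
outcomes are correlated. The FDR family is the grid of results passed in.
The robustness tier codifies a narrative judgment as an explicit rule —
"robust" iff every available sensitivity estimate shares the main
estimate's direction and no single-SNP omission flips it; missing analyses
are recorded as unevaluable, never as failures — and is advisory output.

## Synthetic-data generator

The generator works directly at the summary-statistic level (the level the
analysis consumes); no individual genotypes are simulated. Defaults
describe a well-powered binary exposure GWAS against a large binary
outcome meta-analysis:

| parameter | default | meaning |
|---|---|---|
| k | 100 | instruments |
| theta | 0.1 | causal effect (outcome log-odds per exposure log-odds) |
| maf_range | (0.05, 0.45) | minor-allele frequencies, uniform |
| exposure_effect_sd | 0.15 | spread of true instrument effects (typical per-allele OR ≈ 1.16, consistent with the large effect sizes of autoimmune loci) |
| n_exp / case fraction | 100,000 / 0.20 | exposure GWAS size |
| n_out / case fraction | 200,000 / 0.05 | outcome GWAS size (rare outcome) |
| pleiotropy mean/sd, invalid_fraction | 0 / 0 / 0 | horizontal pleiotropy regime |
| fetal_direct_sd | 0 | spread of direct fetal effects b_j |
| corruption rates | 0 | allele swap / strand flip / palindromic insertion |

Per SNP: se_x = 1/√(2·maf(1−maf)·n·φ(1−φ)) with φ the case fraction; the
true effect γ_j is half-normal (effect alleles oriented to the
liability-increasing allele) and both the true and the observed effect are
rejection-sampled past the genome-wide z threshold (≈5.45), mirroring the
fact that only variants whose measured association passes p < 5×10⁻⁸
enter an instrument list. Pleiotropic effects α_j ~ N(μ_α, σ_α²) are drawn
independently of γ_j (InSIDE) for the invalid fraction; the true outcome
effect is θγ_j + α_j. Allele corruption (orientation swaps with beta
negation, strand complements, palindromic allele pairs with clearly
informative frequencies) is layered onto the outcome dataset so the
harmonization stage has real repairs to perform. Study splits inflate
per-study SEs as se/√w_s with betas constrained so the fixed-effect
meta-analysis of the splits reproduces the pooled dataset exactly.

What the generator does **not** emulate: LD between instruments, winner's
curse (selection is conditioned on the truth as well as the observation),
sample overlap between exposure and outcome GWAS, and assortative-mating
or dynastic confounding. Passing recovery tests therefore show the
estimators and pipeline are correct under the stated generative
assumptions, not that real-data estimates are unbiased.

## Numerical choices and problem sizes

95% intervals use 1.96 (normal) except MR-Egger (t, k − 2 df). P-values
are floored at the smallest positive double and capped at 1. Clumping ties
on p are broken by lexicographic rsid, making instrument selection
invariant to input row order; pairs missing from the LD matrix are treated
as correlated (discarded), degrading to distance-only pruning with a
logged warning. Zero exposure effects exclude a pair from ratio-based
estimators with a warning. Monte-Carlo suites use 60–200 replicates at
k = 100 — enough for the ≈4-standard-error bias bands and the
0.95 ± 0.03 coverage band to be discriminating while the full test suite
and the acceptance script each run in well under a minute.

## Known limitations

The Steiger correlation proxy ignores allele frequency, which shifts
per-SNP r² for binary traits (direction comparisons are unaffected when
both sides use the same proxy). The weighted-median bootstrap is
parametric, not resampling-based. Liability-scale estimates have no direct
clinical magnitude interpretation; direction and robustness are the
meaningful outputs. The phenome-wide adjudication of influential variants
is out of scope: the package reports influence flags and deltas, and any
annotation-based pleiotropy judgment is left to a local lookup by the
user.
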