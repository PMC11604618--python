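# Methods

## Scope and data model

`tsmr` operates entirely on GWAS summary statistics: one delimited table
per trait with one row per SNP (rsid, chromosome, position, effect and
other allele, effect-allele frequency, beta, SE, p, n), following the
GWAS-SSF column vocabulary with a user-supplied column map for dialects.
Betas are per-effect-allele additive effects — log odds ratios for binary
traits, standardized units otherwise. SNPs are matched across traits by
rsid only; positional matching and liftover are out of scope. Duplicate
rsids keep the first occurrence and are logged.

## Harmonization

Outcome (and mediator) associations are aligned to the exposure's effect
allele. Swapped alleles negate the beta and reflect the allele frequency;
strand complements (A↔T, C↔G) are resolved before comparison.
Palindromic SNPs (A/T or C/G pairs) cannot be strand-resolved from
alleles, so the default policy excludes them. The optional `eaf_infer`
policy orients palindromic SNPs by allele frequency and drops them only
when either side's frequency falls in [0.42, 0.58], where orientation is
unreliable. Every input rsid leaves harmonization exactly once — retained
or carrying a drop reason — so filter accounting is exact.

## Instrument selection

The chain is: exposure p-value threshold (default 1×10⁻⁵, strict `<`;
5×10⁻⁵ for reverse MR where the disease is the exposure) → greedy LD
clumping (retain the smallest-p SNP, ties broken lexically by rsid for
determinism; remove same-chromosome SNPs within 10,000 kb at r² ≥ 0.001)
→ harmonization with palindrome exclusion → instrument-strength filter
F = β²/SE² > 10. The F filter runs after harmonization so the reported
instrument count equals the analyzed set. When no LD matrix is given,
`assume_independent` keeps all SNPs with a warning (sensible for
pre-clumped instrument lists); `distance_only` prunes by window alone.
Per-stage survivor counts are recorded and are non-increasing by
construction.

## Estimators

All estimators consume a harmonized table and report the effect on the
log-odds scale plus OR = exp(β) with a 95 % normal CI.

* **Wald ratio** β_out/β_exp with first-order SE se_out/|β_exp|
  (exposure-side variance ignored, the standard two-sample convention).
* **IVW** — weighted regression of β_out on β_exp through the origin,
  weights 1/se_out², equivalently the w-weighted mean of Wald ratios with
  w = β_exp²/se_out². Fixed-effect SE is (Σw)^(−1/2); the multiplicative
  random-effects variant scales it by max(1, √(Q/(J−1))) and is the
  primary reported estimate (it can widen but never shrink the CI).
  Both variants are always available.
* **MR-Egger** — instruments oriented so all β_exp ≥ 0, then WLS of
  β_out on β_exp with a free intercept. Coefficient SEs use the residual
  variance floored at 1 (the multiplicative model is not allowed to
  deflate uncertainty); p-values use Student-t with J−2 df, reflecting
  the small-J regression setting. Every other method uses the normal
  reference; this asymmetry is deliberate.
* **Weighted median** — Wald ratios sorted, weights 1/se_wald²
  normalized; the estimate interpolates the ratio at cumulative weight
  0.5, with the cumulative weight at ratio j taken as the running sum
  minus half its own weight. SE by parametric bootstrap: both β_exp and
  β_out are resampled from their stated normals, the statistic
  recomputed, and the SD over `n_boot` draws (default 5,000) reported.
  A seed is mandatory for every bootstrap; identical seeds give
  identical results.
* **Mode-based estimators** — normal-kernel density over the Wald
  ratios, weights uniform (simple) or 1/se_wald² (weighted); bandwidth
  h = φ·0.9·min(sd, MAD/0.6745)·J^(−1/5) with φ = 1 by default; the
  estimate is the density argmax on a 512-point grid spanning the ratios
  ± 3h. When all ratios coincide the bandwidth degenerates and that
  ratio is returned with SE 0 (documented degenerate path). SE by the
  same parametric bootstrap.
* **Multivariable IVW** — WLS of β_out on (β_exp, β_med) without
  intercept, weights 1/se_out², yielding conditional effects of exposure
  and mediator. A weighted-design condition number above 10⁸ raises a
  collinearity error; an exactly zero column is degenerate-but-defined
  (pseudo-inverse gives a zero coefficient), which makes the
  zero-mediator case reduce exactly to univariable IVW.

## Diagnostics

**Cochran's Q** = Σ w_j(θ̂_j − θ̂_IVW,FE)² with w = 1/se_wald², upper-tail
χ²(J−1) p-value; per-SNP contributions sum to Q exactly. **Egger
intercept test** flags directional pleiotropy at p < 0.05.
**Leave-one-out** refits IVW with each instrument removed.

**MR-PRESSO**: for each instrument j the IVW slope β₋ⱼ is fit without
it; the observed weighted residual sum of squares is compared with
`n_sim` parametric simulations (β_exp* ~ N(β_exp, se_exp), β_out* ~
N(β₋ⱼ·β_exp, se_out), leave-one-out slopes recomputed per simulated
dataset, fully vectorized). The add-one rule (1 + #{RSS* ≥ RSS})/(n_sim
+ 1) keeps p-values off zero, so the smallest attainable global p is
1/(n_sim+1). Per-SNP outlier p-values come from each instrument's own
simulated residual distribution, Bonferroni-adjusted by J, flagged below
0.05. The corrected estimate is random-effects IVW on the non-outliers.
The distortion test compares the raw-vs-corrected displacement against
random same-size-subset removals (1,000 draws); it is implemented but
experimental, as no reference values exist to calibrate it against.
Default `n_sim` is 1,000 at desk scale; 10,000 is the recommended
production setting.

## Screening and direction

`batch_screen` runs every exposure against the outcome, never letting a
single failure abort the batch (empty-instrument exposures become
skipped rows). Findings are tiered per exposure group: IVW p below
α/n_group (Bonferroni; n_group defaults to the number of traits tested
in the group, with a hook for an externally computed effective number)
→ `bonferroni_significant`; below α = 0.05 → `suggestive`; otherwise
null. The consistency flag requires sign agreement of IVW, weighted
median and Egger — the criterion is direction, not magnitude, since no
metric beyond agreement is standard. Pairs failing the MR-PRESSO global
test or the Egger intercept at 0.05 are downgraded to null with a
reason code. Single-instrument pairs use the Wald ratio, skip the
multi-instrument diagnostics and are capped at the suggestive tier.
Reverse MR re-runs the battery with the disease as exposure (P < 5×10⁻⁵
instruments, same clumping); `direction_filter` labels surviving pairs
`forward_only` (reverse p ≥ 0.05) or `bidirectional`, and only
forward-only pairs are eligible for mediation. Per-exposure randomness
derives deterministically from one seed, so reruns are identical.

## Mediation

Two-step MR with product-of-coefficients decomposition: total from
exposure→outcome IVW, β1 from exposure→mediator IVW (exposure
instruments), β2 from mediator→outcome IVW (mediator instruments) or,
with `b2_mode="mvmr"`, the conditional mediator coefficient from
multivariable IVW on the union of instruments. Univariable β2 is the
default because the decomposition arithmetic is then exactly the
product/difference of the reported leg estimates; the MVMR variant is
provided and labeled. `direct + indirect = total` holds by construction
(direct is defined as the difference). The proportion mediated is
reported signed — under inconsistent mediation (indirect opposing the
total) it is negative and flagged, never silently absolute-valued. The
indirect-effect SE uses the delta method; a zero total effect marks the
proportion undefined (NaN) while all other fields remain valid.
Eligibility (both legs direction-filtered `forward_only`) is enforced
when the caller supplies the direction verdicts, raising an error that
names the failing leg.

## Synthetic data generator

The generator emulates the statistical structure of a two-sample MR
study without individual-level data: summary statistics are simulated
directly, which keeps every pipeline stage testable at desk scale. Per
SNP, maf ~ Uniform(0.05, 0.5); the true instrument effect γ comes from a
configurable normal (default mean 0.3, sd 0.05 — the strength of
selected genome-wide hits, giving F ≫ 10) or a fixed list; exposure SE
follows the quantitative-trait law 1/√(2p(1−p)·n); the outcome SE uses
the binary-trait approximation 1/√(2p(1−p)·N·φ(1−φ)) with case fraction
φ. Default sample sizes mirror the study scale the package targets:
5,959 for the exposure GWAS and 1,748 cases / 454,600 controls for the
outcome; the mediator defaults to 5,000, a typical immune-trait GWAS
scale. Observed betas are the true per-trait means plus normal noise at
the stated SE; the outcome mean is (θ + β1β2)·γ + α with pleiotropy α
per model (`none`, `balanced`, `directional`, `inside_violating` with
tunable correlation to instrument strength). Optional blocks add
mediator-specific and outcome-specific instruments with their own
effect sizes — required for a meaningful mediator→outcome leg and for
reverse MR, where the disease needs its own genome-wide hits — plus a
reverse-direction effect for bidirectional systems. LD blocks replicate
index-SNP signals with attenuation √r² and record r² in the block-
diagonal LD matrix; palindromic variants and outcome-side allele flips
exercise harmonization; planted outliers displace outcome betas by a
chosen number of SEs and record their identities in the truth record.
All randomness flows from a single seed (byte-identical reruns), and
the truth record always satisfies total = θ + β1·β2 exactly.

What the generator does **not** emulate: realistic allele-frequency
spectra and genome-wide LD (blocks are idealized), winner's curse in
instrument discovery, sample overlap between GWAS, and non-normal
effect-size distributions. Passing tests therefore demonstrate
statistical correctness of the pipeline under its stated model, not
robustness to every pathology of real cohort data.

## Problem sizes and numerical choices

The test and acceptance suites use desk-scale problem sizes chosen as
the package's own defaults: 8–50 instruments per trait, 100–200
Monte-Carlo replicates for calibration claims, 1,000 MR-PRESSO
simulations, and bootstrap sizes of 100–1,000 inside replicated runs
(5,000 for a single production estimate). Two-sided p-values are floored
into (0, 1]; simulated p-values are clipped at 10⁻³⁰⁰; bootstrap draws
that produce a zero exposure beta are nudged to the smallest positive
float rather than dropped. Exact-fit regressions (zero residual
variance) return zero-variance coefficients instead of NaNs. Clumping
ties on p are broken lexically by rsid, making results independent of
input row order.

## Known limitations

Correlated-instrument IVW with full LD weighting, Steiger filtering,
radial MR, MR-RAPS and multi-mediator joint decomposition are not
implemented. The Wald SE ignores exposure-side variance, so weak
instruments (F near the threshold) attenuate estimates slightly toward
the null — visible as a sub-percent bias in the recovery suites. The
MR-PRESSO distortion p-value is experimental. Proportions mediated are
only interpretable when the total effect is well separated from zero.
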