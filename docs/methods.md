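# Methods

## Model and assumptions

`netmr` implements two-sample Mendelian randomization: SNP–exposure and
SNP–outcome associations come from non-overlapping GWAS samples, and each
retained SNP is assumed to be (i) associated with the exposure, (ii)
independent of confounders, and (iii) affecting the outcome only through
the exposure (no horizontal pleiotropy) — with the sensitivity estimators
and diagnostics quantifying how results degrade when (iii) fails. Binary
traits are modelled on the natural-log odds scale throughout; odds ratios
in reports are exp(β).

The network design decomposes an exposure→outcome effect through one
mediator at a time: the indirect effect is the product of the
exposure→mediator and mediator→outcome MR estimates, assuming no
exposure–mediator interaction and homogeneous effects. Multiple mediators
are never decomposed jointly; correlated mediators are handled by pairwise
multivariable models instead.

## Estimators and their numerics

**IVW (multiplicative random effects).** Weighted regression of β̂ᵧ on β̂ₓ
through the origin, weights 1/se(β̂ᵧ)². The SE is scaled by
σ̂² = Q/(J−1) with *no* floor at 1: balanced heterogeneity widens the
interval and genuinely homogeneous data narrow it. A floored variant
(`floor_variance=True`) exists for cross-checking against implementations
that never go below the fixed-effect SE. CIs and p-values use normal
quantiles. J = 1 degrades to the Wald ratio β̂ᵧ/β̂ₓ with first-order SE
se(β̂ᵧ)/|β̂ₓ| (the second-order term is omitted; the same convention feeds
the weighted-median weights). An exact fit (Q = 0) yields SE 0 and a
degenerate point interval — reported as-is rather than patched.

**MR-Egger.** SNPs are first oriented so every β̂ₓ ≥ 0 (required by the
InSIDE framing), then weighted regression with a free intercept; intercept
and slope inference uses the t distribution with J−2 df and the same
unfloored residual scaling. Directional pleiotropy is declared at
intercept p < 0.05.

**Weighted median.** Per-SNP ratios sorted, cumulative standardized
weights pⱼ = (Σ_{k≤j}w_k − wⱼ/2)/Σw interpolated linearly at 0.5. The SE
is a parametric bootstrap (β̂ₓ*, β̂ᵧ* resampled from their normal sampling
distributions), which requires an explicit seed; n_boot defaults to 1000.

**MR-PRESSO.** Observed statistic RSS = Σⱼ wⱼ(β̂ᵧⱼ − θ̂₍₋ⱼ₎β̂ₓⱼ)² with
leave-one-out IVW estimates; null distribution by parametric simulation
(default n_sim 5000 in pipeline runs, 1000 in tests — the empirical p is
floored at 1/(n_sim+1), which is also its resolution). Per-SNP outlier
p-values are Bonferroni-adjusted by J and flagged below 0.05; IVW is
refit without flagged SNPs. The distortion test of the original procedure
is not implemented — only the global and outlier tests feed the pipeline,
and the corrected estimate replaces raw IVW downstream only when the
global p < 0.05. Outlier removal is a robustness device, not a guarantee:
across simulated systems it reduces the aggregate error of the estimate,
but in any single draw the corrected estimate can land farther from the
truth than the raw one.

**MVMR.** Multivariable IVW through the origin with σ̂² = Q/(k−L), no
floor, normal p-values. Cross-trait sampling covariance between exposure
estimates is assumed zero (exposures estimated in distinct cohorts); a
rank check raises a collinearity error naming the offending exposure pair
rather than returning an arbitrary split. The conditional F-statistic for
exposure j regresses its SNP effects on the other exposures' effects with
weights 1/se(β̂ₓⱼ)² and divides the weighted residual sum of squares by
(k − L + 1) — the simplified independent-samples form, recorded in output
metadata as the implemented variant.

**Mediation.** Indirect effect a·b with delta-method variance
a²·Var(b) + b²·Var(a), treating the two MR estimates as independent
(two-sample design; the shared-exposure covariance between the
exposure→mediator and total-effect estimates is likewise ignored and is a
documented approximation). The proportion mediated uses the analogous
ratio variance and is suppressed — not zeroed — when the indirect effect
is non-significant or opposite-signed to the total effect, since the ratio
is uninterpretable there. Tiers: MVMR-surviving **and**
significant-positive mediation → strong; exactly one → moderate; neither
→ potential.

## Instrument processing

Candidates pass a p-value threshold (5×10⁻⁸ default; 1×10⁻⁵ for
metabolites, whose GWAS is an order of magnitude smaller), then greedy LD
clumping: lowest-p SNP indexes a clump, removing same-chromosome SNPs
within 10,000 kb at r² ≥ 0.001. Ties on p are broken by (chrom, pos, id)
so output is independent of input order; pairs with unknown LD default to
"independent" with a warning (configurable to "dependent"). Harmonization
drops palindromic (A/T, C/G) SNPs unconditionally — no allele-frequency
rescue — and variants are matched by ID, not position. The Steiger filter
converts per-SNP variance explained to correlations and removes SNPs whose
outcome correlation significantly exceeds their exposure correlation
(one-sided Fisher-z test, α = 0.05 default; the multi-exposure convention
takes each SNP's strongest exposure association). Binary traits use the
effective sample size 4/(1/n_case + 1/n_control). Aggregate R² ≥ 0.9 is
flagged "aberrant" and the trait excluded; F ≤ 10 excludes as weak.

## Pipeline screening order

Step-2 metabolite associations are screened in narrative order: nominal
IVW p < 0.05 → exclusion of associations with Egger intercept p < 0.05 →
MR-PRESSO correction where the global test fires → Bonferroni
(α / number of metabolites with valid instruments; 302-sized families
reproduce the 1.66×10⁻⁴ threshold) combined with weighted-median p < 0.05
for "credible" status. "Suggestive" survivors feed step 3, mediation,
pairwise MVMR against |r| > 0.2 partners, and pathway enrichment
(upper-tail hypergeometric including the observed count, no
multiple-testing correction across pathways). All per-pair seeds derive
deterministically from the run seed and the trait labels, so reports are
byte-identical across reruns.

## The synthetic generator

Summary statistics are drawn directly at the estimate level — no
individual-level genotypes — because two-sample MR consumes only summary
data and this keeps runtimes at desk scale. Per SNP: allele frequency
f ~ U(0.05, 0.5), SE = sd_trait/√(2·N·f(1−f)), β̂ ~ Normal(truth, SE),
Wald p-values. True effects follow the diagram
γ·(θ_direct + θ_XM·θ_MY) + δ·θ_MY + α for the outcome, γ·θ_XM + δ for
mediators.

Default conditions (one choice, held fixed): 100 exposure instruments with
per-SNP log-OR ±U(0.06, 0.12) — jointly ≈ 33% pseudo-variance explained, a
strongly instrumented binary trait that still clears the aberrant-R² gate;
30 mediator instruments ±U(0.02, 0.05) on a log10-unit scale with
metabolite SD 0.15 and cohort N = 7824 (the size of the metabolomic GWAS
this emulates); binary exposure 80k/120k cases/controls and outcome
50k/1.5M, matching the non-overlapping large-consortium design; causal
coefficients θ_XM = 0.05, θ_MY = 0.5, θ_direct = 0.02 in the mediation
scenario (true indirect 0.025, 55.6% of the total). Named scenarios plant
one anomaly each: directional pleiotropy (α = 0.05 on every exposure SNP),
a single 10·SE outlier among 20 instruments, reverse-causal SNPs with
effects only in the outcome layer, near-null instruments in a 5k cohort
(F < 10), and a correlated mediator pair sharing 60% of instruments.

What the generator does **not** emulate: realistic LD from reference
panels (blocks are exchangeable with a single within-block r²; non-lead
SNPs tag the lead at √r² attenuation), winner's-curse selection at the
significance margin, sample overlap between cohorts, non-normal effect
distributions, and liability-scale subtleties of binary traits. Passing
tests therefore demonstrate correctness of the estimators and screening
logic under the stated sampling model, not robustness to every
pathology of real GWAS data.

## Known limitations

- No LD-aware (correlated-instrument) IVW, mode-based estimators,
  MR-RAPS, or MVMR-Egger.
- Delta-method mediation CIs are first-order; with weakly estimated legs
  (|β|/se < 3) they can undercover, and the unfloored multiplicative-RE
  SE makes IVW intervals slightly anti-conservative at moderate J (the
  calibration tests bound this at 93–97% coverage for J = 50).
- Proportions mediated inherit the instability of ratio estimates when
  the total effect is weak.
- No genome-build liftover or strand inference; inputs must share variant
  IDs and allele coding conventions.
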