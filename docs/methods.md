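# Methods

This note documents the statistical models the package implements, the
conventions chosen where several are defensible, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Study design

The analysis is one-sample, summary-level Mendelian randomization: genetic
variants associated with dietary intake of a micronutrient (phosphorus,
vitamin B2, B6 or C) serve as instrumental variables for that intake, and
their associations with incident chronic kidney disease (eGFR declining
below 60 mL/min/1.73 m² during follow-up) identify the causal effect of
intake on CKD risk under the usual IV assumptions: relevance, independence
from confounders, and exclusion restriction (no effect on CKD except
through intake). The per-instrument inputs are the quadruples
(γ̂_j, σ_xj, Γ̂_j, σ_yj) on a common effect allele, produced by the
harmonization step.

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
allele labels flip the outcome beta's sign and complement its frequency;
alleles reported on the opposite strand are base-complemented first.
Palindromic (A/T, C/G) variants cannot be strand-resolved from alleles
alone, so they are dropped when the exposure effect-allele frequency lies
in a configurable intermediate band, default [0.40, 0.60] — the common
convention; the source analysis states the exclusion without a band.
Palindromic SNPs with missing frequency are dropped (conservative). Every
drop is logged with a reason code, and instruments + exclusions always
partition the SNP intersection.

## Instrument selection

Four deterministic stages: (1) suggestive exposure significance, p < 1e-5
strictly; (2) greedy LD clumping — keep the smallest-p SNP, discard SNPs
with r² ≥ 0.1 within 250 kb on the same chromosome, ties broken by
(chrom, pos, snp_id) so the result is order-independent; the source states
clumping without parameters, so both are configurable; (3) an
outcome-association screen dropping instruments with two-sided normal
outcome p < 1e-5 (the source says instruments "unrelated" to CKD were
kept; the mirror of the exposure threshold is the documented
operationalization); (4) a mapped-phenotype screen keeping instruments
with at least one dietary-intake annotation (substring "intake" by
default), with unannotated SNPs kept — no positive evidence of pleiotropy.
The packaged instrument tables retain SNPs also mapped to non-dietary
traits (HDL, BMI, cancers), which is why the rule is keep-if-any-dietary
rather than drop-if-any-non-dietary. The published upstream counts
(e.g. 147 → 19 → 11 for phosphorus) are not reproducible without the
unpublished LD structure and annotation judgments; the packaged final sets
(11/13/11/10 SNPs) are the regression target, and the cascade verifies it
keeps all of them.

## Estimators

All p-values are two-sided standard normal on β̂/SE.

- **IVW** is fixed-effect with first-order weights w_j = γ̂_j²/σ_yj². This
  convention reproduces the published SEs exactly (e.g. 1.623 vs printed
  1.624 for vitamin B6); a multiplicative random-effects model would not.
- **Radial IVW** defaults to modified second-order weights
  w_j = (σ_yj²/γ̂_j² + β̂²σ_xj²/γ̂_j²)^(−1), iterated to convergence from
  the first-order solution; with first-order weights the slope is
  algebraically identical to IVW (asserted in tests). The SE uses the
  radial regression's estimated residual variance, SE_radial =
  SE_IVW·√(Q/(k−1)) — the only convention consistent with the published
  radial SEs being smaller than the IVW SEs under low heterogeneity (Q < k−1).
  Per-SNP Q_j contributions and χ²(1)-based outlier flags are exposed.
- **MR-Egger** first orients every instrument to γ̂_j > 0 (a joint sign
  flip, leaving Wald ratios unchanged), then fits weighted least squares
  with an intercept, weights 1/σ_yj². The covariance is scaled by the
  estimated residual variance floored at 1; the floor reproduces the
  published intercept SEs on all four instrument sets.
- **Medians**: ratios sorted ascending; the weighted median interpolates
  the ratio where the cumulative mid-point weight crosses one half; an
  even-count simple median averages the middle two. The penalized variant
  computes one-step heterogeneity contributions about the weighted-median
  estimate and multiplies weights by min(1, 20·q_j), q_j the upper χ²(1)
  tail — inactive when no SNP is outlying. Median SEs come from a
  parametric bootstrap (resample γ̂_j, Γ̂_j from normals with their SEs;
  default 5,000 replicates, seed recorded in every report).
- **MR-PRESSO**: observed RSS uses leave-one-out IVW predictions with
  outcome weights 1/σ_yj²; the null is simulated by redrawing
  Γ*_j ~ N(β̂₍₋ⱼ₎γ̂_j, σ_yj) and recomputing the leave-one-out RSS, with
  global p = (1 + #{RSS* ≥ RSS_obs})/(nsim + 1), default nsim 10,000.
  Per-SNP outlier p-values compare each observed weighted residual with
  its own simulated distribution, Bonferroni-flagged. The distortion test
  is not implemented (not part of the reported analysis).

Known non-reproducibilities, reflected in the comparison tolerances: the
published Egger slope for vitamin B6 (−4.477) is not recoverable from the
printed per-SNP values under any orientation convention (the same oriented
fit reproduces the published intercept −0.026 exactly), so the slope is
reported but not checked; the published weighted medians differ by ~2%
from the standard interpolation on the printed (rounded) inputs and are
checked at ±0.1; the MR-PRESSO p-values for nutrients other than vitamin
B6 were published without simulation settings and two of them sit outside
any plausible Monte-Carlo band of our recomputation, so only the B6 value
is checked (band [0.90, 0.99] around the published 0.953).

## Phenotyping

eGFR follows the 2009 CKD-EPI creatinine equation (no race coefficient):
141·min(Scr/k,1)^α·max(Scr/k,1)^(−1.209)·0.993^Age·1.018[female], k = 0.7/0.9
and α = −0.329/−0.411 for women/men. Incident CKD is the first follow-up
visit with eGFR < 60 among subjects ≥ 60 at baseline; no confirmatory
second measurement is required (a single-crossing definition), eGFR is not
rounded before comparison, and age is taken per visit. The classifier
partitions any cohort into excluded-at-baseline / incident case / non-case.

## Polygenic-score validation

PRS_s = Σ_i β_i·dosage_si with GWAS effect sizes as weights and no
standardization (the formula is an unstandardized weighted sum). Missing
dosages are mean-imputed per SNP by default with the count logged; a
strict mode errors instead. The score-vs-intake regression is closed-form
simple least squares with a t reference. The published PRS slopes (10.596,
0.020, 0.016, 2.492) require the restricted cohort; the package instead
verifies slope recovery on synthetic data at the vitamin-B6 scale (0.016).

## Synthetic cohort generator

Defaults mirror the study conditions where stated: 5,078 subjects, 708
incident cases (fraction 0.1394), biennial visits over 12 years, baseline
age ≈ N(51.8, 8.3) clipped to the cohort's 40–70 recruitment range, 52.6%
female, per-SNP intake effects with |γ| ∈ [0.015, 0.1] (the printed
instrument range), instruments jointly explaining 2% of exposure variance
(a weak-instrument regime typical of dietary traits, and the regime the
source flags as a limitation), and a causal effect defaulting to −4.0, the
vitamin-B6 scale of effect. Genotypes are drawn in exact Hardy–Weinberg
proportions by thresholding a latent Gaussian (equicorrelated within
optional LD blocks). The outcome is a continuous liability
β·exposure + δ'g + λ·confounder + noise, with direct SNP effects δ under
three pleiotropy modes (none / balanced / directional, InSIDE holding);
cases are the top liability quantile, exactly matching the target count.
Creatinine trajectories are manufactured by inverting the CKD-EPI equation
at prescribed eGFR targets (cases cross below 60 at a random follow-up
visit; non-cases stay above 65) plus ~1% multiplicative assay noise, so
the phenotype classifier recovers the liability-defined cases exactly.

What the generator does not emulate: realistic LD maps, imputation error,
chip-specific missingness, assortative mating or population structure, FFQ
measurement error structure, and — deliberately — logistic
non-collapsibility: estimator-calibration runs scan the continuous
liability rather than the thresholded case indicator, because the per-SNP
log-odds effects of a binary scan are attenuated relative to β on the
liability scale and β would no longer be the estimand. A binary logistic
scan (with a score-test fallback under separation) is provided and used
where a case/control GWAS is the point. Passing calibration therefore
shows the estimators are correct and well-calibrated under their own
assumptions, not that the restricted cohort's numbers would re-emerge.

GWAS scans are unadjusted additive regressions (the source's covariate
model is unstated). QC drops SNPs at call rate < 95%, MAF < 1% or
Hardy–Weinberg χ²(1) p < 5e-5; the chi-square test replaces the source's
under-specified permutation test — at this threshold only the rejection
level matters.

## Problem sizes and numerics

Calibration runs use 200 replicates of 5,000 subjects × 50 instruments
(the acceptance suite) — large enough that Monte-Carlo SEs are a few
percent of the effect, small enough to run in well under a minute apiece.
The radial iteration stops at |Δβ̂| < 1e-12 (≤ 100 iterations). Bootstrap
draws of γ̂* crossing zero are kept as-is: medians are robust to the
resulting heavy ratio tails. Degenerate inputs (γ̂_j = 0, constant traits,
all-zero weights, < 3 instruments for intercept/median methods, < 4 for
the global pleiotropy test) raise informative errors rather than returning
numbers.

## Limitations

The packaged per-SNP inputs are printed values rounded to 2–3 decimals, so
reproduced estimates carry ~0.01–0.05 absolute wobble; tolerances are set
accordingly and stored next to the expected values, not in test logic.
One-sample MR with weak instruments is biased toward the observational
association; the calibration suite operates at the defaults' weak-but-
adequate strength and its coverage checks would degrade if `exposure_r2`
were lowered substantially, which is the intended way to study that
regime. The mapped-phenotype screen encodes an inferred keep-if-any-
dietary rule; alternative readings of the published tables are possible
and the screen is fully configurable.
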