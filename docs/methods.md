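# Methods

This note records the models implemented in `iacdens`, the defaults and
the reasoning behind the genuinely open design choices.

## Quantification model

Calcification is defined purely by in-ROI thresholding: any voxel inside
an artery's region of interest with attenuation ≥ 130 HU counts, with no
connected-component filtering or minimum lesion size. 130 HU is the
conventional detection floor for calcium on non-contrast CT; the ladder
(130, 200, 300, 400, 600, 800, 1000 HU) re-applies the same measurement
at rising thresholds to isolate components of increasing density.
Volume is voxel count × voxel volume at the floor threshold — the
standard calcium-volume-scoring convention, adopted because this is the
field's default when no explicit formula is given. Mean density is the
plain arithmetic mean of supra-threshold HU.

**Category bins.** The seven ordinal maximum-density categories are
left-closed/right-open at interior edges ([130, 200), [200, 300), …)
with one exception: 1000 HU itself belongs to "800–1000" because the top
category is printed strictly as "> 1000". The printed labels are
contiguous, so only the edge convention needed deciding; left-closed is
the convention that keeps every label's lower bound inclusive.

**Absent vs zero.** When no voxel reaches the floor, volume is 0 but
density is *absent*, not 0 — an absent density must never enter an
average. Participant/bed mean density is the unweighted mean of
per-artery mean densities over affected arteries (each artery one vote,
regardless of lesion size), not a voxel-pooled mean; the two differ
whenever artery lesion sizes differ, and a regression test pins the
per-artery convention. The participant-level maximum-density category is
the maximum over arteries, which coincides with the pooled-voxel maximum.

## Phantom generator

Phantoms place geometric inserts (spheres, ellipsoids, spherical shells)
with uniform or linearly graded radial HU profiles into Gaussian
soft-tissue background (mean 40 HU, SD 10 HU), clipped below 130 HU by
default so no background voxel can masquerade as calcification, and
rounded to integer HU as CT stores them. Voxel membership uses the
voxel-center-inside-shape rule — the simplest deterministic convention —
which makes partial-volume behaviour at 3-mm slices directly observable:
realized (voxel-counted) volume differs from the analytic shape volume
and converges to it as slices thin, and a test verifies the error
shrinks when dz is halved. Artery masks are the insert voxels dilated by
a configurable soft-tissue margin (default 1.2 mm per axis); real
delineation protocols draw anatomical ROIs, so these masks are synthetic
stand-ins whose only guaranteed property is that they cover their insert.

`truth_table` recomputes every insert's realized voxel count, volume,
mean and maximum HU by an explicit per-voxel scan written independently
of the quantification code path. It is the oracle: the acceptance suite
demands bit-for-bit agreement between the two implementations on 50
seeded random phantoms.

What phantoms do **not** emulate: anatomy, beam hardening, streak
artefacts, scanner noise spectra, contrast. Passing phantom tests shows
the counting and averaging arithmetic is exact, not that the method is
robust to real-scanner physics.

## Cohort simulator

Covariates are drawn independently from the emulated population's
marginals: age ~ N(69.7, 6.8²) years truncated at 55 (the cohort's
enrollment floor), non-HDL cholesterol ~ N(4.2, 1.0²) mmol/L truncated
at 1.0, and Bernoulli draws for female sex (0.519), ever smoking
(0.697), obesity (0.241), hypertension (0.742), diabetes (0.112),
lipid-lowering medication (0.244), CHD history (0.092), CVA history
(0.063) and 64-slice scanner (0.686). Independence is a deliberate
simplification — no joint distribution is published — and is adequate
for estimator-recovery testing but not for emulating real confounding;
the sensitivity-restriction counts in real data, where the exclusion
flags are correlated, are therefore not a target.

**Ordinal outcome.** The 7-level category is generated from its latent
representation: u = xᵀβ + ε with standard-logistic ε, category k when
α_{k−1} < u ≤ α_k. The generating β are the natural logs of the
published adjusted common odds ratios. The published category
frequencies exist only as bar charts, so the cutpoints are free
parameters: the defaults were fixed once as the latent-scale quantiles
giving marginal probabilities (8, 14, 16, 22, 16, 14, 10)% under the
default covariates and effects — chosen so every category has ≥ 2%
probability and fits never face empty categories. They live in the
effect-spec defaults, overridable per run.

**Density–volume pairs.** A Gaussian copula with Pearson parameter
r = 2·sin(π·ρ_S/6) — the exact bivariate-normal inversion of Spearman's
ρ — generates pairs whose population rank correlation equals the target
(default 0.67). Margins are log-normal, matched to the published median
and IQR (density 232 [189–287] HU; volume 67 [22–189] mm³ with the
+1 mm³ offset applied before the log). Quartile matching fixes the
median exactly and the IQR *ratio* exactly; the individual quartiles are
reproduced only insofar as the real data are log-symmetric.

**Linear outcome.** The standardized ln-density outcome is generated as
y = xᵀβ + ε with the published per-SD coefficients and normal noise
scaled so Var(y) = 1, matching the convention that the coefficients
live on the standardized-outcome scale.

**Seeding.** One master seed spawns per-component substreams
(`numpy.random.SeedSequence`), so a fixed seed yields a bit-identical
cohort table and each component is reproducible in isolation.

## Estimators

**Spearman ρ** is the Pearson correlation of mid-ranks (tie-aware); the
95% CI is a seeded percentile bootstrap over participants (default 1000
resamples). The bootstrap was chosen as the nearest self-contained
analogue of common practice; a Fisher-z interval would also be
defensible but is not what the estimate's skewed small-sample
distribution favours. Constant margins make ρ undefined; the result is
returned flagged rather than raising, so batch pipelines can skip it.

**Proportional-odds regression** maximizes the cumulative-logit
likelihood by Newton–Raphson with analytic gradient and Hessian.
Cutpoints are reparameterized as (α₁, log successive gaps) so the
ordering constraint disappears; the chain rule transports gradient and
Hessian, including the curvature of the reparameterization. Step
halving (up to 40 halvings) guarantees the log-likelihood never
decreases — asserted per fit. Starting values: β = 0, cutpoints at the
empirical cumulative logits. Convergence: gradient sup-norm < 1e-8, or
a stall criterion — no log-likelihood change at float64 resolution with
sup-norm < 1e-5 — because on cohorts of this size (|LL| ≈ 3.7×10³) the
attainable gradient floor sits near 1e-8 and pure Newton can park one
ulp away from it. Maximum 100 iterations. Standard errors come from the
observed information in the natural (α, β) parameterization; intervals
are Wald on the log scale (the published intervals are symmetric on
that scale); profile likelihood is not implemented. Smoking enters as
the ever/never binary; a three-level coding can be passed explicitly
via a custom covariate spec but is not the default. Unobserved
categories are rejected with advice to collapse, constant columns are
rejected as separation-inducing, and K = 2 reduces exactly to binary
logistic regression (verified against an independent implementation to
1e-6).

**Linear model.** The ln outcome is z-scored (sample SD, ddof = 1) and
regressed on natural-scale covariates by QR with classical
homoskedastic t-intervals. Only the outcome is standardized — the
"per SD increase" column convention — because covariate rows are
labelled in natural units (per year, per mmol/L). Rank deficiency is
rejected naming the collinear columns.

**Wilcoxon rank-sum.** U counts pairs with x > y (ties ½). Exact
two-sided p-values by the partitions-in-a-box null distribution when
min(n₁, n₂) ≤ 8 and the pooled data are tie-free — tractable at any
opposing sample size — otherwise the normal approximation with tie
correction and a 0.5 continuity correction. The ≤ 8 switch keeps exact
enumeration cheap while covering every small-sample case the exact
distribution materially differs in. The methods-stated test is the
rank-sum; Welch's t is available behind a flag because one figure
caption mentions t-tests. Three pairwise subtype comparisons are
reported raw by default, with an optional Bonferroni adjustment —
reproducing the published display while exposing the safer option.

**Sensitivity restriction** drops any participant with prevalent CHD,
CVA or lipid-lowering medication and reports the removed count. With
complete synthetic data no imputation is needed; the simulator emits no
missing values by design, and multiple imputation is out of scope.

## Validation design and problem sizes

`iacdens.validation` regenerates and refits:

- **Ordinal recovery**: 30 cohorts of n = 2040 (the analysis-sample
  size); the across-seed mean of each estimated odds ratio is compared
  with its generating value. At this replication the Monte-Carlo SE of
  the mean log-OR ranges from ≈ 0.1% (age) to ≈ 3% (CHD, CVA), which
  determines what tolerances are meaningful per covariate.
- **Coverage**: 200 replicate fits; empirical 95%-Wald coverage per
  covariate should land in [90%, 99%] (binomial noise at 200 reps is
  ±1.5 points).
- **Spearman recovery**: 50 seeds at n = 2040; per-seed sampling SD is
  ≈ 0.012, so ±0.03 is a ≈ 2.4σ band — individual seeds occasionally
  exceed it by chance, the across-seed mean is tight to ±0.005.
- **Linear recovery**: 30 refits; the hypertension coefficient's
  per-fit SE is ≈ 0.05, so the mean is good to ≈ 0.01.

These sizes mirror the study conditions (2040 participants with
detectable calcification out of 2464) rather than being scaled down.

## Known limitations

- Synthetic masks are geometric dilations, not anatomical ROIs.
- Covariate independence understates real-world confounding; recovery
  results validate the estimators, not the epidemiology.
- Only the logistic link is implemented for the ordinal model.
- The exact Wilcoxon path requires tie-free data; tied small samples
  fall back to the corrected normal approximation.
- Participant-level "predominantly intimal/medial" labels have no
  published derivation rule from artery scores and are not implemented;
  subtype analysis is artery-level.
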