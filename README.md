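# iacdens

Quantification and statistical modelling of intracranial arterial
calcification (IAC) density on non-contrast CT.

Arterial calcification is usually summarized by its volume, but the
*density* of a calcified lesion — its mean attenuation in Hounsfield
units (HU) — carries independent information about plaque maturity and,
in the coronary literature, about cardiovascular risk. This package
implements the full analysis chain for studying IAC density in a
population cohort: voxel-level quantification inside artery regions of
interest, a ladder of HU thresholds that decomposes each lesion into
components of increasing density, ordinal categorization of the maximum
density, intimal/medial subtype stratification by Kockelkoren score,
and the statistical models that relate cardiovascular risk factors to
density. Because no imaging data ship with it, the package also
contains two first-class synthetic-data generators: CT-like phantoms
with exact geometric ground truth, and a cohort simulator with
realistic covariate marginals and a proportional-odds outcome model.

It is aimed at imaging epidemiologists and methodologists who want a
tested, reproducible reference implementation of this measurement and
inference chain.

## The measurement model

Within each artery's region of interest, a voxel is calcified when its
attenuation is at least the conventional detection floor of 130 HU.
For a threshold *t* from the ladder (130, 200, 300, 400, 600, 800,
1000 HU):

- **volume** V(t) = (number of in-mask voxels with HU ≥ t) × voxel
  volume (mm³),
- **mean density** D(t) = mean HU over those voxels (absent if none),
- the **maximum density category** is the 7-level ordinal bin of the
  highest in-mask HU: 130–200, 200–300, 300–400, 400–600, 600–800,
  800–1000, > 1000 (left-closed interior edges; 1000 HU itself falls
  in 800–1000).

Per-participant bed aggregates (ICAC = paired intracranial carotids,
VBAC = vertebrals + basilar, IAC = all five arteries) average the
per-artery mean densities with equal weight over affected arteries —
not voxel-pooled — and sum volumes.

## The inference chain

- Tie-aware Spearman ρ between ln(density) and ln(volume + 1 mm³), with
  a seeded percentile-bootstrap 95% CI.
- Proportional-odds ordinal regression of the 7-level maximum-density
  category on risk factors, P(Y ≤ k | x) = logistic(α_k − xᵀβ), fitted
  by Newton–Raphson with step-halving; exp(β) is the common odds ratio
  for a higher density category, with Wald intervals from the observed
  information.
- OLS of the z-scored ln outcome ("per SD increase") on natural-scale
  covariates, solved by QR.
- Pairwise two-sided Wilcoxon rank-sum tests comparing mean density
  across intimal (score < 5), ambiguous (5–8) and medial (> 8)
  Kockelkoren strata.
- A sensitivity restriction to participants free of coronary heart
  disease, cerebrovascular accidents and lipid-lowering medication.

## Worked example

```python
import numpy as np
from iacdens import (CalcInsert, PhantomTruth, generate_phantom,
                     threshold_profile, simulate_cohort,
                     fit_proportional_odds, spearman_with_ci)

# A graded calcific insert: 800 HU core falling to 200 HU at the rim
ins = CalcInsert("ICA_left", (9.0, 9.0, 12.0), "sphere", (3.0, 3.0, 3.0),
                 ("graded", 800.0, 200.0))
spec = PhantomTruth(inserts=[ins], seed=11)
grid, masks = generate_phantom(spec, (32, 32, 10), (0.6, 0.6, 3.0))
m = threshold_profile(grid, masks["ICA_left"], artery_id="ICA_left")
rec = m.records[0]
print(f"volume {rec.volume_mm3:.2f} mm^3, mean density {rec.mean_hu:.1f} HU, "
      f"max {m.max_hu:.0f} HU, category {m.density_category}")
```

prints

```
volume 85.32 mm^3, mean density 397.9 HU, max 800 HU, category 6
```

79 voxels of 1.08 mm³ reach the 130-HU floor; their average
attenuation is 397.9 HU (between rim and core, as the radial ramp
dictates), and the hottest voxel (800 HU) puts the artery in ordinal
category 6 ("800–1000").

```python
cohort = simulate_cohort(n=2040, seed=1)
covs = ["age", "female", "ever_smoking", "obesity", "hypertension",
        "diabetes", "non_hdl", "lipid_med", "chd", "cva", "scanner_64"]
fit = fit_proportional_odds(cohort[covs], cohort["density_category"].to_numpy())
print(fit.summary_frame()[["term", "odds_ratio", "ci_low", "ci_high"]].round(2))

corr = spearman_with_ci(cohort["ln_volume_plus1"], cohort["ln_density"], seed=1)
print(f"rho {corr.spearman_rho:.2f} ({corr.ci_low:.2f}-{corr.ci_high:.2f})")
```

prints (abridged)

```
        term  odds_ratio  ci_low  ci_high
         age        1.08    1.07     1.09
hypertension        1.38    1.16     1.64
         chd        2.88    2.18     3.81
...
rho 0.67 (0.64-0.69)
```

One simulated cohort of 2040 participants, refitted: each odds ratio
is an estimate of the generating value (e.g. hypertension generated at
1.59 estimated here at 1.38 — single-cohort sampling noise; averaging
refits across seeds recovers the truths, which is exactly what the
reproduction script below measures). The rank correlation between
ln-volume and ln-density recovers the copula target of 0.67.

## Command line

```sh
iacdens run --out out/demo --seed 0          # full demo pipeline
iacdens phantom --out out/ph --seed 1        # phantoms + truth tables
iacdens simulate --n 2040 --seed 2 --out out/sim
iacdens quantify --image scan.nii --masks 'masks/*.nii' --out out/q
iacdens subtype --arteries arteries.csv --out out/s --adjust bonferroni
iacdens fit --cohort out/sim/cohort.csv --model ordinal --out out/fit
```

Every run writes a `manifest.json` with per-stage seeds and SHA-256
hashes of all outputs; reruns with the same config are hash-identical.

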