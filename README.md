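# olivesig

Plasma multi-metabolite signatures of olive-oil consumption, and their
association with incident cardiometabolic disease.

`olivesig` is a tested, reusable implementation of a nutritional-metabolomics
workflow: starting from a participant table (FFQ-derived olive-oil intakes in
g/day, covariates, total energy) and an LC–MS metabolite matrix, it

1. applies participant and metabolite quality control with auditable
   exclusion logs,
2. normalizes the metabolome (pooled-reference standardization, iterative
   random-forest imputation, Blom rank-based inverse-normal transform) and
   energy-adjusts intakes by the residual method,
3. screens every metabolite against each olive-oil exposure with
   covariate-adjusted linear models under Benjamini–Hochberg FDR control,
4. derives a sparse **multi-metabolite signature** per exposure by tenfold
   cross-validated elastic-net regression with *consistency selection*, and
   validates it by out-of-split and repeat-visit Pearson correlations, and
5. relates the 1-SD signature score to incident disease with
   **Barlow-weighted case-cohort Cox models** (robust clustered variance,
   stratified baseline hazards, nested covariate sequences, interaction
   tests), plus coefficient-space PCA and specificity correlations.

A bundled synthetic-cohort generator (`olivesig.synthetic_cohort`)
reproduces the statistical structure this analysis assumes — block-correlated
metabolite families carrying a sparse planted intake signal with known R²,
a correlated 1-year repeat visit, proportional-hazards outcomes, nested
case-cohort samples — so the whole pipeline is testable against known
ground truth.  It is first-class, tested code, not a fixture.

## The model in brief

For exposure y (energy-adjusted intake, g/day) and standardized metabolites
X, the elastic net minimizes

    (1/2n) ‖y − Xβ‖² + λ ( α‖β‖₁ + (1−α)/2 ‖β‖₂² ),

with α scanned from 0 (ridge) to 1 (lasso) in 0.1 steps and λ chosen by
tenfold cross-validation (λ.min rule by default).  Ten reseeded tenfold-CV
fits on the whole discovery sample define the signature: metabolites with a
nonzero coefficient in **all ten** iterations are retained, weighted by
their mean coefficient.  The score for a new sample is Σ w_j · z_j over the
selected metabolites (z = standardized abundance).  Disjoint 90/10
train/validation splits provide out-of-split scores for the discovery
correlation (Fisher-z 95% CI).

For a nested case-cohort sample with subcohort fraction f, Barlow weights
are 1/f for subcohort non-cases, 1 for cases at failure, with subcohort
cases time-split; the weighted stratified partial likelihood (Breslow
ties, delayed entry) is maximized by Newton iteration and the variance is
the participant-clustered sandwich, matching `coxph(..., weights,
cluster(id))`.  Hazard ratios are per 1 SD of the score.

## Worked example

```python
import numpy as np
from olivesig import synthetic_cohort as syn, preprocess as pp, signature as sig

cfg = syn.SimConfig(seed=3)                  # n=1800, p=381, planted R²=0.16
cohort, met, truth = syn.generate_cohort(cfg)
base = cohort[cohort.visit == "baseline"]

X = pp.blom_transform(met.values.xs("baseline", level=1))
y = pp.energy_adjust_residual(base["intake_total_oo"].to_numpy(),
                              base["energy"].to_numpy())

model = sig.derive_signature(X, y, alpha=0.4, seed=3, exposure="total_oo")
res = sig.validate_signature(model, y)
print(len(model.selected), round(res.r, 3), (round(res.ci_low, 3), round(res.ci_high, 3)))
```

prints

```
91 0.383 (0.343, 0.422)
```

— 91 metabolites selected in all ten CV iterations, and a pooled
out-of-split Pearson correlation of 0.38 between the signature score and
reported total olive-oil intake, close to the theoretical ceiling
√R² = 0.40 of the planted signal.  Applying the same model to the 1-year
visit (`validate_signature(..., mode="external")`) yields r ≈ 0.31, the
attenuation expected from the repeat-visit autocorrelation of 0.8.

The same workflow is available from the shell:

```bash
olivesig simulate --seed 5 --out sim/
olivesig signature derive --cohort sim/ --exposure total_oo --seed 5 --out total_oo.json
olivesig survival fit --cohort sim/ --signature total_oo.json --model 3
```

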