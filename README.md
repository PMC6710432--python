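# pdpattern

Covariance brain-pattern derivation for longitudinal small-animal
FDG-PET: disease-specific and motor-related glucose metabolic patterns
via PCA + linear SVM, with expression scores, Z-values and group
statistics over time.

## The problem

In neurodegenerative disease models, mass-univariate voxel statistics
often show metabolic changes that come and go over time, even when the
underlying degeneration is progressive and stable. A multivariate
alternative is to learn a *covariance pattern*: a single voxel-weight map
whose expression in a scan summarizes how strongly the scan manifests the
disease-related metabolic topography. `pdpattern` implements this
approach for longitudinal rodent FDG-PET cohorts (e.g. a unilateral
α-synuclein Parkinson's-disease rat model with ~18 animals scanned at
baseline and weeks 3/4/6/9), where the number of scans N is tiny compared
with the number of brain voxels D.

## The model

Each co-registered scan is smoothed (Gaussian, FWHM in mm), masked,
vectorized, spatially demeaned and scaled to unit L2 norm, giving a
feature vector x ∈ R^D with Σx = 0 and Σx² = 1 — so injected dose and
global metabolic rate cancel. A PCA fitted on the pooled training set
(both groups) gives an orthonormal transform A (K ≤ N−1 components, all
nonzero-variance components retained), and a linear SVM in component
space learns weights w and bias b:

    y(x) = wᵀ A(x − m) + b = ⟨Aᵀw, x − m⟩ + b

where m is the training mean. The voxel-space map **p = Aᵀw** is the
metabolic brain pattern: derived from PD-vs-control classification
(L1-soft-margin SVC) it is the *disease-specific pattern* (PDSP); derived
from ε-insensitive L1-loss regression of cylinder-test motor scores (SVR)
it is the *motor pattern* (PDMP). Both duals are solved by a hand-written
sequential minimal optimization (SMO) solver; hyperparameters (C, kernel
scale) come from a grid search with seeded nested k-fold cross-validation.

A scan's *expression score* is the inner product ⟨p, x − m⟩; *Z-values*
standardize it by the mean/SD of all control scans across all timepoints.
The pattern is trained at the final timepoint (stable, near-complete
degeneration), classifier accuracy is estimated by leave-one-out
cross-validation with the PCA refit inside every fold (no leakage), and
earlier timepoints are projected onto the final-timepoint pattern, with
two-sided Wilcoxon rank-sum tests (exact for small tie-free samples) per
timepoint.

Because real cohorts of this kind are not openly distributable, the
package ships a synthetic phantom generator: an ellipsoidal brain with
Voronoi parcels, a planted multiplicative regional hyper/hypometabolism
pattern whose amplitude follows the disease schedule
(0, 0, 0.6, 0.9, 1.0 across the five sessions), per-subject global scale
factors, voxel noise, scanner-resolution blur, and motor scores tracking
pattern expression.

## Worked example

```python
import pdpattern as pp

atlas, mask, truth_vol, truth_vec, scans = pp.default_phantom(seed=0)
report = pp.run_study(scans, mask, seed=0)
print(report.results["pdsp"].summary())
```

```
Covariance brain-pattern model
==============================================
mode:            classify  (disease-specific pattern)
subjects:        18  (D = 8744 masked voxels)
components:      17
C:               0.01
kernel scale:    0.125
grid-search CV loss: 0.0000
support vectors: 16 / 18
bias b:          +0.4563
sign flipped:    False
training accuracy: 1.000
```

The grid search picked a strongly regularized classifier (C = 0.01) that
separates the week-9 groups with zero cross-validated error; 17
components (all of them, N−1) carry SVM weights. Downstream:

```python
report.loocv.accuracy_pd, report.loocv.accuracy_control
# (1.0, 1.0)                     # every held-out subject classified correctly
{tp: r.wilcoxon_p for tp, r in report.projections["pdsp"].results.items()}
# {'baseline': 0.63, 'w3': 0.57, 'w4': 4.6e-05, 'w6': 4.6e-05, 'w9': 4.6e-05}
report.score_correlations()["w9"]
# 0.9997                         # PDSP and PDMP scores agree at week 9
```

The groups are indistinguishable before the planted signal turns on
(baseline/week 3) and separate maximally from week 4 onward — 4.6e-05 is
the smallest two-sided exact p attainable with 10 vs 8 subjects — which
is the qualitative timeline expected from the disease model.

A command-line interface wraps the same pipeline:

```bash
pdpattern simulate --config cohort.yaml --out cohort/ --seed 0
pdpattern run --config run.yaml --out results/ --seed 0
```

producing pattern NIfTI maps, regional weighting TSVs (percent
positive/negative weighting and hyper-/hypometabolic predominance per
atlas region), per-subject score CSVs and a JSON summary.

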