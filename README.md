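# herniaquant

Quantitative CT morphometry of ventral hernias, built as a reusable, fully
tested pipeline over synthetic labeled phantoms with analytic ground truth:

* **io_core** — NIfTI intensity/label volumes, the label-code registry, metric
  and cohort CSV tables (patient axes: x = L→R, y = P→A, z = I→S; voxel
  centers, 0-based indices).
* **synthetic_data** — labeled CT phantoms (elliptic-cylinder torso,
  normal-offset muscular wall, half-ellipsoid hernia cap, fat compartments,
  bony landmarks) with closed-form/quadrature ground truth; rater-noise
  simulation (smooth contour-normal displacement, isotropic landmark shifts,
  level-set hernia-boundary noise); synthetic outcome cohorts with known
  generating coefficients.
* **surfaces** — 2-D thin-plate-spline (r² log r) reconstruction of the outer
  anterior wall and the closed abdominal-cavity surface from contours labeled
  every ~5 cm; watertight cavity meshing; wall-thickness statistics along
  outer-surface normals.
* **segmentation** — deterministic fuzzy C-means (m = 2, quantile init) body
  extraction and fat/muscle separation; visceral vs subcutaneous split by the
  closed cavity surface.
* **metrics** — the 20 named morphometrics A–T (hernia shape A–G, location
  H–L, body environment M–T); shape/location metrics are *absent*, not zero,
  for hernia-free subjects.
* **reliability** — mean surface distance, Hausdorff distance, representative
  landmark points (centroid / centermost / most-superior / most-anterior
  rules), voxelwise Cohen's kappa with a bounded negative-class region.
* **outcome_models** — one-tailed pooled t-tests; elastic-net regularized
  logistic regression minimizing (1/N)·Deviance + λ·[α‖β‖₁ + (1−α)/2‖β‖₂²]
  by IRLS + cyclic coordinate descent (numba); 1-SE λ rule with internal
  LOO/K-fold CV; the LOOCV α-sweep (false predictions and retained-variable
  counts per α); linear-SVM separating hyperplane; accuracy bookkeeping.
* **cli** — `herniaquant` command-line orchestration.

## CLI

```bash
herniaquant phantom --seed 1 --out-image img.nii --out-labels lab.nii --out-truth truth.json
herniaquant derive --image img.nii --labels lab.nii --out metrics.csv
herniaquant reliability --labels-a lab.nii --labels-b lab2.nii --out reliability.json
herniaquant cohort --n-bridge 9 --n-nobridge 17 --seed 0 --out cohort.csv
herniaquant ttest  --cohort cohort.csv --out ttests.json
herniaquant sweep  --cohort cohort.csv --alpha-step 0.01 --out sweep.json
herniaquant fit    --cohort cohort.csv --alpha 0.9 --out model.json
herniaquant svm    --cohort cohort.csv --features B E --out svm.json
herniaquant run    --config config.json     # end-to-end demo
```

`run` accepts a JSON config (keys: `seed`, `out_dir`, `n_phantoms`,
`phantom` overrides, `surface_noise_mm`, `landmark_noise_mm`, `alpha_step`,
`threshold`, `n_bridge`, `n_nobridge`, `stages`); unknown keys are rejected.
A single master seed fans out to fixed per-stage offsets, so stages rerun
reproducibly in isolation.

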