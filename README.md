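# reachdecomp

Decomposition of reaching movements from wrist-worn inertial sensors
into **movement elements** — 1D sub-movements between consecutive
velocity zero-crossings — with engineered kinematic features and
Gaussian-process machine learning to estimate **cerebellar ataxia
severity** and distinguish motor phenotypes.

## Who this is for

Researchers in clinical movement analysis and digital biomarkers who
want a tested, reproducible implementation of the movement-element
pipeline for the instrumented finger-to-nose test (FNT): a participant
wearing wrist accelerometers (128 Hz) repeatedly reaches between their
nose and a target for 40 s per hand. Because clinical recordings of
this kind are rarely shareable, the package ships a first-class
**synthetic cohort generator** that emulates healthy, ataxic (graded
severity on a BARS-like 0–30 scale) and parkinsonism-like reaching, so
every stage of the pipeline is testable end to end with no external
data.

## The method

1. **Pre-processing** — gravity is removed from each tri-axial
   acceleration series by subtracting the mean (the mean vector is the
   gravity estimate) followed by a zero-phase 6th-order 20 Hz
   Butterworth low-pass; velocity is obtained by trapezoidal
   integration and a zero-phase 6th-order 0.1–20 Hz band-pass removes
   integration drift. Axes are rotated into anatomical coordinates:
   rostrocaudal (RC) along gravity, anteroposterior (AP) along the
   principal direction of velocity variance orthogonal to gravity,
   mediolateral (ML) completing the frame.
2. **Decomposition** — each axis is independently segmented at its
   velocity zero-crossings into movement elements with duration `T`,
   signed distance `D` (trapezoidal integral) and mean speed
   `v̄ = |D|/T`. Elements smaller than 1 mm or shorter than 5 ms are
   excluded as potential sensor noise.
3. **Features** — 53 per-participant features: nine statistical
   aggregations each of `T`, `log D` and `log v̄`; the power-law
   exponent `α` from the least-squares fit `log v̄ = α log D + c`
   (healthy reaching follows the two-thirds power law, `v̄ ∝ D^(2/3)`);
   aggregations of log-ratios of consecutive distances; central cells
   of the normalized 2D histogram of consecutive signed AP distances
   (density of small consecutive movements — a dysmetria signature);
   and aggregations of the first two principal-component scores of
   element velocity morphologies (unit-mean, 60-sample profiles), with
   PCA fit leave-one-subject-out.
4. **Models** — Gaussian-process regression (RBF kernel) of the
   clinical score and GP classification of phenotype, evaluated with
   leave-one-subject-out cross-validation; features min-max scaled and
   labels z-scored per training fold, pediatric participants excluded
   from training.
5. **Evaluation** — RMSE and squared Pearson `r²` for regression, AUC
   with bootstrap 95% CI for classification, ICC(3,1) for test-retest
   reliability of repeated estimates, and Welch ANOVA / Games-Howell /
   t-test group comparisons, plus a morphology analysis comparing the
   first and last 20 s of the task against the theoretically optimal
   minimum-jerk (Hoff) velocity profile `s(τ) = 30 τ²(1−τ)²`.

## Worked example

```python
from reachdecomp.pipeline import PipelineConfig, CohortConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo", seed=3,
    cohort=CohortConfig(n_healthy=5, n_ataxia=8, n_parkinsonism=4,
                        repeat_visits=2),
)
res = run_pipeline(cfg)
```

prints (via the snippet in `scripts/acceptance.py`-style reporting):

```text
retained elements: 10328
feature table: (19, 53)
BARS-like RMSE: 2.34  r^2: 0.93
AUC ataxia_vs_control: 1.00  95% CI (1.00, 1.00)
AUC ataxia_vs_parkinsonism: 1.00  95% CI (1.00, 1.00)
ICC(3,1) of repeat estimates: 0.62
dominant/nondominant estimate correlation: 0.97
```

Here 17 synthetic participants (19 visits — two ataxia participants
return for a second visit) produce ~10k retained movement elements.
The LOSO GP regression recovers the generating severity to within
~2.3 points on the 0–30 scale (`r² = 0.93`); both classifiers separate
the groups perfectly at this (optimistic, noise-free-label) cohort
size; the ICC reflects only two repeat pairs and is correspondingly
unstable. `demo/` receives five artifacts: `manifest.csv`,
`elements.csv`, `features.csv`, `estimates.csv`, `metrics.json`.

The same pipeline is scriptable from the shell:

```bash
reachdecomp simulate --n-healthy 5 --n-ataxia 10 --seed 1 --out cohort/
reachdecomp decompose --manifest cohort/manifest.csv --out elements.csv
reachdecomp run-all --out run1 --seed 1
```

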