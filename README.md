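# fluidtraj

Personalized change detection for longitudinal retinal-fluid
trajectories from home OCT self-imaging.

## The problem

Patients with neovascular age-related macular degeneration can
self-image daily with a home OCT device. An AI segmentation step
upstream reduces each volume scan to a single number: the total
hypo-reflective volume **TRO**, in volume units (1 VU = 1 nL of
retinal fluid). Over a five-week monitoring window each eye yields an
irregular daily series of TRO values, and the clinical question is
binary: is this trajectory **stable**, or is it **changing** (a
reactivation of exudation, or a response to treatment)?

A population rule applies one fixed cutoff to everyone — commonly "an
excursion above 10 VU means change". The laboratory-medicine
alternative is the **reference change value (RCV)**: estimate each
eye's own total measurement variation SD_T, and flag a change only
when it exceeds what that eye's noise could plausibly produce,

    RCV = √2 · Z · SD_T,   Z = 1.96  →  RCV ≈ 2.8 × SD_T.

`fluidtraj` implements the personalized trajectory analysis behind
that rule and the machinery to compare it with the population rule:

1. **Trend labeling** — each point is labeled incline / plateau /
   decline. Mean-shift changepoints are found with a CUSUM-GLR
   statistic applied recursively (binary segmentation), boundary
   points are iteratively reassigned to the better-fitting stretch.
2. **Segmentation** — maximal runs of one label become segments.
3. **Continuity-constrained fit** — each segment gets a low-degree
   polynomial in calendar day; every segment after the first is
   anchored so its fitted start equals the previous segment's fitted
   end. The curve is continuous; its derivative may jump at
   reactivation or treatment boundaries.
4. **Scoring** — signal A = fit max − fit min; noise SD_T = RMS
   residual; SNR score = A / SD_T; population amplitude =
   raw max − raw min.
5. **Evaluation** — ROC of each score against ground truth, AUROC,
   Youden-optimal threshold, and fixed operating points at SNR > 2.8
   and amplitude > 10 VU.

Because no trajectory data ship with the package, a synthetic cohort
generator reproduces the study conditions (5-week near-daily series,
~28 tests per eye, stable / rise / fall / rise-then-fall shapes,
additive truncated-Gaussian noise) with labeled ground truth.

## Worked example

```python
import fluidtraj as ft
from fluidtraj.synthetic import TrajectoryShape, simulate_trajectory

shape = TrajectoryShape(kind="rise", baseline=3.0, amplitude=18.0,
                        onset_day=14, ramp_days=10)
traj = simulate_trajectory(shape, noise_sd=1.5, days_total=35,
                           test_rate=0.8, seed=11, eye_id="OD-demo")
res = ft.TrajectoryModel(traj).fit()
print(res.summary())
```

```
             Personalized TRO change analysis
==========================================================
Eye:                                               OD-demo
Tests (days spanned):                              29 (35)
Segments (changepoints):                             2 (3)
----------------------------------------------------------
Signal A (fit max-min):                     18.067 VU
Noise SD_T (RMS resid):                      1.613 VU
SNR score:                                  11.203
RCV (sqrt2*Z*SD_T, Z=1.96):                  4.470 VU
Raw amplitude (max-min):                    20.137 VU
----------------------------------------------------------
Call @ SNR > 2.80:                            changing
Call @ amplitude > 10 VU:                     changing
Ground truth:                                 changing
==========================================================
```

The fitted curve's excursion (18.1 VU, recovering the simulated 18 VU
ramp) is 11.2 times this eye's estimated noise (1.6 VU, simulated
1.5), far above the 2.8 cutoff — a clear change. The personalized
notification threshold for this eye would be its RCV, 4.5 VU, well
below the 10 VU population rule.

At cohort scale (the default study conditions: 300 eyes, 36.1%
changing, amplitudes 5–40 VU, noise 1–4 VU):

```python
cohort  = ft.simulate_cohort(ft.CohortConfig(seed=1))
results = ft.analyze_cohort(cohort)
labels  = [r.model.trajectory.label for r in results]
comp    = ft.compare_methods([r.score for r in results], labels)
comp.roc_personalized.auroc   # 0.9789
comp.roc_population.auroc     # 0.9595
```

The personalized SNR score dominates the population amplitude score
(AUROC 0.979 vs 0.960 on this seed), and the fixed 10 VU rule shows
the expected trade-off: high sensitivity to large changes but poor
specificity whenever an eye's own noise spans more than 10 VU.

The same pipeline is available from the shell:

```bash
fluidtraj simulate --n-trajectories 300 --seed 1 --out cohort.csv
fluidtraj analyze cohort.csv --out results/
fluidtraj report results/
```

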