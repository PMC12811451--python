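# Methods

## Model

A TRO trajectory is modeled as a continuous piecewise-smooth mean
curve plus independent measurement noise:

    y_i = f(d_i) + e_i,    e_i ~ N(0, SD_T^2),   y_i >= 0,

where `d_i` are the (irregular) test days of one eye and `f` is
piecewise polynomial with a small number of breakpoints at which the
derivative — but not the value — may jump. The breakpoints correspond
to clinical events (reactivation onset, treatment response); SD_T
aggregates every source of within-eye variation (device noise,
fixation, scan coverage, diurnal biology, segmentation error).

The trajectory-level decision statistic is the signal-to-noise score

    SNR = A / SD_T,      A = max f̂ − min f̂ (over observed days),

with SD_T estimated as the root-mean-square residual of the fit. The
personalized rule calls a trajectory changing when SNR exceeds a
cutoff; the cutoff 2.8 corresponds to the laboratory-medicine
reference change value RCV = √2·Z·SD_T at Z = 1.96. The comparator
population rule thresholds the raw excursion (trajectory max − min,
default cutoff 10 VU). A configuration switch
(`ScoreParameters.snr_denominator="mse"`) divides by the raw mean
squared error instead of its square root, for sensitivity analysis;
the root form is the default because the score is then dimensionless
and directly comparable to the 2.8 × SD_T reference interval.

## Changepoint detection and labeling

Breakpoints are found offline by recursive binary segmentation with a
generalized-likelihood-ratio statistic for a mean shift:

    G(k) = (n_L n_R / n) (ȳ_L − ȳ_R)² / σ̂²,

maximized over admissible splits of the segment under test and
accepted when G ≥ h; accepted splits are recursed on both sides until
nothing exceeds h. Each side of a split must keep at least
`min_segment_len` points (default 3 — fewer points cannot support a
trend label).

σ̂² is estimated per segment from successive differences,
σ̂ = MAD(Δy)·1.4826/√2, rather than from pooled within-split
residuals. This is deliberate: for a transient rise-then-fall spike,
every single split leaves the spike inside one half, so a pooled
residual variance absorbs exactly the structure being tested and the
statistic loses essentially all power; the difference-based MAD is
insensitive to level shifts and slow trends and keeps detection power
for the clinically central reactivation-then-treatment shape. σ̂² is
floored at 10⁻⁶ VU² so noiseless step fixtures register an effectively
infinite shift instead of dividing by zero.

The default threshold h = 10.62 is the 95th percentile of the maximum
top-level statistic over 4000 simulated pure-noise series of 28 points
(`scripts/calibrate_glr_threshold.py`, seed 20240601), i.e. a ~5%
per-trajectory false-alarm rate at the typical series length. The
threshold is a config field, not magic.

Between changepoints, each stretch is labeled incline / plateau /
decline by its least-squares slope against calendar day (not point
index; sampling is irregular), with a plateau band of
±`slope_tolerance` = 0.2 VU/day. Boundary points within
`min_segment_len` of a changepoint are then iteratively reassigned to
the neighbouring stretch when that stretch's OLS line predicts them
strictly better (by more than a 10⁻⁹ VU margin, so analytic ties are
decided stably under floating point — tied points do not move); the
loop runs to a fixed point, capped at `max_iterations` = 20 with a
logged warning, and is idempotent on its own output.

## Segmented fit

Maximal runs of one label become segments. Segment degrees are
`min(max_degree, n_points − 1, 2)`: quadratics capture the smooth
monotone arcs of real fluid dynamics, and the hard cap is the main
anti-overfitting guard — an overfit curve would steal variance from
the noise estimate and inflate every SNR, so keeping the fit stiff is
load-bearing for the score.

The first segment is ordinary least squares. Every later segment is
fitted in the shifted basis `(day − first_day)` subject to
`p(0) = anchor`, where the anchor is the *previous segment's fitted
value at its last observed day* (the fit's end, not the raw
observation). Fixing the constant term reduces the constrained
problem to an ordinary regression of `(y − anchor)` on the
intercept-free basis, which is exact, fast and well-conditioned; the
KKT formulation of the same problem serves as an independent oracle in
the tests. Continuity gaps are therefore zero to floating point by
construction. Between the last day of one segment and the first day
of the next no observation exists; the curve is taken as linear there
for plotting only. Single-point segments reduce to the anchor value
(or the observation, for the first segment). The first segment is
deliberately unconstrained — there is nothing upstream to anchor to.

## Evaluation

Changing is the positive class and every positive call uses the
strict rule `score > threshold`, consistently across classification,
ROC construction and operating points — so every ROC point, including
the optimum, is exactly reproducible by thresholding. One ROC point
is emitted per distinct score (ties collapsed) plus the all-positive
anchor, whose threshold is −∞ (serialized as null in JSON reports).
AUROC is the trapezoidal area, which under this construction equals
the Mann–Whitney pair concordance with half-credit for ties; the test
suite verifies this identity by exhaustive pair enumeration and
cross-checks against scikit-learn.

The "optimal" threshold maximizes Youden's J = sens + spec − 1 (a
maximum-accuracy criterion is available behind a flag); ties break
toward higher sensitivity, then the lower threshold. Degenerate
single-class inputs raise an explicit error; operating points with an
empty class report the undefined rate as NaN with a warning. No
confidence intervals are computed.

## Synthetic cohort

The generator emulates 5 weeks of near-daily self-imaging. Defaults
(all `CohortConfig` fields):

| parameter | default | why |
|---|---|---|
| days_total | 35 | five-week monitoring window |
| test_rate | 0.8 | ≈28 tests per eye, matching the observed testing frequency |
| n_trajectories | 300 | cohort scale of the study after exclusions |
| prop_changing | 0.361 | observed class mix |
| amplitude_range | 5–40 VU | plausible change amplitudes (uncalibrated; not reported per eye) |
| noise_sd_range | 1–4 VU | plausible per-eye SD_T (uncalibrated) |
| baseline_range | 0–20 VU | plausible resting TRO; scores are shift-invariant, so non-load-bearing |

Mean curves are piecewise linear — flat (stable), a single ramp of
total height `amplitude` over `ramp_days` (rise / fall), or an
up-ramp immediately followed by a symmetric down-ramp (rise_fall,
the reactivation-then-treatment shape); ramp durations are drawn so
the ramp(s) complete within the window, and fall baselines sit above
the amplitude so TRO stays non-negative. Noise is additive Gaussian
truncated at zero; the truncation biases observed means upward near
zero and slightly deflates the empirical SD there, which is accepted
and only material for baselines within ~2 SD of zero. Missingness is
i.i.d. Bernoulli per day (the first day is always kept so a series is
never empty). Everything is reproducible from a single seed, with
per-trajectory child seeds drawn from the cohort stream.

What the generator does **not** emulate: diurnal or autocorrelated
biological variation, heteroscedastic segmentation error (real TRO
noise likely grows with fluid load), device-specific artifacts, and
missingness that correlates with disease state. Passing tests
therefore establish the internal correctness and statistical
behaviour of the pipeline under the stated model, not device-level
clinical performance.

## Problem sizes

Cohort-level checks run on the 300-trajectory default cohort (a
single seed, ~8000 tests) — the scale at which the class mix and
score distributions are stable; oracle equivalence suites use 40–80
random instances of length ≤ 30–50 where brute-force enumeration is
exact and fast. Threshold calibration uses 4000 null series.

## Known limitations

- Binary segmentation is greedy; a configuration of multiple closely
  spaced shifts below `2·min_segment_len` apart cannot all be found.
- The GLR operates on raw values; a drift with no mean plateau is
  handled by the slope labeler and the fit, not the detector.
- SD_T from fit residuals is slightly optimistic (the fit consumes a
  few degrees of freedom per segment); no small-sample correction is
  applied, matching the plain RMS definition of the score.
- The exclusion rule (≥ 4 tests) leaves very short retained series
  whose single-segment quadratic can interpolate closely; their SNR
  is then governed by the noise floor and should be read with care.
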