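# Methods

## Problem and data model

The package estimates per-minute oxygen uptake (V̇O₂, mL·kg⁻¹·min⁻¹,
weight-normalized) of manual wheelchair users from a triaxial accelerometer
worn on the upper arm. A *session* is one participant's synchronized triple
of streams: acceleration (nominally 50 Hz, units of g, gravity **not**
removed — no high-pass or band-pass filtering is applied anywhere),
V̇O₂ measurements, and labelled activity intervals. Timestamps are seconds
from session start; the accelerometer reader rebases absolute clock stamps
by subtracting the first stamp, while the V̇O₂ reader takes an explicit
origin (`t0`) because silently rebasing a gas-analyzer file whose first
breath is not at session start would destroy the inter-stream alignment.

Windows are anchored at each activity's start (rest periods between
activities are excluded), one minute long, non-overlapping, with a trailing
partial window discarded. The window's V̇O₂ is the arithmetic mean of all
measurements in the half-open interval — no interpolation. Irregular
sampling is tolerated without resampling as long as the median inter-sample
gap stays within ±20% of the nominal period; features operate on the raw
sample sequence.

## Features (55 per window)

For each of x, y, z and the resultant vector RV: sample SD and variance
(n−1 denominator, so `VAR = SD²` exactly), the 10/25/50/75/90th percentiles
and the IQR, the lag-one autocorrelation, the Euclidean norms of a 2-level
Daubechies-2 DWT's detail and deepest-approximation coefficients, and
sample entropy; plus the three zero-lag between-axis Pearson correlations.

Numerical conventions, fixed so results (and the committed golden vector)
are reproducible:

* **Percentiles**: linear interpolation between order statistics (the
  "type-7" convention). At 3000 samples per window the choice is
  numerically negligible, but it must be pinned.
* **Wavelet boundary**: periodization. For window lengths divisible by 4
  (every whole-rate minute window used here: 3000, 600, 480 samples) the
  transform is orthonormal, making coefficient-energy conservation an exact
  testable invariant; other lengths are padded internally and conserve
  energy only approximately.
* **Sample entropy**: SampEn(m = 2, r = 0.3 × SD of the window's own
  channel), Chebyshev distance, self-matches excluded, both template counts
  over the first n − m start positions. Degenerate conventions: a constant
  channel returns 0; when no (m+1)-length pair matches, the standard cap
  −ln(2/((n−m−1)(n−m))) is returned. Pair counting uses a KD-tree, which is
  exactly equivalent to (and tested against) the quadratic template scan.
* **Cross-correlation** means the zero-lag Pearson correlation within the
  window, not a maximum over lags.
* Degenerate windows: any correlation of a constant series is reported as
  0 with a logged warning rather than NaN.

Features are classed *linear* (SD, VAR, percentiles, IQR; 32) or
*nonlinear* (lag-one, wavelet norms, SampEn, cross-correlations; 23).

## Modelling experiment

Windows (not participants) are randomly partitioned into k = 10 near-equal
folds — mirroring the pooled-window design of the original experiment; a
`group_by` option folds by participant instead, since window-level folding
leaks within-participant correlation and flatters validation metrics.
Within each fold's training 90%, greedy forward selection adds, at each
step, the candidate minimizing training MSE of the refit OLS model (the
selection criterion had to be fixed by us; training MSE is the natural
greedy companion to least squares). Ties break by canonical feature order;
candidates that would make the design singular are skipped. Metrics
(Pearson r, MSE, MAE) for each predictor count 1–10 are computed on
predictions *pooled across folds* — one concatenated vector per split —
rather than averaged per fold; the two aggregations differ only at second
order but pooling had to be chosen for determinism of the reported curve.
The final model takes the 3-predictor set selected most frequently across
folds (ties by canonical order) and refits it on all windows; 3 predictors
is the published operating point on the performance-versus-complexity
curve. Classical OLS standard errors of the refit accompany the model.

The per-activity table reports, for pooled validation predictions,
100·MSE/mean(obs²) and 100·MAE/mean(obs) per activity — a declared
convention for "relative normalized" errors; activities with fewer than two
windows are flagged rather than computed.

The three published equations are packaged verbatim, including the slightly
different printed coefficients of the all-variables and linear-variables
models (10.784 vs 10.7083 for RV_75-25, 21.0447 vs 21.04487 for Y_SD) —
almost certainly rounding artefacts, but harmonizing them would be
invention, so both are kept as printed.

## Synthetic cohort generator

The generator exists because the original recordings are available only on
request; it reproduces the protocol's *statistical structure* so the
pipeline — including model selection — can be validated end to end.

**Signal model.** Per activity (10 per session: 3 sedentary, 4 housework,
3 locomotion; 300 s each, 60 s rest between): a slowly drifting unit-norm
gravity orientation, plus per-axis constant zero-g bias (σ = 0.05 g,
emulating consumer-MEMS offset/temperature drift), plus an
amplitude-modulated sinusoid at the activity's dominant frequency with
independent per-axis amplitude weights (log-normal, σ = 0.55 about base
weights 0.9/1.0/0.7) and phases, gated on/off in 5-s blocks by an
activity-level duty cycle ~ U(0.25, 1), plus white movement noise whose SD
is an activity-specific fraction of the oscillation amplitude, sparse
impact spikes (rate ~ U(0, 0.15) s⁻¹, 1–1.8× amplitude), and a 0.004 g
sensor noise floor. Per-axis oscillation amplitude is capped at 0.5 g.
Activity amplitudes (0.015–0.42 g) are ordered
sedentary < housework < locomotion.

Several of these ingredients are deliberate *identifiability* devices, not
decoration. V̇O₂ is generated by applying a known linear equation (by
default the published all-variables one) to the features of each minute's
own signal, so whether forward selection recovers exactly
{RV_75-25, Y_VAR, Y_SD} from the 55 candidates is a meaningful check — but
only if those features are statistically distinguishable from their
proxies. Varying the noise-to-oscillation mix and the duty cycle varies
window distribution *shape* (IQR/SD = 2 for a pure sinusoid, ≈1.35 for
Gaussian noise; low-duty windows collapse the IQR but not the SD), which
separates the IQR from SD/variance proxies; impact spikes load the tails
and separate SD from robust statistics; the MEMS bias injects location
noise that degrades raw-percentile proxies while location-invariant
features cancel it exactly; and independent per-axis weights keep
single-axis dispersion from being collinear with resultant-vector
dispersion. The amplitude scale keeps per-axis SD below ≈0.4 g — the regime
in which the published equation is monotone increasing in Y_SD
(21.04s − 25.45s² peaks at s ≈ 0.41), i.e. the regime the original data
must have occupied for the printed coefficients to be physiologically
sensible.

**V̇O₂ stream.** Minute values = truth(features) + Gaussian noise
(default σ = 1 mL·kg⁻¹·min⁻¹), floored at 0, emitted every 5 s
(breath-like cadence, so minute-averaging is exercised non-trivially); rest
minutes carry a resting value of 3 mL·kg⁻¹·min⁻¹. With zero noise the
pipeline reproduces observed window V̇O₂ from extracted features to
≤ 1e−6 (tested). A `misspecified` switch adds +4·RV_75-25² to probe
robustness to an imperfect model class. The activity schedule places
activity i at i × 360 s, so annotation-anchored windows coincide exactly
with the generator's internal minute grid.

**Cohort.** 20 participants by default; per participant, seeded log-normal
perturbations of amplitudes (global σ = 0.15, per-activity σ = 0.12),
frequencies (σ = 0.10), jitter and noise mix, and body mass ~
N(74.8, 18.05²) kg clipped to [45, 125]. All randomness descends from one
master seed through `numpy.random.SeedSequence` spawns; outputs are
byte-identical across runs (session bundles are written with 17-significant-
digit floats and read back bit-exactly).

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: wheelchair-propulsion biomechanics (stroke
kinematics, road vibration spectra), physiological V̇O₂ kinetics (on/off
transients, drift, breath-by-breath noise correlation), device clock drift
between the two instruments, and any nonlinearity of the true
acceleration–energy relationship beyond the optional quadratic term. The
recovery study demonstrates that the pipeline is correct and well-powered
*when its model class contains the truth*; it cannot certify the published
equations' accuracy on new participants.

## Problem sizes and tolerances

Replicated studies run at 10 Hz (600-sample windows) — window counts,
fold structure and the generating equation are rate-independent, and
sample entropy (the only super-linear feature) keeps the replicate loop
tractable; single-session structural checks run at the full 50 Hz default.
The recovery acceptance surface uses 20 replicates × 20 participants
(1000 windows each): predictor-set recovery ≥ 80% of replicates,
coefficients within 3 classical standard errors in ≥ 90% of the replicates
that recovered the set (a replicate with a different set has no matching
coefficients to compare), and mean pooled validation correlation > 0.9.
The smaller 50-replicate coefficient-recovery property in the modelling
tests uses 4 participants at 8 Hz with selection capped at 3 predictors.
Oracle equivalences are exact for sample entropy (identical counts, hence
identical values) and 1e−8 relative for wavelet energy.

## Known limitations

* Window-level folding is the default to mirror the original experiment;
  participant-level folding gives honester generalization estimates and is
  one flag away.
* The per-task relative-error normalization is a declared convention; other
  definitions of "relative normalized MSE" exist.
* The published nonlinear equation's large intercept (−343.09) makes it
  numerically sensible only near lag-one correlations ≈ 0.68–0.7; applied
  to signals outside the population/placement it was fit on, it
  extrapolates badly. That is a property of the equation, not of this
  implementation.
* The exact re-synchronization rule for clock drift between instruments
  over a session is not specified upstream; readers assume the declared
  synchronization holds.
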