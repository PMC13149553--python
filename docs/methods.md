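# Methods

`speedcode` quantifies how single-neuron firing encodes locomotion
speed in head-fixed rodents, and provides a synthetic-session
generator with known ground truth so that every stage of the analysis
can be validated end to end.

## The encoding model

The core object is the single-phase association (saturating
exponential) between firing rate *f* (spikes/s) and running speed *v*
(cm/s):

    v = v_m · (1 − e^−(f − f0)/τ)

- **f0** — initial firing rate: the baseline below which firing drives
  no movement;
- **v_m** — asymptotic maximum speed: speed saturates as firing grows;
- **τ** — firing effect constant (spikes/s): the rise in firing above
  f0 at which speed reaches 63.2 % (1 − 1/e) of v_m. Small τ means a
  *more sensitive* neuron — less extra firing per unit of speed.

The same functional form, with optogenetic stimulation frequency *F*
(Hz) on the abscissa, describes the dose–response of evoked running
or backing-away speed; its effect constant is written τ_s to
distinguish it from the firing-based τ_f.

Fitting is bounded nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region reflective): v_m ∈ (0, 10·max v], τ > 0, f0 ≥ −5 spikes/s
(a small negative floor absorbs noise; negative estimates are
flagged). Initialisation: v_m₀ = 1.05·max v, f0₀ = min f,
τ₀ = span(f)/2, with up to five jittered restarts if the default start
fails. For the stimulation curve the offset f0 is restricted to
[0, min F]: evoked movement vanishes below the lowest tested
frequency, not at a negative one. A linear fit is always reported
alongside, with ΔR², per-model regression F-tests, and AICc; the
non-nested comparison is deliberately reported as information criteria
plus ΔR² rather than a single F statistic.

## Analysis pipeline

1. **Running events.** A bout starts at the first sample with
   |speed| > 0.5 cm/s and ends when the trace stays below threshold for
   ≥ `min_gap` (0.5 s); bouts shorter than `min_duration` (0.5 s) are
   dropped. Onsets are sample-accurate (no interpolation). Speed is
   signed — forward positive, backing away negative — and analysed as
   magnitude.
2. **Trial labelling.** A run is *spontaneous* iff no stimulus onset
   fell within `sensory_running_window` before it; a stimulus trial is
   *no-run* iff speed stays sub-threshold throughout that window after
   onset. The window length comes from prior characterisation of
   stimulus-evoked running and is not derivable from first principles;
   the package default is 3 s and it must be set deliberately per
   dataset.
3. **Classification.** Two one-sided Wilcoxon signed-rank stages at
   α = 0.05: (i) per modality, post-stimulus [0, 1] s rate vs 1 s
   pre-stimulus baseline on no-run trials — any significant modality
   marks the neuron sensory-responsive; (ii) otherwise, pre-running
   rate (over the neuron's detected firing window, else a default
   [−3, 0] s) vs a stationary baseline ([−10, −5] s) across spontaneous
   runs. R-neuron = running-related and not sensory-responsive. No
   multiple-testing correction is applied across the three modalities;
   directional hypotheses motivate the one-sided tests. Fewer than 5
   usable trials in either stage yields an indeterminate label.
4. **Firing window.** On the running-onset PETH (10 ms bins) the
   window runs from the first bin whose rate exceeds baseline mean +
   2 SD, sustained until onset, to the onset itself. The trial-mean
   rate is smoothed with a Gaussian kernel (default σ = 0.1 s) before
   the scan: at 10 ms bins and ~20 trials the per-bin rate is
   dominated by Poisson counting noise and a raw sustained-crossing
   rule fragments — with smoothing disabled (σ = 0) the rule is exact
   and is tested against hand-constructed histograms. A
   single-crossing variant sits behind `firing_window_sustained=False`.
5. **CCF.** Firing (spike counts per 0.1 s bin, divided by the bin) is
   correlated with mean |speed| per bin over a lag grid of
   [−10, 10] s in 0.1 s steps (201 lags); positive lag = firing leads
   speed. The observed curve uses truncated (non-circular) overlap.
   r_max is the curve maximum; the *plateau* is the contiguous run of
   lags within 10⁻³ of r_max and the optimal lag is its midpoint; FWHM
   is measured at (r_max + r_floor)/2 with r_floor the grid minimum
   (the half-maximum needs a floor reference, which the curve's own
   minimum provides). Significance: 1000 circular shifts of the speed
   series only, each by a uniform offset of at least one lag range so
   no shift recreates near-alignment; the observed |r_max| is
   significant if it exceeds the null's 95th percentile, and the
   add-one estimator p = (1 + #{null ≥ obs})/(1 + n) keeps p > 0.
6. **Encoding fit.** Speed is realigned by the optimal lag and the
   (f, v) pairs fitted. For session data the pipeline estimates the
   parameters by the *inverse* regression f = f0 − τ·ln(1 − v/v_m):
   binned firing rates carry Poisson counting noise while the encoder
   speed is nearly noise-free, and regressing speed on noisy firing
   (errors in the predictor) inflates τ and v_m severely (observed
   bias ≈ +90 % on synthetic ground truth, vs ≈ +2 % for the inverse
   direction). Both directions describe the same curve; the forward
   fitter is used wherever the abscissa is noise-free (dose–response
   curves, noiseless identities). The linear comparison recomputes
   both models' R² in the speed direction so ΔR² stays consistent.
   Population normalization: per neuron,
   subtract minimum firing and minimum speed, rescale speed by
   (group mean fitted v_m)/(neuron fitted v_m), then refit τ alone
   with f0 = 0 and v_m fixed at the group mean. "Measured v_m" means
   the fitted asymptote, not the max observed speed. The collapse
   isolates τ for within- and between-group comparison.
7. **Stimulation analysis.** Per opto trial: peak |speed| during
   stimulation (sign labels running vs backing away; sub-threshold
   throughout = stopping), or, if quiet during stimulation, the peak
   within 10 s after offset (rebound, latency measured from offset).
   Trials are block-averaged (default 10 per frequency, zeros from
   stopping trials included) before the dose–response fit. Frequency →
   firing-rate conversion is an OLS slope per neuron class with
   slope ratios (direct vs trans-synaptic drive); latency curves
   report mean latency per frequency and against model-converted
   speed, with a Spearman monotonicity diagnostic.

## The synthetic generator

Sessions emulate head-fixed turntable recordings: 600 s, ~24
spontaneous running bouts (trapezoids with 1 s linear ramps, durations
4–9 s) and 5 presentations each of sound/light/air-puff (1 s),
scheduled so stimulus trials are running-free and all bouts are
spontaneous under the default labelling window. Sensor noise on the
speed trace is Gaussian (SD 0.05 cm/s).

Running-related neurons fire as an inhomogeneous Poisson process
(thinning algorithm) whose rate is the *inverse* encoding model
applied to the future speed, rate(t) = f0 − τ·ln(1 − |v(t+lag)|/v_m),
with |v| clipped at 0.99·v_m where the logarithm would diverge.
Population draws: lag N(2.064, 0.273²) s for the cortical group and
N(0.903, 0.228²) s for the midbrain group; f0 N(2, 1) floored at 0.
Each neuron's v_m is anchored just above the session's fastest bout
(the fastest speed falls at a saturation fraction drawn from
U(0.78, 0.95) of v_m, mirroring how a fitted asymptote sits slightly
beyond the data) and τ follows the empirical line v_m = 1.43·τ + 7.37
(residual SD 1.5, floor 3). With group bout speeds of 16–28 cm/s
(cortical) and 10–18 cm/s (midbrain) this yields τ ≈ 17 vs ≈ 9 and
v_m ≈ 32 vs ≈ 20 — the ~2:1 τ contrast between the groups. Sensory
neurons carry a rectangular rate bump (default 3·√baseline spikes/s)
during each stimulus with a 200 ms exponential tail and no speed
coupling; unrelated neurons fire at a constant rate.

Optogenetic trials follow the forward dose–response curve (defaults
τ_s = 14.32 Hz, v_m = 22.81 cm/s) plus Gaussian trial noise (SD
2 cm/s), floored at zero magnitude; backing-away tables carry negative
sign; rebound uses a separate parameter set (default τ_s = 8.166).
Latency follows an invented monotone-decreasing form
latency(F) = 0.3 + 2·e^(−F/10 Hz) s — the decreasing shape is the
modelled phenomenon, the functional form is a package choice.

### What the generator does not emulate

Real recordings have non-Poisson spiking (bursting, refractoriness),
speed-history dependence, slow drift, and stimulus-evoked running;
the generator has none of these. Passing tests therefore demonstrate
that the pipeline is *correct and calibrated under its own model
assumptions*, not that those assumptions hold for any particular
recording. One consequence worth stating plainly: with the
paper-scale τ and v_m magnitudes and the unsmoothed 0.1-s-binned
count rates this package correlates, the attainable population r_max
is ≈ 0.74 for the cortical-like group and ≈ 0.59 for the
midbrain-like group. Published r_max values near 0.87/0.82 derive
from smoothed firing-rate curves, which suppress counting noise; the
CCF here deliberately uses raw binned counts, so its r_max values sit
lower at identical underlying coupling. Lag recovery is unaffected
(median error ≈ 0.02 s).

## Numerical choices

- Bins are half-open [left, right); a spike exactly at an event onset
  belongs to the first post-event bin.
- Speed traces are linearly resampled to a common 100 Hz grid on read.
- The permutation calibration check uses series of 2000 bins (200 s):
  at a few hundred bins the seam discontinuity a circular shift
  introduces makes the null slightly anti-conservative (~8 % rejection
  at 400 bins); at session-scale lengths the rule is calibrated
  (~4.5–6 %).
- Heatmap rate per bin is count/(N·Δt) with Δt = 0.1 s; rows are
  min-max scaled and constant rows map to 0.
- All stochastic steps (simulation, permutations, fit restarts) are
  driven by explicit seeds; the pipeline is a pure function of
  (session, config).

## Problem sizes used in the validation suite

Validation checks are sized to run on one CPU in minutes, as the
package's own test-budget choice: 100 sessions for lag recovery, 500
AR(1) pairs × 200 shifts for permutation calibration, one n = 100
population for classifier operating characteristics, 200 simulated
frequency-series experiments for dose–response recovery, and 100
random parameter draws for noiseless fit identity.

## Known limitations

- The sensory/running Wilcoxon stages inherit the uncorrected
  α = 0.05 design; with many stimulus presentations per modality the
  R-neuron false-exclusion rate approaches 1 − 0.95³ ≈ 14 %. At the
  4–6 trials per modality typical of these recordings the discrete
  signed-rank levels keep it near 5 %.
- The plateau midpoint defines the optimal lag; for curves with a
  unique peak this is the argmax, but the choice matters for broad
  plateaus and is configurable only through the plateau tolerance.
- A neuron both sensory-responsive and running-correlated is labelled
  sensory and excluded from the R pool; the alternative policy is not
  implemented.
- No GLM/point-process encoding models, no spike sorting, no circuit
  dynamics.
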