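# Methods

## Signal model

A CW-fNIRS channel records hemoglobin changes as concentration × optical
path length. With an unknown differential path length the absolute scale is
arbitrary, so nothing in this package ever divides by a path-length factor
and amplitudes are comparable only within a channel.

The observed pair (ΔHbO, ΔHbR) is modelled as the sum of two components,
each internally coupled by a fixed slope:

* functional: ΔHbR_F = k_F·ΔHbO_F, k_F < 0 — capillary flow-velocity
  changes exchange oxygenated for deoxygenated blood at roughly constant
  volume, moving the two species in opposite directions;
* systemic: ΔHbR_S = k_S·ΔHbO_S, k_S ≥ 0 — volume-capacity changes in
  larger vessels scale both species in proportion to their content, giving
  k_S = (1 − S)/S at blood oxygen saturation S (0 at S = 1, 0.43 at venous
  S = 0.70, 1.0 at S = 0.50).

Given both slopes the decomposition is a per-sample 2×2 linear solve with
determinant k_S − k_F, which the sign constraints keep bounded away from
zero. The decomposition is exact: components re-sum to the input to float
precision, each component lies exactly on its modality line, and the map is
linear and idempotent on pure-modality inputs.

The model assumes both slopes are constant over a session (homeostatic
regulation) and that k_F is universal across healthy adult cortex. The
packaged survey of published responses (17 estimates across species,
stimuli and modalities) gives k_F = −0.56 ± 0.12 (mean ± sample SD); the
package default is −0.6. Pathological or infant brains, where the
flow response may invert the deoxyhemoglobin sign, are outside the model.

## Estimating k_S

k_S depends on which vascular compartment fluctuates (arterial vs venous
mix) and therefore on the task; it is estimated per channel and session.
The functional and systemic components originate in different vessel
populations and are assumed statistically independent, so k_S is chosen to
minimize the mutual information between the separated components:

* candidates are enumerated in ascending order over [0, 1] in steps of
  0.01; ties take the first (smallest) minimizer; a minimum on either grid
  end is flagged `at_boundary` (a true slope above 1 saturates at 1);
* MI is computed between the ΔHbO traces of the two components only — each
  component's ΔHbR is an exact multiple of its ΔHbO and adds no
  information;
* densities are normalized histograms, 64 equal-width bins per axis
  spanning each series' observed min–max, MI in nats (the argmin is
  base-invariant). The bin count is configurable; the histogram estimator's
  positive bias (≈ (B−1)²/2n nats for independent inputs) is irrelevant to
  the argmin, which only uses profile shape.

A useful identity: for candidate k the separated systemic trace is the true
systemic trace rescaled by (k_true − k_F)/(k − k_F), while the functional
trace is the true functional trace plus a systemic leak proportional to
(k − k_true). The MI profile therefore measures the dependence introduced
by that leak, and its minimum sits at the true slope exactly when the two
sources are independent. Dependence between the sources (e.g., a strongly
task-locked functional response riding on a task-locked systemic response)
biases the minimum; the estimator is accordingly most reliable when
systemic variance is dominated by non-task structure (drift, Mayer waves,
cardiac pulsation), which is the regime real recordings occupy.

Estimation runs on the series as given — no detrending and no extra
filtering; drifts are treated as part of the systemic source. Degenerate
all-constant channels return a boundary-flagged estimate at the grid floor
with a warning instead of raising, so batch runs survive dead channels.

Profile unimodality (reported by `KsEstimate.n_local_minima`) counts
minima, including boundary ones, with a prominence floor of 1% of the
profile range: ripples below that are histogram-estimator noise, not
structure.

## MBLL conversion

Attenuation changes at ≥ 2 wavelengths map to (ΔHbO, ΔHbR) by least-squares
inversion of the molar-absorption matrix (exact inverse at 2 wavelengths,
normal equations beyond). ΔA follows the −log10(I/I0) optical-density
convention; only a global scale depends on that choice. Wavelength lookup
in the extinction table is exact-match only — interpolation would silently
change the inversion and is deliberately rejected. The packaged table is a
best-effort literature-style compilation (mM⁻¹ cm⁻¹ scale, 690–850 nm) and
is fully user-replaceable; no coefficient is hard-coded in logic.

## Synthetic sessions

The generator emulates block-design sessions with exact ground truth:

* designs: `tilt_or_breathhold` = 20 s rest + 5×(20 s task + 20 s rest)
  (220 s, task fundamental 0.025 Hz); `finger_tapping` = 20 s rest +
  5×(20 s left + 20 s rest + 20 s right + 20 s rest) (420 s, per-side
  fundamental 0.0125 Hz); 10 Hz sampling;
* functional component: task boxcar convolved with a gamma-difference HRF
  (peak 6 s, undershoot ratio 0.2, area-normalized so a sustained task
  plateaus at the configured amplitude), contralateral amplitude 0.4,
  ipsilateral 0.12 (ratio 0.3), ΔHbR exactly k_F×ΔHbO with k_F = −0.6;
* systemic component, identical on all channels and blind to task side:
  task-locked vasomotor rise (boxcar over all task epochs through a
  first-order kernel, τ = 8 s, amplitude 1.0), cardiac sinusoid (1.5 Hz,
  amplitude 1.0), Mayer sinusoid (0.1 Hz, amplitude 0.2), random-walk
  drift (innovation SD 0.01 per sample, ≈ 0.4 RMS wander over 7 min);
  ΔHbR exactly k_S×ΔHbO with k_S = 0.4 (venous-dominated bed);
* white Gaussian noise (SD 0.05) added after mixing, independently to the
  HbO and HbR traces — deliberately violating both modality lines so that
  separation robustness is actually exercised. All randomness derives from
  one integer seed.

The amplitude hierarchy (systemic fluctuations, including cardiac
pulsation of comparable size and baseline wander, dominating a functional
response a few-fold smaller) reflects the contamination problem the method
exists to solve, and simultaneously realizes the near-independence of the
two sources that the MI estimator assumes. Units are arbitrary throughout.

What the generator does **not** emulate: motion/optode-contact artifacts
(spikes, coupling-loss drifts), respiration, distance-dependent partial
path lengths (every channel sees the full systemic signal), heart-rate
variability, or session-to-session slope drift. Passing tests therefore
demonstrate correctness of the algorithms under the stated model, not
performance on artifact-laden recordings.

## Analysis conventions

* Low-pass: 4th-order Butterworth applied forward-backward (zero phase,
  DC gain 1); the acquisition convention is 40 → 10 Hz decimation plus a
  1.0 Hz low-pass. Filter family and order are configurable choices, not
  dictated by the model.
* Spectra: one-sided DFT magnitude of the mean-removed, Hann-windowed
  series; peaks are read as the maximum bin in a band, no interpolation.
  Spectral checks of task-locked structure drop the 20 s initial rest so
  the analyzed segment spans an integer number of task cycles (200 s or
  400 s), putting the design fundamentals (0.025, 0.0125 Hz) exactly on
  DFT bins; with the full record they fall between bins and the reported
  peak would carry a ±half-bin quantization.
* Block averages align epochs at onset and subtract the onset sample
  (onset-anchored traces); SD is the across-trial population SD, zero by
  convention for one trial; default window 40 s (task + following rest).
* Laterality: per trial and side, mean HbO over 10–20 s after task onset
  minus mean over the last 10 s of the preceding rest (the 10 s offset
  discards the hemodynamic transient); left/right paired by repetition
  index, two-sided paired t with df = n − 1, uncorrected (per-channel
  scaling differences violate the homoscedasticity assumed by standard
  multiple-comparison corrections). Zero-variance differences: t = 0 if
  all differences are exactly zero, otherwise flagged undefined.
* Correlation/rescaling: Pearson r plus the least-squares scale
  ⟨a,b⟩/⟨b,b⟩; the amplitude-vs-distance profile fits each distance's
  series to the 30 mm reference the same way.

## Problem sizes and tolerances

Seeded validation uses 20 sessions of 420 s at 10 Hz (4200 samples per
trace), chosen so the full suite runs in seconds while leaving the k_S grid
resolution (0.01), not sample noise, as the dominant error term. Recovery
is asserted as median |k̂_S − 0.4| ≤ 0.05 with a unimodal MI profile in
≥ 80% of runs; separation algebra is exact to 1e-12 relative, MBLL round
trips to 1e-10. Separating with misspecified k_F ∈ {−0.4, −0.8} (true
−0.6) must preserve contralateral dominance of the block-averaged
functional response — the separation is deliberately insensitive to
moderate k_F error.

## Known limitations

* A global cortical capillary-flow change is indistinguishable from the
  functional modality and would be attributed to it.
* k_F and k_S are session constants; slow physiological drifts of either
  violate the model silently.
* The k_S grid ceiling of 1 censors severely desaturated states; such
  estimates are only flagged, not extrapolated.
* Histogram MI with 64 bins needs a few thousand samples; very short
  records should reduce the bin count.
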