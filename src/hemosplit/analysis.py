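"""Preprocessing and evaluation of block-design sessions.

Covers the standard CW-fNIRS workflow around the two-modality separation:
zero-phase low-pass filtering, integer-ratio downsampling, onset-anchored
block averaging, one-sided amplitude spectra with band-limited peak
picking, a paired laterality t-test on task-minus-rest window means, and
least-squares correlation/rescaling of one series against another (used
e.g. to compare a separated component with an externally obtained
reference series, or attenuation changes across source-detector
distances).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import BlockDesign, HemoSignal

__all__ = [
    "BlockAverage",
    "Spectrum",
    "LateralityResult",
    "lowpass_filter",
    "downsample",
    "lowpass_hemo",
    "downsample_hemo",
    "block_average",
    "amplitude_spectrum",
    "find_spectral_peak",
    "laterality_ttest",
    "component_correlation",
    "attenuation_ratio_profile",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- filtering

def lowpass_filter(x, sampling_rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    No group delay; DC gain is exactly 1. The filter family and order are
    not dictated by the workflow itself — a 4th-order Butterworth is the
    conventional choice and the order is exposed.
    """
    x = np.asarray(x, dtype=float)
    if cutoff >= sampling_rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist "
                         f"({sampling_rate / 2} Hz)")
    sos = sps.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def downsample(x, original_rate: float, target_rate: float) -> np.ndarray:
    """Anti-alias filter then decimate by an integer factor."""
    x = np.asarray(x, dtype=float)
    ratio = original_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"original rate {original_rate} Hz is not an integer "
                         f"multiple of target {target_rate} Hz")
    if factor == 1:
        return x.copy()
    return sps.decimate(x, factor, zero_phase=True)


def lowpass_hemo(sig: HemoSignal, cutoff: float, order: int = 4) -> HemoSignal:
    return HemoSignal(sig.sampling_rate,
                      lowpass_filter(sig.hbo, sig.sampling_rate, cutoff, order),
                      lowpass_filter(sig.hbr, sig.sampling_rate, cutoff, order),
                      sig.units_label)


def downsample_hemo(sig: HemoSignal, target_rate: float) -> HemoSignal:
    return HemoSignal(target_rate,
                      downsample(sig.hbo, sig.sampling_rate, target_rate),
                      downsample(sig.hbr, sig.sampling_rate, target_rate),
                      sig.units_label)


# ------------------------------------------------------------- block average

@dataclass(frozen=True)
class BlockAverage:
    """Across-trial mean and SD traces aligned at epoch onset."""

    epoch_time: np.ndarray  # s relative to onset
    hbo_mean: np.ndarray
    hbo_sd: np.ndarray
    hbr_mean: np.ndarray
    hbr_sd: np.ndarray
    n_trials: int


def block_average(sig: HemoSignal, design: BlockDesign, epoch_window: float = 40.0,
                  labels=None, baseline: str = "onset") -> BlockAverage:
    """Average epochs aligned at their onsets.

    Each matching epoch contributes the samples in
    [onset, onset + epoch_window); with baseline='onset' every trial is
    shifted so its onset sample is zero (onset-anchored traces), with
    baseline='none' raw values are averaged. SD is the across-trial
    population SD (zero, by convention, for a single trial).
    """
    if labels is None:
        epochs = design.task_epochs
    else:
        epochs = design.select(labels)
    fs = sig.sampling_rate
    win = int(round(epoch_window * fs))
    trials_hbo, trials_hbr = [], []
    for ep in epochs:
        start = int(round(ep.onset * fs))
        if start + win > sig.n_samples:
            continue  # epoch window not fully inside the record
        hbo = sig.hbo[start:start + win].copy()
        hbr = sig.hbr[start:start + win].copy()
        if baseline == "onset":
            hbo -= hbo[0]
            hbr -= hbr[0]
        elif baseline != "none":
            raise ValueError(f"unknown baseline policy {baseline!r}")
        trials_hbo.append(hbo)
        trials_hbr.append(hbr)
    if not trials_hbo:
        raise ValueError("no matching epoch lies fully inside the record")
    hbo = np.vstack(trials_hbo)
    hbr = np.vstack(trials_hbr)
    return BlockAverage(np.arange(win) / fs,
                        hbo.mean(axis=0), hbo.std(axis=0),
                        hbr.mean(axis=0), hbr.std(axis=0),
                        n_trials=len(trials_hbo))


# ------------------------------------------------------------------ spectra

@dataclass(frozen=True)
class Spectrum:
    frequencies: np.ndarray  # Hz, ascending from 0 to Nyquist
    magnitude: np.ndarray


def amplitude_spectrum(x, sampling_rate: float) -> Spectrum:
    """One-sided magnitude of the DFT of the mean-removed, Hann-windowed series."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("series too short for a meaningful spectrum (need >= 16)")
    window = np.hanning(x.size)
    spec = np.fft.rfft((x - x.mean()) * window)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sampling_rate)
    return Spectrum(freqs, np.abs(spec))


def find_spectral_peak(spec: Spectrum, band: tuple) -> float:
    """Frequency of the maximum-magnitude bin inside [band[0], band[1]] Hz.

    No interpolation between bins. When the band maximum barely rises
    above the surrounding level a low-prominence warning is logged (the
    band probably excludes any real tone).
    """
    lo, hi = band
    mask = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    if mask.sum() < 3:
        raise ValueError(f"band {band} contains fewer than 3 spectral bins")
    mags = spec.magnitude[mask]
    freqs = spec.frequencies[mask]
    i = int(np.argmax(mags))
    med = np.median(mags)
    if med > 0 and mags[i] < 5.0 * med:
        log.warning("find_spectral_peak: peak at %.4g Hz has low prominence "
                    "(%.3g vs band median %.3g)", freqs[i], mags[i], med)
    return float(freqs[i])


# ---------------------------------------------------------------- laterality

@dataclass(frozen=True)
class LateralityResult:
    """Paired left-vs-right task response comparison.

    left_values / right_values hold, per trial, the mean HbO over the
    late-task window minus the mean over the late preceding-rest window.
    t is the paired t statistic of (left − right) with df = n_trials − 1;
    NaN when the paired differences have zero variance (t undefined).
    p is the two-sided uncorrected p-value.
    """

    left_values: np.ndarray
    right_values: np.ndarray
    t: float
    p: float
    df: int

    @property
    def undefined(self) -> bool:
        return bool(np.isnan(self.t))


def _window_means(sig: HemoSignal, design: BlockDesign, label: str,
                  window: float, offset: float) -> np.ndarray:
    fs = sig.sampling_rate
    values = []
    for ep in design.select(label):
        rest = design.preceding_rest(ep)
        if rest is None or rest.duration < offset + window - 1e-9:
            raise ValueError(
                f"epoch {label}@{ep.onset}: no preceding rest of >= "
                f"{offset + window} s")
        t0 = int(round((ep.onset + offset) * fs))
        t1 = int(round((ep.onset + offset + window) * fs))
        r1 = int(round(rest.end * fs))
        r0 = int(round((rest.end - window) * fs))
        if t1 > sig.n_samples:
            raise ValueError(f"epoch {label}@{ep.onset} extends past the record")
        values.append(sig.hbo[t0:t1].mean() - sig.hbo[r0:r1].mean())
    return np.asarray(values)


def laterality_ttest(sig: HemoSignal, design: BlockDesign, window: float = 10.0,
                     offset: float = 10.0) -> LateralityResult:
    """Paired t-test of left- vs right-hand task responses on one channel.

    Per trial and side, the HbO mean over [onset+offset, onset+offset+window)
    minus the mean over the last `window` seconds of the preceding rest —
    the offset discards the transient phase of the hemodynamic response.
    Left and right trials are paired by repetition index; the t statistic
    uses df = n_trials − 1.
    """
    left = _window_means(sig, design, "task_left", window, offset)
    right = _window_means(sig, design, "task_right", window, offset)
    if left.size != right.size:
        raise ValueError(f"unequal trial counts: {left.size} left vs {right.size} right")
    if left.size < 2:
        raise ValueError("need at least two trials per side")
    d = left - right
    sd = d.std(ddof=1)
    df = d.size - 1
    if sd == 0.0:
        if np.all(d == 0.0):
            # perfectly symmetric responses: no asymmetry, not an error
            return LateralityResult(left, right, 0.0, 1.0, df)
        log.warning("laterality_ttest: zero variance of paired differences, t undefined")
        return LateralityResult(left, right, float("nan"), float("nan"), df)
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return LateralityResult(left, right, float(t), float(p), df)


# ------------------------------------------------------------- correlations

def component_correlation(a, b) -> tuple[float, float]:
    """Pearson r between two series plus the least-squares scale of b onto a.

    scale = argmin_s Σ(a − s·b)² = ⟨a, b⟩ / ⟨b, b⟩.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("inputs must be equal-length with at least 3 samples")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero-variance input")
    r, _ = stats.pearsonr(a, b)
    scale = float(np.dot(a, b) / np.dot(b, b))
    return float(r), scale


def attenuation_ratio_profile(series_by_distance: dict,
                              reference_distance: float = 30.0) -> dict:
    """Amplitude ratio of each distance's series against the reference.

    ratio(d) is the least-squares factor by which the reference series
    must be multiplied to best coincide with the series at distance d:
    ratio = ⟨x_d, ref⟩ / ⟨ref, ref⟩, identically 1 at the reference.
    Under a multilayer model with layer-uniform hemodynamics this profiles
    the partial-path-length dependence on source–detector distance.
    """
    if reference_distance not in series_by_distance:
        raise ValueError(f"reference distance {reference_distance} missing "
                         f"(have {sorted(series_by_distance)})")
    ref = np.asarray(series_by_distance[reference_distance], dtype=float)
    denom = float(np.dot(ref, ref))
    if denom == 0.0:
        raise ValueError("reference series is identically zero")
    out = {}
    for dist, series in series_by_distance.items():
        x = np.asarray(series, dtype=float)
        if x.shape != ref.shape:
            raise ValueError(f"series at {dist} mm has mismatched length")
        out[float(dist)] = float(np.dot(x, ref) / denom)
    return out
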