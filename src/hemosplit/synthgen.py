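"""Seeded synthetic fNIRS sessions with known ground truth.

Emulates block-design motor/physiology sessions: a lateralized functional
response (boxcar convolved with a gamma-difference hemodynamic response
function, exact negative HbO/HbR coupling k_F) riding on a global systemic
fluctuation (task-locked vasomotor rise with a first-order time constant,
cardiac pulsation near 1.5 Hz, a Mayer-wave oscillation near 0.1 Hz and a
random-walk drift, exact positive coupling k_S), plus white measurement
noise added independently to the HbO and HbR traces after mixing — the
noise deliberately violates both modality lines so that separation
robustness is actually exercised.

The systemic component is identical on every channel and blind to the
task side (left- and right-hand epochs drive it equally); the functional
component responds contralaterally with a larger amplitude than
ipsilaterally. Amplitudes are in the same arbitrary concentration x
path-length units as real CW recordings — absolute scale is not meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as gamma_dist

from .core import TASK_LABELS, BlockDesign, Epoch, HemoSignal
from .mbll import Channel, ExtinctionTable, OpticalRecording, hemoglobin_to_attenuation
from .separation import ComponentPair, ModalityCoefficients

__all__ = [
    "SynthConfig",
    "SyntheticSession",
    "standard_designs",
    "hemodynamic_impulse_response",
    "generate_functional_component",
    "generate_systemic_component",
    "generate_session",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; all amplitudes share one arbitrary unit.

    Defaults follow the study conditions the generator emulates: 10 Hz
    working rate, k_F = −0.6 (literature consensus), k_S = 0.4 (venous-
    dominated systemic bed at ~70% saturation), cardiac pulsation at
    1.5 Hz, task repetition every 40 s, and a contralateral:ipsilateral
    functional amplitude ratio of 1:0.3. Amplitudes put the session in the
    contamination-dominated regime the separation method addresses: the
    systemic fluctuation (task-evoked rise, cardiac pulsation of
    comparable size, Mayer wave, baseline wander) carries most of the
    variance, while the cortical functional response is a modest fraction
    of it and measurement noise is well below both. That regime is also
    what makes the two modalities statistically near-independent, the
    premise the mutual-information estimator of k_S rests on.
    """

    sampling_rate: float = 10.0
    k_f_true: float = -0.6
    k_s_true: float = 0.4
    functional_amplitude_contra: float = 0.4
    functional_amplitude_ipsi: float = 0.12
    systemic_amplitude: float = 1.0
    cardiac_freq: float = 1.5
    cardiac_amplitude: float = 1.0
    mayer_freq: float = 0.1
    mayer_amplitude: float = 0.2
    drift_sd: float = 0.01   # random-walk innovation SD per sample
    noise_sd: float = 0.05   # white noise SD added to each trace
    hrf_peak: float = 6.0    # s
    hrf_undershoot_ratio: float = 0.2
    systemic_tau: float = 8.0  # s, first-order vasomotor time constant
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.k_f_true >= 0:
            raise ValueError("k_f_true must be negative")
        if self.k_s_true < 0:
            raise ValueError("k_s_true must be non-negative")
        for name in ("functional_amplitude_contra", "functional_amplitude_ipsi",
                     "systemic_amplitude", "cardiac_amplitude", "mayer_amplitude",
                     "drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cardiac_freq >= self.sampling_rate / 2:
            raise ValueError("cardiac_freq must be below Nyquist")


@dataclass(frozen=True)
class SyntheticSession:
    """Observed signals plus the stored ground truth they were built from.

    observed[ch] == truth[ch].functional + truth[ch].systemic + noise[ch]
    exactly (the noise arrays are stored, so the identity is checkable to
    the last bit). `attenuation` is present when forward MBLL modelling
    was requested.
    """

    observed: dict
    truth: dict
    noise: dict
    design: BlockDesign
    config: SynthConfig
    sides: dict
    attenuation: OpticalRecording | None = None


def standard_designs(name: str) -> BlockDesign:
    """Canonical block designs.

    ``tilt_or_breathhold``: 20 s initial rest, then five (20 s task +
    20 s rest) cycles — 220 s, task fundamental 1/40 = 0.025 Hz.

    ``finger_tapping``: 20 s initial rest, then five (20 s left tap +
    20 s rest + 20 s right tap + 20 s rest) cycles — 420 s; one side's
    epochs recur every 80 s, fundamental 0.0125 Hz.
    """
    if name == "tilt_or_breathhold":
        epochs = [Epoch("rest", 0.0, 20.0)]
        t = 20.0
        for _ in range(5):
            epochs.append(Epoch("task", t, 20.0)); t += 20.0
            epochs.append(Epoch("rest", t, 20.0)); t += 20.0
        return BlockDesign(tuple(epochs), session_length=t, initial_rest=20.0)
    if name == "finger_tapping":
        epochs = [Epoch("rest", 0.0, 20.0)]
        t = 20.0
        for _ in range(5):
            for label in ("task_left", "rest", "task_right", "rest"):
                epochs.append(Epoch(label, t, 20.0)); t += 20.0
        return BlockDesign(tuple(epochs), session_length=t, initial_rest=20.0)
    raise ValueError(f"unknown design {name!r} "
                     "(choose 'tilt_or_breathhold' or 'finger_tapping')")


def hemodynamic_impulse_response(peak_time: float, undershoot_ratio: float,
                                 sampling_rate: float) -> np.ndarray:
    """Gamma-difference hemodynamic response kernel, unit peak, causal.

    The main lobe is a gamma density with its mode at `peak_time`; the
    undershoot is a wider gamma peaking at 16/6 x `peak_time`, scaled by
    `undershoot_ratio`. Support runs to peak_time x 16/6 + 15 s, beyond
    which the kernel is negligible.
    """
    if peak_time <= 0:
        raise ValueError("peak_time must be positive")
    if undershoot_ratio < 0:
        raise ValueError("undershoot_ratio must be non-negative")
    under_peak = peak_time * 16.0 / 6.0
    support = 2.5 * under_peak + 5.0  # lets the undershoot tail decay fully
    t = np.arange(0.0, support, 1.0 / sampling_rate)
    # gamma with shape a and scale b has mode (a-1)b
    main = gamma_dist.pdf(t, a=6.0, scale=peak_time / 5.0)
    main /= main.max()
    kernel = main
    if undershoot_ratio > 0:
        under = gamma_dist.pdf(t, a=16.0, scale=under_peak / 15.0)
        under /= under.max()
        kernel = main - undershoot_ratio * under
        kernel /= kernel.max()
    return kernel


def _convolve_boxcar(box: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(box, kernel)[: box.size]


def _contra_labels(side: str) -> set:
    """Task labels the given measurement side responds to (contralateral)."""
    if side == "left":
        return {"task", "task_right"}
    if side == "right":
        return {"task", "task_left"}
    raise ValueError(f"channel side must be 'left' or 'right', got {side!r}")


def generate_functional_component(design: BlockDesign, config: SynthConfig,
                                  channel_side: str) -> HemoSignal:
    """Lateralized neurovascular response: boxcar * HRF, exact k_F coupling.

    Contralateral task epochs drive the response at full amplitude,
    ipsilateral ones at the (smaller) ipsilateral amplitude; unlateralized
    'task' epochs count as contralateral for every channel.
    """
    contra = _contra_labels(channel_side)
    ipsi = (TASK_LABELS - contra) - {"task"}
    kernel = hemodynamic_impulse_response(config.hrf_peak, config.hrf_undershoot_ratio,
                                          config.sampling_rate)
    # area-normalize for convolution so a sustained task plateaus at `amplitude`
    kernel = kernel / kernel.sum()
    fs = config.sampling_rate
    hbo = config.functional_amplitude_contra * _convolve_boxcar(design.boxcar(fs, contra), kernel)
    if ipsi:
        hbo = hbo + config.functional_amplitude_ipsi * _convolve_boxcar(
            design.boxcar(fs, ipsi), kernel)
    return HemoSignal(fs, hbo, config.k_f_true * hbo)


def generate_systemic_component(design: BlockDesign, config: SynthConfig) -> HemoSignal:
    """Global systemic fluctuation, identical for all channels, exact k_S.

    Sum of a task-locked vasomotor response (boxcar over ALL task epochs
    convolved with a first-order low-pass step kernel, so left- and
    right-hand epochs contribute identically), a cardiac sinusoid, a
    Mayer-wave sinusoid and a seeded random-walk drift. Phases and drift
    derive deterministically from config.seed.
    """
    fs = config.sampling_rate
    n = int(round(design.session_length * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    # first-order kernel normalized so a sustained boxcar plateaus at 1
    tk = np.arange(0.0, 5.0 * config.systemic_tau, 1.0 / fs)
    kernel = np.exp(-tk / config.systemic_tau)
    kernel /= kernel.sum()
    task = config.systemic_amplitude * _convolve_boxcar(design.boxcar(fs, TASK_LABELS), kernel)

    cardiac = config.cardiac_amplitude * np.sin(
        2 * np.pi * config.cardiac_freq * t + rng.uniform(0, 2 * np.pi))
    mayer = config.mayer_amplitude * np.sin(
        2 * np.pi * config.mayer_freq * t + rng.uniform(0, 2 * np.pi))
    drift = np.cumsum(rng.normal(0.0, config.drift_sd, n))

    hbo = task + cardiac + mayer + drift
    return HemoSignal(fs, hbo, config.k_s_true * hbo)


def generate_session(design: BlockDesign, config: SynthConfig,
                     channels=(("Left", "left"), ("Right", "right")),
                     extinction: ExtinctionTable | None = None,
                     wavelengths=(780.0, 805.0, 830.0)) -> SyntheticSession:
    """Build a full session: truth components, mixing, noise, optional ΔA.

    `channels` is a sequence of (label, side) pairs. When an extinction
    table is supplied the observed signals are additionally pushed through
    the forward MBLL to produce an OpticalRecording at `wavelengths`
    (nominal 30 mm source–detector distance).
    """
    coeffs = ModalityCoefficients(config.k_f_true, config.k_s_true)
    systemic = generate_systemic_component(design, config)
    observed, truth, noise, sides = {}, {}, {}, {}
    for i, (label, side) in enumerate(channels):
        functional = generate_functional_component(design, config, side)
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1, i]))
        n_hbo = rng.normal(0.0, config.noise_sd, functional.n_samples)
        n_hbr = rng.normal(0.0, config.noise_sd, functional.n_samples)
        observed[label] = HemoSignal(
            config.sampling_rate,
            functional.hbo + systemic.hbo + n_hbo,
            functional.hbr + systemic.hbr + n_hbr,
        )
        truth[label] = ComponentPair(functional, systemic, coeffs)
        noise[label] = (n_hbo, n_hbr)
        sides[label] = side

    attenuation = None
    if extinction is not None:
        data = {label: hemoglobin_to_attenuation(sig, extinction, wavelengths)
                for label, sig in observed.items()}
        attenuation = OpticalRecording(
            config.sampling_rate, tuple(wavelengths),
            tuple(Channel(label, 30.0) for label, _ in channels), data)

    return SyntheticSession(observed, truth, noise, design, config, sides, attenuation)
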