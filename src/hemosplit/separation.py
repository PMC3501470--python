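"""Two-modality decomposition of fNIRS hemoglobin signals.

The observed signal is modelled as the sum of a *functional* component of
neurovascular origin, whose deoxyhemoglobin change is a negative multiple
of its oxyhemoglobin change,

    ΔHbR_F = k_F · ΔHbO_F,          k_F < 0,

and a *systemic* component from volume-capacity changes in arteries,
arterioles, venules and veins, whose coupling is positive,

    ΔHbR_S = k_S · ΔHbO_S,          k_S ≥ 0.

Given both slopes the decomposition is closed-form:

    ΔHbO_F = (k_S·ΔHbO − ΔHbR) / (k_S − k_F)
    ΔHbO_S = (ΔHbR − k_F·ΔHbO) / (k_S − k_F)

k_F is treated as a physiological constant (literature consensus ≈ −0.6),
while k_S depends on the vascular bed involved — k_S = (1 − S)/S for blood
oxygen saturation S — and is estimated per channel and session by
enumerating candidates over an ascending grid and minimizing the mutual
information between the two separated components, the two vascular
compartments being assumed statistically independent.

Mutual information is computed between the ΔHbO traces of the two
components only: within each component ΔHbR is an exact multiple of ΔHbO,
so the ΔHbO traces carry all the information. Densities are estimated by
normalized equal-width histograms over each series' observed range
(64 bins per axis by default); MI is reported in nats.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import HemoSignal

__all__ = [
    "ModalityCoefficients",
    "ComponentPair",
    "HistogramSpec",
    "KsEstimate",
    "separate_components",
    "mutual_information",
    "estimate_ks",
    "so2_to_ks",
    "summarize_kf_table",
    "load_kf_survey",
    "DEFAULT_KF",
]

log = logging.getLogger(__name__)

#: Consensus functional coupling slope adopted from the literature survey.
DEFAULT_KF = -0.6


@dataclass(frozen=True)
class ModalityCoefficients:
    """Coupling slopes of the two hemodynamic modalities."""

    k_f: float
    k_s: float

    def __post_init__(self):
        if not np.isfinite(self.k_f) or not np.isfinite(self.k_s):
            raise ValueError("coefficients must be finite")
        if self.k_f >= 0:
            raise ValueError(f"k_f must be negative, got {self.k_f}")
        if self.k_s < 0:
            raise ValueError(f"k_s must be non-negative, got {self.k_s}")
        # Defensive: cannot occur given the sign constraints above.
        if self.k_s == self.k_f:
            raise ValueError("k_s == k_f: separation system is singular")


@dataclass(frozen=True)
class ComponentPair:
    """Functional and systemic parts of one observed HemoSignal."""

    functional: HemoSignal
    systemic: HemoSignal
    coefficients: ModalityCoefficients | None = None

    @property
    def total(self) -> HemoSignal:
        return self.functional + self.systemic


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram density estimator settings: equal-width bins per axis,
    range = each series' observed min–max."""

    n_bins: int = 64

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


@dataclass(frozen=True)
class KsEstimate:
    """Result of grid-enumeration MI minimization for k_S."""

    k_s_hat: float
    grid: np.ndarray
    mi_profile: np.ndarray
    at_boundary: bool

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "mi_profile", np.asarray(self.mi_profile, dtype=float))
        if self.grid.shape != self.mi_profile.shape:
            raise ValueError("grid and mi_profile must have equal length")

    def n_local_minima(self, prominence_frac: float = 0.01) -> int:
        """Count interior + boundary minima of the MI profile.

        Sub-noise ripples are ignored: a minimum must be separated from the
        surrounding profile by more than `prominence_frac` of the profile's
        total range.
        """
        from scipy.signal import find_peaks

        rng = float(np.ptp(self.mi_profile))
        if rng == 0.0:
            return 1
        prom = prominence_frac * rng
        # find_peaks ignores boundary extrema; pad with +inf so boundary
        # minima are counted too.
        padded = np.concatenate([[np.inf], -self.mi_profile, [np.inf]])
        peaks, _ = find_peaks(padded, prominence=prom)
        return len(peaks)


def separate_components(sig: HemoSignal, coeffs: ModalityCoefficients) -> ComponentPair:
    """Closed-form split of `sig` into functional and systemic components.

    The sum of the two components reconstructs the input exactly (to float
    round-off), and each component lies exactly on its modality line.
    """
    denom = coeffs.k_s - coeffs.k_f
    hbo_f = (coeffs.k_s * sig.hbo - sig.hbr) / denom
    hbo_s = (sig.hbr - coeffs.k_f * sig.hbo) / denom
    functional = HemoSignal(sig.sampling_rate, hbo_f, coeffs.k_f * hbo_f, sig.units_label)
    systemic = HemoSignal(sig.sampling_rate, hbo_s, coeffs.k_s * hbo_s, sig.units_label)
    return ComponentPair(functional, systemic, coeffs)


def mutual_information(x, y, spec: HistogramSpec = HistogramSpec()) -> float:
    """Histogram-based mutual information of two series, in nats.

    MI = Σ_ij p(x_i, y_j) log[ p(x_i, y_j) / (p(x_i) p(y_j)) ] over occupied
    cells, with 0·log 0 := 0. The marginal and joint probabilities are the
    normalized 1-D and 2-D histograms of the inputs. A constant series
    carries no information and yields 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} != {y.size}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be 1-D with at least 2 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        log.warning("mutual_information: constant input series, returning 0")
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=spec.n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mask = p > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(p[mask] * np.log(p[mask] / outer[mask])))


def estimate_ks(sig: HemoSignal, k_f: float = DEFAULT_KF, grid_lo: float = 0.0,
                grid_hi: float = 1.0, grid_step: float = 0.01,
                spec: HistogramSpec = HistogramSpec()) -> KsEstimate:
    """Estimate the systemic slope k_S by enumerative MI minimization.

    For each candidate k_S on the ascending grid [grid_lo, grid_hi] the
    signal is separated and MI(ΔHbO_F, ΔHbO_S) recorded; the candidate with
    minimal MI is returned. Ties break toward the smallest candidate (the
    first minimum met in ascending order). A minimum sitting on either grid
    end is flagged `at_boundary`: a true k_S above the grid ceiling is
    estimated as the ceiling.

    An all-constant signal has no estimable slope; it yields a
    boundary-flagged estimate at `grid_lo` with a zero MI profile and a
    warning rather than an exception, so batch runs survive dead channels.
    """
    if not grid_lo < grid_hi:
        raise ValueError("grid_lo must be below grid_hi")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if k_f >= grid_lo:
        raise ValueError("k_f must lie below the candidate grid")
    n_steps = int(round((grid_hi - grid_lo) / grid_step))
    grid = grid_lo + grid_step * np.arange(n_steps + 1)

    if np.ptp(sig.hbo) == 0.0 and np.ptp(sig.hbr) == 0.0:
        log.warning("estimate_ks: constant signal, k_S undefined; returning grid_lo")
        return KsEstimate(float(grid[0]), grid, np.zeros_like(grid), True)

    mi = np.empty_like(grid)
    for i, ks in enumerate(grid):
        pair = separate_components(sig, ModalityCoefficients(k_f, float(ks)))
        mi[i] = mutual_information(pair.functional.hbo, pair.systemic.hbo, spec)
    best = int(np.argmin(mi))  # argmin takes the first minimum on ties
    return KsEstimate(float(grid[best]), grid, mi,
                      at_boundary=best in (0, len(grid) - 1))


def so2_to_ks(saturation: float) -> float:
    """Systemic slope implied by blood oxygen saturation: k_S = (1 − S)/S.

    A compartment at saturation S holds deoxy- and oxyhemoglobin in the
    ratio (1 − S) : S, and a pure volume-capacity change scales both
    proportionally. Arterial blood (S > 0.95) gives k_S < 0.053, venous
    blood (S ≈ 0.70) gives ≈ 0.43, and S = 0.50 after intense activity
    gives 1.0.
    """
    if not 0 < saturation <= 1:
        raise ValueError(f"saturation must be in (0, 1], got {saturation}")
    return (1.0 - saturation) / saturation


def summarize_kf_table(values) -> tuple[float, float]:
    """Mean and sample (n−1) standard deviation of surveyed k_F slopes."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return float(values.mean()), float(values.std(ddof=1))


def load_kf_survey() -> pd.DataFrame:
    """The packaged survey of published functional coupling slopes.

    One row per reported estimate (a study reporting two durations
    contributes two rows); column `k_f` holds the slopes.
    """
    ref = resources.files("hemosplit.data") / "kf_literature.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
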