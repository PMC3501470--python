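"""Modified Beer–Lambert law (MBLL) conversion.

Optical-attenuation changes ΔA(λ, t) at two or more wavelengths are mapped
to hemoglobin-concentration changes (ΔHbO, ΔHbR) by a least-squares
inversion of the molar-absorption matrix E (rows = wavelengths,
columns = HbO, HbR):

    ΔA(λ, t) = ε_HbO(λ)·ΔHbO(t) + ε_HbR(λ)·ΔHbR(t)

ΔA follows the optical-density convention ΔA = −log10(I/I0) (dimensionless).
No differential path-length factor is applied anywhere, so the hemoglobin
outputs are concentration x path length in arbitrary units; only relative
amplitudes carry meaning.

The default extinction table ships as a CSV data file compiled from the
standard NIR absorption literature; it is fully user-replaceable and no
coefficient is hard-coded in logic. Wavelength lookup is exact-match only —
interpolating between tabulated wavelengths would silently change the
inversion, so it is deliberately not offered.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import HemoSignal

__all__ = [
    "ExtinctionTable",
    "OpticalRecording",
    "Channel",
    "load_extinction_table",
    "default_extinction_table",
    "build_extinction_matrix",
    "attenuation_to_hemoglobin",
    "hemoglobin_to_attenuation",
]

log = logging.getLogger(__name__)

_RCOND = 1e-8  # relative singular-value cutoff declaring rank deficiency


class WavelengthLookupError(KeyError):
    """Requested wavelength has no exact entry in the extinction table."""


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar absorption coefficients ε_HbO(λ), ε_HbR(λ).

    entries: tuple of (wavelength_nm, eps_hbo, eps_hbr); units are
    consistent but arbitrary (only ratios matter for CW inversion).
    """

    entries: tuple[tuple[float, float, float], ...]
    source_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(tuple(map(float, e)) for e in self.entries))
        wls = [e[0] for e in self.entries]
        if len(set(wls)) != len(wls):
            raise ValueError("duplicate wavelengths in extinction table")
        for wl, eo, er in self.entries:
            if wl <= 0 or eo <= 0 or er <= 0:
                raise ValueError(f"non-positive entry at {wl} nm")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(e[0] for e in self.entries)

    def lookup(self, wavelength: float) -> tuple[float, float]:
        for wl, eo, er in self.entries:
            if wl == wavelength:
                return eo, er
        raise WavelengthLookupError(
            f"no extinction entry for {wavelength} nm "
            f"(available: {sorted(self.wavelengths)})"
        )


def load_extinction_table(path) -> ExtinctionTable:
    """Read an extinction table CSV with columns wavelength_nm, eps_hbo, eps_hbr."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "eps_hbo", "eps_hbr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"extinction table missing columns: {sorted(missing)}")
    entries = tuple(
        (row.wavelength_nm, row.eps_hbo, row.eps_hbr) for row in df.itertuples()
    )
    return ExtinctionTable(entries, source_label=str(path))


def default_extinction_table() -> ExtinctionTable:
    """The packaged literature compilation (mM⁻¹ cm⁻¹ scale)."""
    ref = resources.files("hemosplit.data") / "extinction_coefficients.csv"
    with resources.as_file(ref) as path:
        table = load_extinction_table(path)
    return ExtinctionTable(table.entries, source_label="packaged literature compilation")


@dataclass(frozen=True)
class Channel:
    label: str
    source_detector_distance: float  # mm


@dataclass(frozen=True)
class OpticalRecording:
    """ΔA(λ, t) per channel plus acquisition geometry.

    data maps channel label -> array of shape (n_wavelengths, n_samples),
    row order matching `wavelengths`.
    """

    sampling_rate: float
    wavelengths: tuple[float, ...]
    channels: tuple[Channel, ...]
    data: dict

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        object.__setattr__(self, "channels", tuple(self.channels))
        n_wl = len(self.wavelengths)
        lengths = set()
        data = {}
        for ch in self.channels:
            if ch.label not in self.data:
                raise ValueError(f"no data for channel {ch.label!r}")
            arr = np.asarray(self.data[ch.label], dtype=float)
            if arr.shape[0] != n_wl:
                raise ValueError(
                    f"channel {ch.label!r}: expected {n_wl} wavelength rows, got {arr.shape[0]}"
                )
            lengths.add(arr.shape[1])
            data[ch.label] = arr
        if len(lengths) > 1:
            raise ValueError(f"unequal series lengths across channels: {sorted(lengths)}")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[1] if self.data else 0


def build_extinction_matrix(table: ExtinctionTable, wavelengths) -> np.ndarray:
    """Assemble E with one row per requested wavelength, columns (HbO, HbR).

    Raises WavelengthLookupError for a missing wavelength and ValueError
    when the matrix is column-rank deficient (the two chromophores would be
    indistinguishable). The condition number is logged.
    """
    wavelengths = [float(w) for w in wavelengths]
    if len(wavelengths) < 2:
        raise ValueError("at least two wavelengths are required")
    E = np.array([table.lookup(wl) for wl in wavelengths], dtype=float)
    s = np.linalg.svd(E, compute_uv=False)
    if s[-1] <= _RCOND * s[0]:
        raise ValueError(
            "extinction matrix is rank deficient: HbO and HbR columns are "
            "(numerically) proportional for the requested wavelengths"
        )
    log.info("extinction matrix for %s nm: condition number %.3g",
             wavelengths, s[0] / s[-1])
    return E


def attenuation_to_hemoglobin(rec: OpticalRecording, table: ExtinctionTable) -> dict:
    """Invert the MBLL per channel: least-squares solve E·x = ΔA per sample.

    Returns {channel label: HemoSignal}. With two wavelengths this is the
    exact matrix inverse; with more it is the normal-equations solution
    (Moore–Penrose pseudo-inverse applied to each time point).
    """
    E = build_extinction_matrix(table, rec.wavelengths)
    pinv = np.linalg.pinv(E)
    out = {}
    for ch in rec.channels:
        arr = rec.data[ch.label]
        if not np.all(np.isfinite(arr)):
            wl_i, t_i = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite attenuation in channel {ch.label!r} "
                f"(wavelength {rec.wavelengths[wl_i]} nm, sample {t_i})"
            )
        if np.ptp(arr) == 0.0:
            log.warning("channel %s: constant attenuation; hemoglobin output is all-zero offset",
                        ch.label)
        hb = pinv @ arr  # (2, n_samples)
        out[ch.label] = HemoSignal(rec.sampling_rate, hb[0], hb[1])
    return out


def hemoglobin_to_attenuation(sig: HemoSignal, table: ExtinctionTable,
                              wavelengths) -> np.ndarray:
    """Forward MBLL: ΔA(λ, t) = ε_HbO(λ)·hbo(t) + ε_HbR(λ)·hbr(t).

    Returns an array of shape (n_wavelengths, n_samples) suitable as one
    channel of an OpticalRecording.
    """
    E = build_extinction_matrix(table, wavelengths)
    return E @ np.vstack([sig.hbo, sig.hbr])
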