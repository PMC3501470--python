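"""Delimited-text readers/writers, session config and run manifests.

Column-name dialect (chosen for greppability):

* hemoglobin CSV — ``<channel>__hbo`` and ``<channel>__hbr`` per channel;
* attenuation CSV — ``<channel>__<wavelength>nm`` per channel x wavelength.

Sampling rate, geometry and separation settings travel in a YAML sidecar
(`SessionConfig`), never inside the CSV. NaNs are rejected by default;
with ``allow_gaps`` gaps of at most 0.5 s are linearly interpolated with a
warning.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BlockDesign, Epoch, HemoSignal
from .mbll import Channel, OpticalRecording

__all__ = [
    "SessionConfig",
    "read_hemo_csv",
    "write_hemo_csv",
    "read_attenuation_csv",
    "write_attenuation_csv",
    "read_design",
    "write_design",
    "load_session_config",
    "write_manifest",
]

log = logging.getLogger(__name__)

_MAX_GAP_S = 0.5
_ATT_COL = re.compile(r"^(?P<channel>.+)__(?P<wl>[0-9.]+)nm$")
_HEMO_COL = re.compile(r"^(?P<channel>.+)__(?P<kind>hbo|hbr)$")


class ParseError(ValueError):
    """Malformed input file (message carries row/column context)."""


def _read_numeric_csv(path, allow_gaps: bool, sampling_rate: float) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        bad = series.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(f"{path}: non-numeric cell at row {row + 2}, "
                             f"column {col!r}")  # +2: header + 1-based
        df[col] = series
    if df.isna().any().any():
        if not allow_gaps:
            col = df.columns[df.isna().any()][0]
            row = int(df[col].isna().idxmax())
            raise ParseError(f"{path}: missing value at row {row + 2}, column "
                             f"{col!r} (pass allow_gaps to interpolate)")
        max_gap = int(round(_MAX_GAP_S * sampling_rate))
        for col in df.columns:
            na = df[col].isna()
            if not na.any():
                continue
            # longest run of consecutive NaNs
            runs = (na.groupby((~na).cumsum()).sum()).max()
            if runs > max_gap:
                raise ParseError(f"{path}: gap of {runs} samples in column "
                                 f"{col!r} exceeds the {_MAX_GAP_S} s limit")
            df[col] = df[col].interpolate(limit_direction="both")
            log.warning("%s: interpolated %d missing samples in column %s",
                        path, int(na.sum()), col)
    return df


def read_hemo_csv(path, sampling_rate: float, channels=None,
                  allow_gaps: bool = False) -> dict:
    """Read a hemoglobin CSV into {channel: HemoSignal}.

    `channels` optionally declares the expected channel labels; a declared
    channel missing from the header is a schema error.
    """
    df = _read_numeric_csv(path, allow_gaps, sampling_rate)
    found = {}
    for col in df.columns:
        m = _HEMO_COL.match(col)
        if not m:
            raise ParseError(f"{path}: column {col!r} does not match "
                             "'<channel>__hbo' / '<channel>__hbr'")
        found.setdefault(m["channel"], {})[m["kind"]] = df[col].to_numpy()
    if channels is not None:
        missing = set(channels) - set(found)
        if missing:
            raise ParseError(f"{path}: declared channels missing from header: "
                             f"{sorted(missing)}")
    out = {}
    for ch, parts in found.items():
        if set(parts) != {"hbo", "hbr"}:
            raise ParseError(f"{path}: channel {ch!r} lacks "
                             f"{sorted({'hbo', 'hbr'} - set(parts))} column")
        out[ch] = HemoSignal(sampling_rate, parts["hbo"], parts["hbr"])
    log.info("%s: read %d samples x %d channels", path, len(df), len(out))
    return out


def write_hemo_csv(signals: dict, path) -> None:
    cols = {}
    for ch, sig in signals.items():
        cols[f"{ch}__hbo"] = sig.hbo
        cols[f"{ch}__hbr"] = sig.hbr
    pd.DataFrame(cols).to_csv(path, index=False)


def read_attenuation_csv(path, sampling_rate: float, distances: dict | None = None,
                         allow_gaps: bool = False) -> OpticalRecording:
    """Read an attenuation CSV into an OpticalRecording.

    `distances` maps channel label -> source-detector distance in mm
    (defaults to 30 mm when omitted).
    """
    df = _read_numeric_csv(path, allow_gaps, sampling_rate)
    per_channel = {}
    wavelengths = []
    for col in df.columns:
        m = _ATT_COL.match(col)
        if not m:
            raise ParseError(f"{path}: column {col!r} does not match "
                             "'<channel>__<wavelength>nm'")
        wl = float(m["wl"])
        if wl not in wavelengths:
            wavelengths.append(wl)
        per_channel.setdefault(m["channel"], {})[wl] = df[col].to_numpy()
    wavelengths = sorted(wavelengths)
    data, channels = {}, []
    for ch, series in per_channel.items():
        missing = set(wavelengths) - set(series)
        if missing:
            raise ParseError(f"{path}: channel {ch!r} lacks wavelengths "
                             f"{sorted(missing)}")
        data[ch] = np.vstack([series[wl] for wl in wavelengths])
        dist = 30.0 if distances is None else float(distances.get(ch, 30.0))
        channels.append(Channel(ch, dist))
    return OpticalRecording(sampling_rate, tuple(wavelengths), tuple(channels), data)


def write_attenuation_csv(rec: OpticalRecording, path) -> None:
    cols = {}
    for ch in rec.channels:
        for i, wl in enumerate(rec.wavelengths):
            wl_txt = f"{wl:g}"
            cols[f"{ch.label}__{wl_txt}nm"] = rec.data[ch.label][i]
    pd.DataFrame(cols).to_csv(path, index=False)


# ------------------------------------------------------------------ designs

def read_design(path) -> BlockDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    epochs = tuple(Epoch(str(e["label"]), float(e["onset"]), float(e["duration"]))
                   for e in raw["epochs"])
    return BlockDesign(epochs, float(raw["session_length"]),
                       float(raw.get("initial_rest", 0.0)))


def write_design(design: BlockDesign, path) -> None:
    payload = {
        "session_length": design.session_length,
        "initial_rest": design.initial_rest,
        "epochs": [{"label": ep.label, "onset": ep.onset, "duration": ep.duration}
                   for ep in design.epochs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ------------------------------------------------------------------- config

@dataclass(frozen=True)
class SessionConfig:
    """Validated top-level run settings loaded from YAML."""

    sampling_rate: float
    wavelengths: tuple = ()
    channels: tuple = ()          # (label, distance_mm) pairs
    design: BlockDesign | None = None
    k_f: float = -0.6
    grid: tuple = (0.0, 1.0, 0.01)  # lo, hi, step
    n_bins: int = 64
    extinction_path: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.k_f >= 0:
            raise ValueError("k_f must be negative")
        lo, hi, step = self.grid
        if not (lo < hi and step > 0):
            raise ValueError("grid must be (lo, hi, step) with lo < hi, step > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


def load_session_config(path) -> SessionConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    design = None
    if "design" in raw:
        d = raw["design"]
        if isinstance(d, str):
            design_path = Path(d)
            if not design_path.is_absolute():
                design_path = path.parent / design_path
            if not design_path.exists():
                raise FileNotFoundError(f"design file {design_path} not found")
            design = read_design(design_path)
        else:
            design = BlockDesign(
                tuple(Epoch(str(e["label"]), float(e["onset"]), float(e["duration"]))
                      for e in d["epochs"]),
                float(d["session_length"]), float(d.get("initial_rest", 0.0)))
    sep = raw.get("separation", {})
    extinction = raw.get("extinction")
    if extinction is not None:
        ext_path = Path(extinction)
        if not ext_path.is_absolute():
            ext_path = path.parent / ext_path
        if not ext_path.exists():
            raise FileNotFoundError(f"extinction table {ext_path} not found")
        extinction = str(ext_path)
    return SessionConfig(
        sampling_rate=float(raw["sampling_rate"]),
        wavelengths=tuple(float(w) for w in raw.get("wavelengths", ())),
        channels=tuple((str(c["label"]), float(c.get("distance_mm", 30.0)))
                       for c in raw.get("channels", ())),
        design=design,
        k_f=float(sep.get("k_f", -0.6)),
        grid=tuple(float(g) for g in sep.get("grid", (0.0, 1.0, 0.01))),
        n_bins=int(sep.get("n_bins", 64)),
        extinction_path=extinction,
        seed=int(raw.get("seed", 0)),
    )


def write_manifest(path, settings: dict) -> None:
    """Machine-readable echo of everything a rerun needs."""
    import hemosplit

    payload = {"hemosplit_version": hemosplit.__version__,
               "numpy_version": np.__version__, **settings}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
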