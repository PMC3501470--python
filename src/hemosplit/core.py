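"""Core containers shared across the package.

Hemoglobin series are expressed as concentration x optical path length in
arbitrary units: with continuous-wave instruments the differential path
length is unknown, so no division by a path-length factor is ever applied
and only relative amplitudes are meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HemoSignal", "Epoch", "BlockDesign", "TASK_LABELS"]

#: Epoch labels that count as task execution (as opposed to rest).
TASK_LABELS = frozenset({"task", "task_left", "task_right"})


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains a non-finite value at index {bad}")
    return arr


@dataclass(frozen=True)
class HemoSignal:
    """Paired oxy-/deoxyhemoglobin change series for one channel.

    Parameters
    ----------
    sampling_rate : float
        Samples per second, > 0.
    hbo, hbr : array-like
        Equal-length ΔHbO and ΔHbR series (concentration x path length,
        arbitrary scale).
    units_label : str
        Free-text record of the (arbitrary) units.
    """

    sampling_rate: float
    hbo: np.ndarray
    hbr: np.ndarray
    units_label: str = "mM x mm (arbitrary path length)"

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "hbo", _as_float_array(self.hbo, "hbo"))
        object.__setattr__(self, "hbr", _as_float_array(self.hbr, "hbr"))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError(
                f"hbo and hbr must have equal length "
                f"({self.hbo.size} != {self.hbr.size})"
            )

    @property
    def n_samples(self) -> int:
        return self.hbo.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def __add__(self, other: "HemoSignal") -> "HemoSignal":
        if other.sampling_rate != self.sampling_rate:
            raise ValueError("sampling rates differ")
        return HemoSignal(self.sampling_rate, self.hbo + other.hbo,
                          self.hbr + other.hbr, self.units_label)


@dataclass(frozen=True)
class Epoch:
    label: str
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class BlockDesign:
    """Ordered task/rest epochs of a block-design session.

    Epochs must be non-overlapping, time-ordered and contained in
    ``[0, session_length]``.
    """

    epochs: tuple[Epoch, ...]
    session_length: float
    initial_rest: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "epochs", tuple(self.epochs))
        prev_end = 0.0
        for ep in self.epochs:
            if ep.duration <= 0:
                raise ValueError(f"epoch {ep.label}@{ep.onset}: duration must be > 0")
            if ep.onset < prev_end - 1e-9:
                raise ValueError(f"epoch {ep.label}@{ep.onset} overlaps its predecessor")
            prev_end = ep.end
        if prev_end > self.session_length + 1e-9:
            raise ValueError("epochs extend past session_length")

    def select(self, labels) -> tuple[Epoch, ...]:
        """Epochs whose label is in `labels` (a str or an iterable of str)."""
        if isinstance(labels, str):
            labels = {labels}
        labels = set(labels)
        return tuple(ep for ep in self.epochs if ep.label in labels)

    @property
    def task_epochs(self) -> tuple[Epoch, ...]:
        return self.select(TASK_LABELS)

    def boxcar(self, sampling_rate: float, labels=None) -> np.ndarray:
        """0/1 indicator sampled at `sampling_rate` over the whole session.

        `labels` defaults to all task labels.
        """
        if labels is None:
            labels = TASK_LABELS
        n = int(round(self.session_length * sampling_rate))
        t = np.arange(n) / sampling_rate
        box = np.zeros(n)
        for ep in self.select(labels):
            box[(t >= ep.onset) & (t < ep.end)] = 1.0
        return box

    def preceding_rest(self, epoch: Epoch) -> Epoch | None:
        """The rest epoch immediately before `epoch`, if any."""
        best = None
        for ep in self.epochs:
            if ep.label == "rest" and ep.end <= epoch.onset + 1e-9:
                if best is None or ep.end > best.end:
                    best = ep
        return best
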