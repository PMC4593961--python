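"""Turn raw multichannel EMG into baseline-corrected per-channel RMS.

The analysis chain is: zero-phase band-pass of the continuous record,
RMS over the steady active window and over a rest window per channel,
rest subtraction (floored at zero by default), and averaging across the
repetitions of a condition.

Filtering is applied to the whole continuous recording rather than to
individual windows so that filter edge transients fall outside every
analysis window; the first and last ``EDGE_GUARD_S`` seconds of a
filtered record are excluded from any analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .exceptions import InvalidConfigurationError, InvalidInputError

__all__ = [
    "FINGERS",
    "TASKS",
    "EFFORTS",
    "CONSTRAINTS",
    "Condition",
    "TaskTrial",
    "EmgRecording",
    "bandpass",
    "channel_rms",
    "baseline_corrected_rms",
    "average_repetitions",
    "mean_grid_rms",
    "normalize_subject_effort",
    "condition_rms",
    "EDGE_GUARD_S",
]

FINGERS = ("index", "middle", "ring", "little")
TASKS = FINGERS + ("four",)
EFFORTS = ("high", "low")
CONSTRAINTS = ("dynamic", "static")

#: Seconds trimmed from each end of a filtered record before any window
#: may begin/end (filter edge-transient guard).
EDGE_GUARD_S = 0.25


@dataclass(frozen=True, order=True)
class Condition:
    """One experimental cell: instructed finger x effort x constraint."""

    finger: str
    effort: str
    constraint: str

    def __post_init__(self) -> None:
        if self.finger not in TASKS:
            raise InvalidInputError(f"unknown finger {self.finger!r}; expected one of {TASKS}")
        if self.effort not in EFFORTS:
            raise InvalidInputError(f"unknown effort {self.effort!r}; expected one of {EFFORTS}")
        if self.constraint not in CONSTRAINTS:
            raise InvalidInputError(
                f"unknown constraint {self.constraint!r}; expected one of {CONSTRAINTS}"
            )

    @property
    def label(self) -> str:
        return f"{self.finger}-{self.effort}-{self.constraint}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        parts = label.split("-")
        if len(parts) != 3:
            raise InvalidInputError(f"malformed condition label {label!r}")
        return cls(*parts)


@dataclass(frozen=True)
class TaskTrial:
    """Annotation of one contraction: active window plus its paired rest.

    Windows are ``(start, stop)`` in samples, stop exclusive.  The rest
    window is taken from the rest period immediately preceding the
    contraction, so each repetition carries its own baseline.
    """

    condition: Condition
    active_window: tuple[int, int]
    rest_window: tuple[int, int]
    repetition: int

    def __post_init__(self) -> None:
        for name, (a, b) in (("active", self.active_window), ("rest", self.rest_window)):
            if not (0 <= a < b):
                raise InvalidInputError(f"{name}_window {a, b} is empty or negative")
        ra, rb = self.rest_window
        aa, ab = self.active_window
        if max(ra, aa) < min(rb, ab):
            raise InvalidInputError("active and rest windows overlap")
        if self.repetition < 1:
            raise InvalidInputError("repetition is 1-based")


@dataclass
class EmgRecording:
    """A channels x samples signal block with its annotations.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
    fs : float
        Sampling rate, Hz.
    trials : list of TaskTrial
    meta : dict
        Free-form provenance (subject id, seed, grid reference, ...).
    """

    signal: np.ndarray
    fs: float
    trials: list[TaskTrial] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise InvalidInputError("signal must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise InvalidConfigurationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def bandpass(
    recording: EmgRecording,
    low_hz: float = 20.0,
    high_hz: float = 400.0,
    order: int = 2,
) -> EmgRecording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward and backward (double pass), doubling
    the effective attenuation and cancelling phase shift, so window
    positions are unaffected by filtering.

    Parameters
    ----------
    recording
        Continuous multichannel recording.
    low_hz, high_hz
        Pass-band edges; must satisfy ``0 < low < high < fs / 2``.
    order
        Order of the underlying Butterworth design (per pass).

    Returns
    -------
    EmgRecording
        New recording with filtered signal; annotations and metadata are
        carried over.
    """
    nyq = recording.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidConfigurationError(
            f"band edges ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < {nyq} Hz"
        )
    if order < 1:
        raise InvalidConfigurationError("filter order must be >= 1")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.signal, axis=1)
    meta = dict(recording.meta)
    meta["filter"] = {"low_hz": low_hz, "high_hz": high_hz, "order": order, "zero_phase": True}
    return EmgRecording(signal=filtered, fs=recording.fs, trials=list(recording.trials), meta=meta)


def channel_rms(signal_window: np.ndarray) -> float | np.ndarray:
    """Root-mean-square amplitude of a window.

    For a 1-D window returns a scalar; for a 2-D channels x samples
    block returns the per-channel vector.  Non-negative and
    scale-equivariant: ``rms(k * s) == |k| * rms(s)``.
    """
    w = np.asarray(signal_window, dtype=float)
    if w.size == 0:
        raise InvalidInputError("RMS of an empty window is undefined")
    out = np.sqrt(np.mean(np.square(w), axis=-1))
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def _check_window(window: tuple[int, int], recording: EmgRecording, guard: int) -> None:
    a, b = window
    if a < guard or b > recording.n_samples - guard:
        raise InvalidInputError(
            f"window [{a}, {b}) must lie within the guarded record "
            f"[{guard}, {recording.n_samples - guard}) "
            f"({EDGE_GUARD_S} s edge-transient trim at fs={recording.fs} Hz)"
        )


def baseline_corrected_rms(
    trial: TaskTrial,
    recording: EmgRecording,
    floor_at_zero: bool = True,
) -> np.ndarray:
    """Per-channel active RMS minus rest RMS for one trial.

    Parameters
    ----------
    trial
        Annotation carrying the active and paired rest windows.
    recording
        The band-passed continuous recording.
    floor_at_zero
        If True (default) negative differences are clipped to 0:
        negative "activation" is physically meaningless and would
        corrupt downstream centroid weights.  Set False to retain raw
        differences.

    Returns
    -------
    ndarray, shape (n_channels,)
    """
    guard = int(round(EDGE_GUARD_S * recording.fs))
    _check_window(trial.active_window, recording, guard)
    _check_window(trial.rest_window, recording, guard)
    a0, a1 = trial.active_window
    r0, r1 = trial.rest_window
    active = channel_rms(recording.signal[:, a0:a1])
    rest = channel_rms(recording.signal[:, r0:r1])
    diff = np.asarray(active) - np.asarray(rest)
    if floor_at_zero:
        diff = np.maximum(diff, 0.0)
    return diff


def average_repetitions(per_rep_rms: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-repetition RMS vectors."""
    if len(per_rep_rms) == 0:
        raise InvalidInputError("need at least one repetition")
    arrays = [np.asarray(v, dtype=float) for v in per_rep_rms]
    n = arrays[0].shape
    if any(a.shape != n for a in arrays):
        raise InvalidInputError("repetition vectors have mismatched lengths")
    return np.mean(arrays, axis=0)


def mean_grid_rms(map_values: np.ndarray) -> float:
    """Mean RMS across all channels — the scalar effort-level summary."""
    v = np.asarray(map_values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("cannot average an empty map")
    return float(np.mean(v))


def normalize_subject_effort(
    mean_rms_by_condition: Mapping[Condition, float],
) -> dict[Condition, float]:
    """Normalize a subject's condition table by their reference effort.

    The reference is the highest mean RMS among that subject's
    four-finger high-effort conditions; the reference condition maps to
    exactly 1.0.
    """
    refs = {
        c: v
        for c, v in mean_rms_by_condition.items()
        if c.finger == "four" and c.effort == "high"
    }
    if not refs:
        raise InvalidInputError("table lacks a four-finger high-effort reference condition")
    ref = max(refs.values())
    if ref <= 0:
        raise InvalidInputError("reference mean RMS is zero; cannot normalize")
    return {c: float(v) / ref for c, v in mean_rms_by_condition.items()}


def condition_rms(
    recording: EmgRecording,
    condition: Condition,
    floor_at_zero: bool = True,
) -> np.ndarray:
    """Baseline-corrected RMS averaged over a condition's repetitions.

    Convenience wrapper: selects the recording's trials for
    ``condition``, corrects each against its paired rest window, and
    averages across repetitions.
    """
    trials = [t for t in recording.trials if t.condition == condition]
    if not trials:
        raise InvalidInputError(f"recording has no trials for condition {condition.label!r}")
    per_rep = [baseline_corrected_rms(t, recording, floor_at_zero) for t in trials]
    return average_repetitions(per_rep)
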