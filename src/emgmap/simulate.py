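"""Synthetic multichannel surface-EMG generator with full ground truth.

The generator emulates the statistical structure the analysis pipeline
consumes, with no claim to biophysical realism:

* each finger's muscle compartment is a 2-D Gaussian amplitude
  territory over the grid plane in relative coordinates;
* instructed tasks recruit compartments through an enslaving matrix
  (own compartment fully, neighbours at a low fraction);
* effort scales compartment gains; the dynamic constraint shifts
  territory centers by a configurable displacement;
* the signal on each channel is an independent band-limited Gaussian
  carrier whose local RMS follows the configured activation envelope,
  with additive baseline noise present in both rest and active windows.

Compartment RMS contributions combine as root-sum-of-squares
(independent carriers add in power).  Per-channel RMS amplitude is the
only signal property the downstream analysis uses, so interference-EMG
carriers are a sufficient stand-in for motor-unit activity.

Everything is deterministic given a seed; per-condition and per-subject
streams are derived from :class:`numpy.random.SeedSequence` spawns so
recordings are reproducible independently of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import signal as sp_signal

from .exceptions import InvalidConfigurationError, InvalidInputError
from .grid import ElectrodeGrid, build_grid
from .preprocessing import (
    CONSTRAINTS,
    EFFORTS,
    FINGERS,
    TASKS,
    Condition,
    EmgRecording,
    TaskTrial,
)

__all__ = [
    "CompartmentModel",
    "EnslavingMatrix",
    "SimulationConfig",
    "CohortJitter",
    "default_compartments",
    "default_config",
    "spatial_weights",
    "simulate_recording",
    "subject_configs",
    "generate_cohort",
    "all_conditions",
]


@dataclass(frozen=True)
class CompartmentModel:
    """Gaussian activation territory of one finger's compartment.

    ``center`` and ``spread`` are in relative grid coordinates
    (% circumference, % forearm length); ``gain`` is the peak RMS
    amplitude at the territory center.
    """

    finger: str
    center: tuple[float, float]
    spread: tuple[float, float]
    gain: float

    def __post_init__(self) -> None:
        if self.finger not in FINGERS:
            raise InvalidConfigurationError(f"unknown compartment finger {self.finger!r}")
        if self.spread[0] <= 0 or self.spread[1] <= 0:
            raise InvalidConfigurationError("compartment spread must be positive")
        # gain 0 is allowed so a silent (pure-noise) session can be simulated
        if self.gain < 0:
            raise InvalidConfigurationError("compartment gain must be non-negative")


@dataclass(frozen=True)
class EnslavingMatrix:
    """Task x compartment activation fractions.

    Rows are the five instructed tasks (four single fingers plus the
    four-finger task), columns the four finger compartments.  The
    instructed finger's own entry is 1 and the four-finger row is all
    ones; off-diagonal entries model low-level co-activation of
    neighbouring compartments.
    """

    values: np.ndarray  # shape (5, 4), rows ordered as TASKS, cols as FINGERS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(TASKS), len(FINGERS)):
            raise InvalidConfigurationError(
                f"enslaving matrix must be {len(TASKS)} x {len(FINGERS)}, got {v.shape}"
            )
        if np.any(v < 0):
            raise InvalidConfigurationError("enslaving fractions must be non-negative")
        for i, task in enumerate(TASKS[:-1]):
            if not np.isclose(v[i, FINGERS.index(task)], 1.0):
                raise InvalidConfigurationError(
                    f"instructed finger {task!r} must have enslaving fraction 1"
                )
        if not np.allclose(v[TASKS.index("four")], 1.0):
            raise InvalidConfigurationError("four-finger row must be all ones")
        object.__setattr__(self, "values", v)

    def fraction(self, task: str, finger: str) -> float:
        return float(self.values[TASKS.index(task), FINGERS.index(finger)])

    @classmethod
    def default(cls, neighbour: float = 0.15, far: float = 0.05) -> "EnslavingMatrix":
        """Order-of-magnitude co-activation defaults.

        No quantitative enslaving levels are available for this muscle,
        so adjacent fingers get ``neighbour`` and non-adjacent fingers
        ``far``; both are freely overridable.
        """
        order = list(FINGERS)  # anatomical adjacency: index-middle-ring-little
        v = np.zeros((len(TASKS), len(FINGERS)))
        for i, task in enumerate(TASKS[:-1]):
            for j, fing in enumerate(FINGERS):
                if task == fing:
                    v[i, j] = 1.0
                elif abs(order.index(task) - order.index(fing)) == 1:
                    v[i, j] = neighbour
                else:
                    v[i, j] = far
        v[len(TASKS) - 1] = 1.0
        return cls(values=v)


def default_compartments() -> tuple[CompartmentModel, ...]:
    """Compartment layout matching the qualitative territory geography:

    index most distal (~60% forearm length), middle most proximal
    (~30%), ring and little intermediate (~40-50%) and mutually close;
    radial-to-ulnar ordering ring, index/little, middle.
    """
    return (
        CompartmentModel("index", center=(45.0, 60.0), spread=(9.0, 10.0), gain=1.0),
        CompartmentModel("middle", center=(60.0, 30.0), spread=(9.0, 10.0), gain=1.0),
        CompartmentModel("ring", center=(38.0, 44.0), spread=(9.0, 10.0), gain=1.0),
        CompartmentModel("little", center=(50.0, 48.0), spread=(9.0, 10.0), gain=0.85),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated subject/session."""

    grid: ElectrodeGrid
    compartments: tuple[CompartmentModel, ...]
    enslaving: EnslavingMatrix
    effort_gain: dict = field(default_factory=lambda: {"high": 1.0, "low": 0.4})
    dynamic_shift: tuple[float, float] = (2.0, -3.0)
    noise_rms: float = 0.05
    fs: float = 2000.0
    n_reps: int = 3
    active_s: float = 5.0
    rest_s: float = 4.0
    pad_s: float = 0.5
    band: tuple[float, float] = (20.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.compartments:
            raise InvalidConfigurationError("at least one compartment is required")
        eg = self.effort_gain
        if "high" not in eg or "low" not in eg:
            raise InvalidConfigurationError("effort_gain must define 'high' and 'low'")
        if any(g <= 0 for g in eg.values()):
            raise InvalidConfigurationError("effort gains must be positive")
        if self.noise_rms < 0:
            raise InvalidConfigurationError("noise_rms must be non-negative")
        if self.fs <= 2 * self.band[1]:
            raise InvalidConfigurationError("fs must exceed twice the carrier band upper edge")
        if self.n_reps < 1 or self.active_s <= 0 or self.rest_s <= 0 or self.pad_s < 0:
            raise InvalidConfigurationError("invalid protocol timing")


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default 63-channel simulated session."""
    cfg = SimulationConfig(
        grid=build_grid(7, 9, (0.0, 100.0)),
        compartments=default_compartments(),
        enslaving=EnslavingMatrix.default(),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def all_conditions() -> list[Condition]:
    """The full 5 x 2 x 2 condition design, in deterministic order."""
    return [
        Condition(f, e, c)
        for f in TASKS
        for e in EFFORTS
        for c in CONSTRAINTS
    ]


def spatial_weights(compartment: CompartmentModel, grid: ElectrodeGrid) -> np.ndarray:
    """Per-channel amplitude of a compartment territory.

    ``w(channel) = gain * exp(-(x - cx)^2 / (2 sx^2) - (y - cy)^2 / (2 sy^2))``
    evaluated at each electrode's relative coordinates.
    """
    x, y = grid.coordinate_arrays()
    cx, cy = compartment.center
    sx, sy = compartment.spread
    return compartment.gain * np.exp(
        -((x - cx) ** 2) / (2 * sx**2) - ((y - cy) ** 2) / (2 * sy**2)
    )


def _condition_stream(seed: int, condition: Condition) -> np.random.Generator:
    """Deterministic, order-independent RNG for one condition."""
    key = zlib.crc32(condition.label.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def noise_free_rms(config: SimulationConfig, condition: Condition) -> np.ndarray:
    """Per-channel noise-free active RMS for a condition (ground truth).

    Compartment contributions add in power: the channel RMS is the
    root-sum-of-squares of ``effort_gain * enslaving_fraction * weight``
    over compartments.
    """
    effort = config.effort_gain[condition.effort]
    shift = config.dynamic_shift if condition.constraint == "dynamic" else (0.0, 0.0)
    power = np.zeros(config.grid.n_channels)
    for comp in config.compartments:
        shifted = replace(
            comp,
            center=(comp.center[0] + shift[0], comp.center[1] + shift[1]),
        )
        frac = config.enslaving.fraction(condition.finger, comp.finger)
        amp = effort * frac * spatial_weights(shifted, config.grid)
        power += amp**2
    return np.sqrt(power)


def _band_limited_carriers(
    n_channels: int, n_samples: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Independent band-limited Gaussian carriers calibrated to unit RMS.

    Calibration is performed *after* the default analysis band-pass
    (2nd-order Butterworth over ``band``, double pass): that filter's
    soft passband removes ~8% of in-band carrier RMS, so normalizing the
    raw carrier instead would make configured amplitudes systematically
    unrecoverable downstream.
    """
    white = rng.standard_normal((n_channels, n_samples))
    sos = sp_signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    carriers = sp_signal.sosfiltfilt(sos, white, axis=1)
    sos_analysis = sp_signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    analyzed = sp_signal.sosfiltfilt(sos_analysis, carriers, axis=1)
    rms = np.sqrt(np.mean(analyzed**2, axis=1, keepdims=True))
    return carriers / rms


def simulate_recording(
    config: SimulationConfig, condition: Condition
) -> tuple[EmgRecording, dict]:
    """Simulate one condition's recording (all repetitions) plus truth.

    The record layout is ``pad, (rest, active) x n_reps, pad``.  Each
    trial annotation pairs the 5-s active window with the final 2 s of
    the rest period immediately preceding it.

    Returns
    -------
    (EmgRecording, dict)
        The recording and a ground-truth dict with keys
        ``rms_map`` (noise-free per-channel active RMS), ``centroid``
        (its exact discrete weighted centroid as an ``(cx, cy)`` tuple),
        and ``config``/``condition`` references.
    """
    if condition.finger not in TASKS:
        raise InvalidInputError(f"condition outside design: {condition!r}")
    fs = config.fs
    n_pad = int(round(config.pad_s * fs))
    n_rest = int(round(config.rest_s * fs))
    n_active = int(round(config.active_s * fs))
    n_rest_window = min(n_rest, int(round(2.0 * fs)))
    cycle = n_rest + n_active
    n_samples = 2 * n_pad + config.n_reps * cycle

    target = noise_free_rms(config, condition)  # (n_channels,)
    n_ch = config.grid.n_channels

    # Per-sample RMS envelope: sqrt(active_power + noise^2) inside the
    # active windows, noise_rms elsewhere.
    envelope = np.full((n_ch, n_samples), config.noise_rms)
    trials = []
    for rep in range(config.n_reps):
        start = n_pad + rep * cycle
        a0, a1 = start + n_rest, start + n_rest + n_active
        envelope[:, a0:a1] = np.sqrt(target**2 + config.noise_rms**2)[:, None]
        trials.append(
            TaskTrial(
                condition=condition,
                active_window=(a0, a1),
                rest_window=(a0 - n_rest_window, a0),
                repetition=rep + 1,
            )
        )

    rng = _condition_stream(config.seed, condition)
    carriers = _band_limited_carriers(n_ch, n_samples, fs, config.band, rng)
    recording = EmgRecording(
        signal=carriers * envelope,
        fs=fs,
        trials=trials,
        meta={
            "condition": condition.label,
            "seed": config.seed,
            "noise_rms": config.noise_rms,
            "grid": config.grid.to_dict(),
            "synthetic": True,
        },
    )
    # Exact centroid of the noise-free map on the discrete grid.
    total = target.sum()
    x, y = config.grid.coordinate_arrays()
    truth = {
        "rms_map": target,
        "centroid": (
            (float((target * x).sum() / total), float((target * y).sum() / total))
            if total > 0
            else None
        ),
        "condition": condition.label,
        "noise_rms": config.noise_rms,
    }
    return recording, truth


@dataclass(frozen=True)
class CohortJitter:
    """Between-subject variability of the simulated cohort.

    ``center_sd`` (in % coordinates) perturbs compartment centers,
    ``gain_sd`` multiplies gains by ``exp(N(0, gain_sd))``, and
    ``enslaving_sd`` jitters the off-diagonal co-activation fractions
    (clipped at 0; structural ones stay at 1).
    """

    center_sd: float = 2.0
    gain_sd: float = 0.15
    enslaving_sd: float = 0.02


def subject_configs(
    template: SimulationConfig,
    n_subjects: int,
    seed: int,
    jitter: CohortJitter = CohortJitter(),
) -> list[SimulationConfig]:
    """Deterministically jittered per-subject configurations."""
    if n_subjects < 1:
        raise InvalidInputError("n_subjects must be >= 1")
    configs = []
    streams = np.random.SeedSequence(entropy=seed).spawn(n_subjects)
    for s, stream in enumerate(streams):
        jitter_stream, signal_stream = stream.spawn(2)
        rng = np.random.default_rng(jitter_stream)
        comps = []
        for comp in template.compartments:
            dx, dy = rng.normal(0.0, jitter.center_sd, size=2)
            gain = comp.gain * float(np.exp(rng.normal(0.0, jitter.gain_sd)))
            comps.append(
                replace(comp, center=(comp.center[0] + dx, comp.center[1] + dy), gain=gain)
            )
        ens = template.enslaving.values.copy()
        noise = rng.normal(0.0, jitter.enslaving_sd, size=ens.shape)
        jittered = np.clip(ens + noise, 0.0, None)
        jittered[ens == 1.0] = 1.0  # structural ones are not jittered
        configs.append(
            replace(
                template,
                compartments=tuple(comps),
                enslaving=EnslavingMatrix(values=jittered),
                seed=int(np.random.default_rng(signal_stream).integers(2**31 - 1)),
            )
        )
    return configs


def generate_cohort(
    template: SimulationConfig,
    n_subjects: int,
    seed: int,
    jitter: CohortJitter = CohortJitter(),
    conditions: list[Condition] | None = None,
) -> Iterator[tuple[int, Condition, EmgRecording, dict]]:
    """Lazily simulate a cohort over the full condition design.

    Yields ``(subject_index, condition, recording, ground_truth)`` one
    recording at a time (a full cohort does not fit comfortably in
    memory).  Deterministic for a given ``(template, n_subjects, seed)``.
    """
    conds = conditions if conditions is not None else all_conditions()
    for s, cfg in enumerate(subject_configs(template, n_subjects, seed, jitter)):
        for cond in conds:
            recording, truth = simulate_recording(cfg, cond)
            recording.meta["subject"] = s
            truth["subject"] = s
            yield s, cond, recording, truth
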