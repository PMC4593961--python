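"""Plain-text file formats for recordings, maps, grids and tables.

Recordings are stored as a tab-separated numeric matrix (one column per
channel, header row naming channels ``R{row}C{col}``) with a YAML
sidecar holding the sampling rate, grid configuration and trial
annotation table (window bounds in samples).  Metadata round-trips
bit-exactly; signal values round-trip within float formatting precision
(17 significant digits, i.e. exactly for float64).

Maps are tab-separated matrices with ``#`` header comments recording
the grid configuration, condition label and normalization state.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .exceptions import InvalidInputError
from .grid import ElectrodeGrid
from .maps import NormalizedMap, RmsMap
from .preprocessing import Condition, EmgRecording, TaskTrial

__all__ = [
    "write_recording",
    "read_recording",
    "write_map",
    "read_map",
    "load_grid",
    "save_grid",
    "config_hash",
]


def _sidecar_path(data_path: Path) -> Path:
    return data_path.with_suffix(data_path.suffix + ".meta.yaml")


def write_recording(recording: EmgRecording, data_path: str | Path, grid: ElectrodeGrid) -> Path:
    """Write signal matrix + metadata sidecar; returns the sidecar path."""
    data_path = Path(data_path)
    if recording.n_channels != grid.n_channels:
        raise InvalidInputError(
            f"recording has {recording.n_channels} channels but grid expects {grid.n_channels}"
        )
    header = "\t".join(grid.channel_names)
    np.savetxt(
        data_path,
        recording.signal.T,
        fmt="%.17g",
        delimiter="\t",
        header=header,
        comments="",
    )
    meta = {
        "fs": float(recording.fs),
        "grid": grid.to_dict(),
        "trials": [
            {
                "condition": t.condition.label,
                "active_window": [int(t.active_window[0]), int(t.active_window[1])],
                "rest_window": [int(t.rest_window[0]), int(t.rest_window[1])],
                "repetition": int(t.repetition),
            }
            for t in recording.trials
        ],
        "meta": _plain(recording.meta),
    }
    sidecar = _sidecar_path(data_path)
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return sidecar


def read_recording(data_path: str | Path) -> tuple[EmgRecording, ElectrodeGrid]:
    """Read a recording written by :func:`write_recording`."""
    data_path = Path(data_path)
    if not data_path.exists():
        raise InvalidInputError(f"recording file not found: {data_path}")
    sidecar = _sidecar_path(data_path)
    if not sidecar.exists():
        raise InvalidInputError(f"missing metadata sidecar: {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    grid = ElectrodeGrid.from_dict(meta["grid"])
    matrix = np.loadtxt(data_path, delimiter="\t", skiprows=1)
    if matrix.ndim == 1:
        matrix = matrix[:, np.newaxis]
    trials = [
        TaskTrial(
            condition=Condition.from_label(t["condition"]),
            active_window=tuple(t["active_window"]),
            rest_window=tuple(t["rest_window"]),
            repetition=t["repetition"],
        )
        for t in meta.get("trials", [])
    ]
    recording = EmgRecording(
        signal=matrix.T, fs=meta["fs"], trials=trials, meta=meta.get("meta", {})
    )
    return recording, grid


def write_map(rms_map: RmsMap | NormalizedMap, path: str | Path) -> Path:
    """Write a grid map as TSV with a commented header."""
    path = Path(path)
    normalized = isinstance(rms_map, NormalizedMap)
    header_lines = [
        f"# grid: {json.dumps(rms_map.grid.to_dict())}",
        f"# condition: {rms_map.condition}",
        f"# normalized: {normalized}",
    ]
    if normalized and rms_map.degenerate:
        header_lines.append("# degenerate: true")
    body = "\n".join(
        "\t".join(f"{v:.17g}" for v in row) for row in np.asarray(rms_map.values)
    )
    path.write_text("\n".join(header_lines) + "\n" + body + "\n")
    return path


def read_map(path: str | Path) -> RmsMap | NormalizedMap:
    """Read a map written by :func:`write_map`."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"map file not found: {path}")
    header: dict[str, str] = {}
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            header[key.strip()] = value.strip()
        elif line.strip():
            try:
                rows.append([float(tok) for tok in line.split("\t")])
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: malformed numeric row") from exc
    if "grid" not in header:
        raise InvalidInputError(f"{path}: missing '# grid:' header")
    grid = ElectrodeGrid.from_dict(json.loads(header["grid"]))
    values = np.asarray(rows, dtype=float)
    condition = header.get("condition", "")
    if header.get("normalized", "False") == "True":
        return NormalizedMap(
            values=values,
            grid=grid,
            condition=condition,
            degenerate=header.get("degenerate", "false") == "true",
        )
    return RmsMap(values=values, grid=grid, condition=condition)


def save_grid(grid: ElectrodeGrid, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(grid.to_dict(), sort_keys=True))
    return path


def load_grid(path: str | Path) -> ElectrodeGrid:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"grid config not found: {path}")
    return ElectrodeGrid.from_dict(yaml.safe_load(path.read_text()))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    blob = json.dumps(_plain(config_dict), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
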