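"""File I/O: delimited sensor recordings, manifests, configs, label maps.

Recordings are whitespace-delimited numeric text, one row per time step:
sensor channels in columns plus one integer label column, with missing
values written as ``NaN`` — the dialect of the common public wearable
datasets. A dataset manifest (YAML) lists the recording files with
their roles (train / validation / test) and the shared column layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .network import ModelSpec
from .preprocessing import SensorRecording, WindowConfig
from .synthetic import SyntheticConfig
from .training import TrainingConfig

__all__ = [
    "ManifestEntry",
    "DatasetManifest",
    "read_recording",
    "write_recording",
    "build_label_map",
    "save_label_map",
    "load_label_map",
    "load_manifest",
    "read_manifest_recordings",
    "save_manifest",
    "load_run_config",
    "save_run_config",
]


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    role: str  # train | validation | test

    def __post_init__(self) -> None:
        if self.role not in ("train", "validation", "test"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class DatasetManifest:
    """Recording files plus the column layout they share."""

    entries: list[ManifestEntry]
    label_column: int = -1
    channel_columns: list[int] | None = None  # None = all but label column
    modality_tags: list[str] | None = None
    channel_names: list[str] | None = None
    sample_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        roles = {e.role for e in self.entries}
        if "train" not in roles or "test" not in roles:
            raise ValueError("manifest needs at least one train and one test file")

    def files(self, role: str) -> list[str]:
        return [e.path for e in self.entries if e.role == role]


def write_recording(recording: SensorRecording, path) -> None:
    """Write channels + label column as whitespace-delimited text.

    Floats use 17 significant digits so a write-read round trip is
    value-identical; missing values appear as ``nan``.
    """
    data = np.column_stack(
        [recording.samples, recording.labels.astype(np.float64)]
    )
    fmt = ["%.17g"] * recording.n_channels + ["%d"]
    np.savetxt(path, data, fmt=fmt)


def read_recording(
    path,
    label_column: int = -1,
    channel_columns: list[int] | None = None,
    label_map: dict[int, int] | None = None,
    sample_rate_hz: float = 30.0,
    modality_tags: list[str] | None = None,
    channel_names: list[str] | None = None,
) -> tuple[SensorRecording, dict[int, int]]:
    """Read a delimited recording; map raw labels to contiguous ids.

    ``channel_columns`` selects and orders the sensor columns (default:
    every column except the label column). Raw label values are mapped
    to contiguous 0-based class ids: pass the persisted ``label_map``
    from training, or leave it ``None`` to build one from this file
    (sorted raw values; a raw 0 always maps to class 0). Returns the
    recording and the map used. NaN tokens survive as missing values
    for the preprocessing stage.
    """
    try:
        data = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    n_cols = data.shape[1]
    label_idx = label_column % n_cols
    if channel_columns is None:
        channel_columns = [c for c in range(n_cols) if c != label_idx]
    if any(not 0 <= c < n_cols for c in channel_columns):
        raise ValueError(
            f"channel columns {channel_columns} out of range for "
            f"{n_cols}-column file {path}"
        )
    raw_labels = data[:, label_idx]
    if np.isnan(raw_labels).any():
        raise ValueError(f"label column of {path} contains NaN")
    raw_labels = raw_labels.astype(np.int64)
    if label_map is None:
        label_map = build_label_map(raw_labels)
    try:
        labels = np.array([label_map[v] for v in raw_labels.tolist()])
    except KeyError as exc:
        raise ValueError(
            f"label {exc.args[0]} in {path} is not in the persisted "
            "label map; was the model trained on a different class set?"
        ) from exc
    recording = SensorRecording(
        samples=data[:, channel_columns],
        labels=labels,
        sample_rate_hz=sample_rate_hz,
        channel_names=channel_names,
        modality_tags=modality_tags,
    )
    return recording, label_map


def build_label_map(raw_labels) -> dict[int, int]:
    """Sorted raw label values -> contiguous 0-based class ids."""
    values = sorted(set(int(v) for v in np.asarray(raw_labels).ravel()))
    return {v: i for i, v in enumerate(values)}


def save_label_map(label_map: dict[int, int], path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in label_map.items()}, fh, indent=0)


def load_label_map(path) -> dict[int, int]:
    with open(path) as fh:
        return {int(k): int(v) for k, v in json.load(fh).items()}


# ---------------------------------------------------------------------------
# manifest and run configuration
# ---------------------------------------------------------------------------

def save_manifest(manifest: DatasetManifest, path) -> None:
    doc = {
        "sample_rate_hz": manifest.sample_rate_hz,
        "label_column": manifest.label_column,
        "channel_columns": manifest.channel_columns,
        "modality_tags": manifest.modality_tags,
        "channel_names": manifest.channel_names,
        "recordings": [
            {"path": e.path, "role": e.role} for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_manifest(path) -> DatasetManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    known = {
        "sample_rate_hz", "label_column", "channel_columns",
        "modality_tags", "channel_names", "recordings",
    }
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown manifest keys: {sorted(unknown)}")
    base = Path(path).parent
    entries = [
        ManifestEntry(path=str(base / r["path"]), role=r["role"])
        for r in doc["recordings"]
    ]
    return DatasetManifest(
        entries=entries,
        label_column=doc.get("label_column", -1),
        channel_columns=doc.get("channel_columns"),
        modality_tags=doc.get("modality_tags"),
        channel_names=doc.get("channel_names"),
        sample_rate_hz=doc.get("sample_rate_hz", 30.0),
    )


def read_manifest_recordings(
    manifest: DatasetManifest,
    role: str,
    label_map: dict[int, int] | None = None,
) -> tuple[list[SensorRecording], dict[int, int]]:
    """Read all recordings of one role, sharing a single label map.

    When no map is given it is built from the union of raw labels of
    the requested files (use role="train" first and persist the result).
    """
    paths = manifest.files(role)
    if not paths:
        raise ValueError(f"manifest lists no {role!r} recordings")
    if label_map is None:
        raw = []
        for p in paths:
            data = np.loadtxt(p, dtype=np.float64, ndmin=2)
            raw.append(data[:, manifest.label_column % data.shape[1]])
        label_map = build_label_map(np.concatenate(raw))
    recordings = []
    for p in paths:
        rec, _ = read_recording(
            p,
            label_column=manifest.label_column,
            channel_columns=manifest.channel_columns,
            label_map=label_map,
            sample_rate_hz=manifest.sample_rate_hz,
            modality_tags=manifest.modality_tags,
            channel_names=manifest.channel_names,
        )
        recordings.append(rec)
    return recordings, label_map


# ---------------------------------------------------------------------------
# run configuration: one YAML with a section per config dataclass
# ---------------------------------------------------------------------------

_SECTIONS = {
    "model": ModelSpec,
    "training": TrainingConfig,
    "window": WindowConfig,
    "synthetic": SyntheticConfig,
}


def _coerce(cls, values: dict):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(values) - fields
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    # YAML lists -> tuples for the frozen configs that expect them
    coerced = {
        k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
        if isinstance(v, list)
        else v
        for k, v in values.items()
    }
    return cls(**coerced)


def load_run_config(path) -> dict:
    """Parse a run-config YAML into config objects, one per section.

    Recognised sections: ``model`` (ModelSpec), ``training``
    (TrainingConfig), ``window`` (WindowConfig), ``synthetic``
    (SyntheticConfig). Unknown sections or keys raise before any
    compute starts. Missing sections fall back to defaults lazily
    (absent from the returned dict).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {
        name: _coerce(cls, doc[name] or {})
        for name, cls in _SECTIONS.items()
        if name in doc
    }


def save_run_config(configs: dict, path) -> None:
    """Write the fully resolved configuration of a run."""
    doc = {}
    for name, obj in configs.items():
        row = {}
        for f in obj.__dataclass_fields__:
            v = getattr(obj, f)
            if isinstance(v, tuple):
                v = [list(x) if isinstance(x, tuple) else x for x in v]
            row[f] = v
        doc[name] = row
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
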