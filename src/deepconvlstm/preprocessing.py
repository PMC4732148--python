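"""Preprocessing of raw multichannel sensor recordings.

Turns a continuous, possibly gappy, labelled sensor stream into
model-ready fixed-length windows: linear interpolation of missing
samples, per-channel min-max normalisation to [0, 1], and sliding-window
segmentation with last-sample labelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SensorRecording",
    "WindowConfig",
    "WindowBatch",
    "interpolate_missing",
    "normalize_channels",
    "sliding_windows",
    "drop_null_windows",
]


@dataclass
class SensorRecording:
    """A D-channel time series with a per-sample integer label.

    Parameters
    ----------
    samples
        Array of shape ``(N, D)``: one row per time step, one column per
        sensor channel. May contain NaN for missing values before
        preprocessing.
    labels
        Integer class id per time step, shape ``(N,)``. Class 0 is the
        Null class (no activity of interest) by convention.
    sample_rate_hz
        Nominal sampling rate; 30 Hz for typical body-worn inertial
        sensors.
    channel_names
        Optional list of D channel names.
    modality_tags
        Optional per-channel modality tag ("acc", "gyro", "mag", ...),
        used for sensor-fusion channel selection.
    """

    samples: np.ndarray
    labels: np.ndarray
    sample_rate_hz: float = 30.0
    channel_names: list[str] | None = None
    modality_tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (N, D) array")
        n, d = self.samples.shape
        if d < 1:
            raise ValueError("recording needs at least one channel")
        if self.labels.shape != (n,):
            raise ValueError(
                f"labels length {self.labels.shape} does not match N={n}"
            )
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.channel_names is not None and len(self.channel_names) != d:
            raise ValueError("channel_names length must equal D")
        if self.modality_tags is not None and len(self.modality_tags) != d:
            raise ValueError("modality_tags length must equal D")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window segmentation parameters.

    ``window_len_samples`` is the sequence length S1 fed to the network;
    ``step_samples`` the hop between consecutive window starts. Each
    window is labelled with the ground-truth class of its final sample
    (``label_policy`` is fixed to "last-sample").
    """

    window_len_samples: int = 24
    step_samples: int = 12
    label_policy: str = "last-sample"

    def __post_init__(self) -> None:
        if self.label_policy != "last-sample":
            raise ValueError("only the last-sample label policy is supported")
        if not 1 <= self.step_samples <= self.window_len_samples:
            raise ValueError("require 1 <= step_samples <= window_len_samples")


@dataclass
class WindowBatch:
    """A stack of segmented windows.

    ``sequences`` has shape ``(M, D, S1)`` (window, channel, time);
    ``labels`` holds one integer class per window (the label of the
    window's last sample); ``starts`` records each window's start index
    in the source recording.
    """

    sequences: np.ndarray
    labels: np.ndarray
    starts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.sequences.ndim != 3:
            raise ValueError("sequences must have shape (M, D, S1)")
        m = self.sequences.shape[0]
        if self.labels.shape != (m,):
            raise ValueError("labels length must equal number of windows")
        if self.starts is None:
            self.starts = np.full(m, -1, dtype=np.int64)
        else:
            self.starts = np.asarray(self.starts, dtype=np.int64)

    def __len__(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_channels(self) -> int:
        return self.sequences.shape[1]

    @property
    def window_len(self) -> int:
        return self.sequences.shape[2]


def interpolate_missing(recording: SensorRecording) -> SensorRecording:
    """Fill missing values (NaN) by per-channel linear interpolation.

    Interior gaps are interpolated linearly between the nearest observed
    neighbours in time; leading and trailing gaps are filled with the
    nearest observed value. Observed samples pass through unchanged.

    Raises
    ------
    ValueError
        If a channel contains no observed value at all.
    """
    x = recording.samples
    if not np.isnan(x).any():
        return recording
    out = x.copy()
    t = np.arange(x.shape[0], dtype=np.float64)
    for d in range(x.shape[1]):
        col = x[:, d]
        obs = ~np.isnan(col)
        if not obs.any():
            name = (
                recording.channel_names[d]
                if recording.channel_names
                else str(d)
            )
            raise ValueError(
                f"channel {name!r} has no observed values; cannot interpolate"
            )
        if obs.all():
            continue
        # np.interp clamps to the boundary values, which implements
        # nearest-value extension at the edges.
        out[:, d] = np.interp(t, t[obs], col[obs])
    return replace(recording, samples=out)


def normalize_channels(
    recording: SensorRecording,
    bounds: np.ndarray | None = None,
) -> tuple[SensorRecording, np.ndarray]:
    """Map every channel affinely onto [0, 1].

    Parameters
    ----------
    recording
        Recording with no missing values (run :func:`interpolate_missing`
        first).
    bounds
        Optional ``(D, 2)`` array of per-channel ``(min, max)`` to apply
        — pass the bounds returned from the training data when
        normalising validation or test data, so the mapping is learned
        once and no information leaks from the evaluation split. When
        omitted, bounds are computed from the data itself.

    Returns
    -------
    (normalised recording, bounds used) — feed the returned bounds back
    in for any further split of the same dataset. Values outside the
    provided bounds are clipped to [0, 1]. A constant channel
    (max == min) maps to all zeros with a logged warning.
    """
    x = recording.samples
    if np.isnan(x).any():
        raise ValueError("recording contains missing values; interpolate first")
    if bounds is None:
        bounds = np.stack([x.min(axis=0), x.max(axis=0)], axis=1)
    else:
        bounds = np.asarray(bounds, dtype=np.float64)
        if bounds.shape != (x.shape[1], 2):
            raise ValueError("bounds must have shape (D, 2)")
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        which = np.flatnonzero(degenerate)
        msg = f"constant channel(s) {which.tolist()} mapped to zeros"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    safe_span = np.where(degenerate, 1.0, span)
    out = (x - lo) / safe_span
    out[:, degenerate] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    return replace(recording, samples=out), bounds


def sliding_windows(
    recording: SensorRecording, cfg: WindowConfig
) -> WindowBatch:
    """Segment a recording into fixed-length windows.

    Windows start at 0, step, 2*step, ... while fully inside the
    recording, giving ``floor((N - S1) / step) + 1`` windows. Window m is
    labelled with the recording label at its final sample
    (``start_m + S1 - 1``): the class active when the window closes.
    """
    n = recording.n_samples
    s1, step = cfg.window_len_samples, cfg.step_samples
    if n < s1:
        raise ValueError(
            f"recording shorter than window: N={n} < S1={s1}"
        )
    starts = np.arange(0, n - s1 + 1, step, dtype=np.int64)
    # (M, D, S1): gather then move the channel axis ahead of time.
    idx = starts[:, None] + np.arange(s1)[None, :]
    sequences = recording.samples[idx].transpose(0, 2, 1)
    labels = recording.labels[starts + s1 - 1]
    return WindowBatch(sequences=sequences, labels=labels, starts=starts)


def drop_null_windows(batch: WindowBatch, shift_labels: bool = True) -> WindowBatch:
    """Remove windows labelled Null (class 0).

    With ``shift_labels`` the remaining labels are decremented by one so
    they form a contiguous 0-based class set — the label space of a
    model trained on the activity classes only.
    """
    keep = batch.labels != 0
    labels = batch.labels[keep]
    if shift_labels:
        labels = labels - 1
    return WindowBatch(
        sequences=batch.sequences[keep],
        labels=labels,
        starts=batch.starts[keep],
    )
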