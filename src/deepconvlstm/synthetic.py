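"""Synthetic multichannel sensor streams for activity recognition.

Generates labelled recordings with the statistical structure of
naturalistic wearable-sensor datasets: sporadic gesture motifs embedded
in a dominant Null background (~75 % of samples), three modality groups
(accelerometer-, gyroscope- and magnetometer-like channels) with a
descending signal-to-noise ladder, and optional gesture-class pairs
whose motifs are exact time reversals of each other — so that temporal
order is the only cue separating them.

Everything is deterministic given the config seed, which makes the
generator usable as a test fixture for the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import SensorRecording

__all__ = [
    "SyntheticConfig",
    "make_templates",
    "generate_recording",
    "modality_subset",
    "mirrored_pair_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic sensor-stream generator.

    Parameters
    ----------
    channels_per_modality
        Ordered (tag, count) pairs; channels are laid out group by
        group. Defaults to 5 accelerometer-, 5 gyroscope- and 5
        magnetometer-like channels.
    n_classes
        Number of classes including Null (class 0); classes 1..nc-1 are
        gestures.
    gestures_per_class
        Gesture instances inserted per gesture class.
    template_len_range
        Inclusive range of per-class motif lengths in samples; motifs
        are longer than the default analysis window, as real gestures
        usually are.
    null_fraction
        Target share of Null samples in the stream (0.75 matches the
        imbalance of naturalistic gesture datasets).
    noise_sd / template_amp
        Per-modality noise standard deviation and motif amplitude. The
        defaults form an informativeness ladder: accelerometer channels
        are cleanest, magnetometer channels weakest and noisiest.
    mirrored_pairs
        Class-id pairs (a, b) whose motifs satisfy
        ``template_b(t) = template_a(L-1-t)`` exactly.
    amp_jitter, time_warp
        Per-instance uniform amplitude jitter and duration warp
        (+-20 % by default).
    drift_amplitude
        Amplitude of the slow per-channel baseline drift in the Null
        background.
    min_gap_samples
        Minimum Null gap before, between and after gestures (at least
        one analysis window, so last-sample labelling is unambiguous at
        boundaries).
    missing_rate
        Approximate fraction of samples replaced by NaN runs, to
        exercise interpolation; 0 disables.
    max_template_correlation
        Cap on the pairwise correlation between motifs of non-mirrored
        classes; offending motifs are redrawn.
    """

    channels_per_modality: tuple = (("acc", 5), ("gyro", 5), ("mag", 5))
    n_classes: int = 5
    gestures_per_class: int = 40
    template_len_range: tuple = (32, 56)
    null_fraction: float = 0.75
    noise_sd: tuple = (("acc", 0.05), ("gyro", 0.15), ("mag", 0.30))
    template_amp: tuple = (("acc", 1.0), ("gyro", 0.7), ("mag", 0.4))
    mirrored_pairs: tuple = ()
    amp_jitter: float = 0.2
    time_warp: float = 0.2
    drift_amplitude: float = 0.05
    min_gap_samples: int = 24
    missing_rate: float = 0.0
    max_template_correlation: float = 0.8
    sample_rate_hz: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.null_fraction < 1:
            raise ValueError("null_fraction must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need Null plus at least one gesture class")
        ids = [c for pair in self.mirrored_pairs for c in pair]
        if any(not 1 <= c < self.n_classes for c in ids):
            raise ValueError("mirrored_pairs must name gesture classes")
        if len(set(ids)) != len(ids):
            raise ValueError("a class may appear in one mirrored pair only")

    @property
    def n_channels(self) -> int:
        return sum(n for _, n in self.channels_per_modality)

    @property
    def modality_tags(self) -> list[str]:
        return [
            tag for tag, n in self.channels_per_modality for _ in range(n)
        ]

    @property
    def channel_names(self) -> list[str]:
        return [
            f"{tag}_{i}"
            for tag, n in self.channels_per_modality
            for i in range(n)
        ]

    def _per_channel(self, table: tuple) -> np.ndarray:
        lookup = dict(table)
        return np.array([lookup[t] for t in self.modality_tags])


def mirrored_pair_config(**overrides) -> SyntheticConfig:
    """Config for the temporal-order disambiguation experiment.

    Four gesture classes plus Null, arranged as two mirrored pairs
    (1, 2) and (3, 4): within each pair the motifs are time reversals of
    each other, so per-window value distributions carry no class
    information and only sample order separates the pair.
    """
    defaults = dict(n_classes=5, mirrored_pairs=((1, 2), (3, 4)))
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def _smooth_motif(rng: np.random.Generator, d: int, length: int) -> np.ndarray:
    """Band-limited random motif: summed sinusoids under a Hann envelope.

    Smooth on the scale of a few samples, so short temporal kernels can
    pick up local structure, like real inertial gesture signatures.
    """
    t = np.arange(length) / length
    motif = np.zeros((d, length))
    n_harmonics = 4
    freqs = rng.uniform(0.5, 3.5, size=(d, n_harmonics))
    phases = rng.uniform(0, 2 * np.pi, size=(d, n_harmonics))
    amps = rng.uniform(0.3, 1.0, size=(d, n_harmonics))
    for k in range(n_harmonics):
        motif += amps[:, [k]] * np.sin(
            2 * np.pi * freqs[:, [k]] * t[None, :] + phases[:, [k]]
        )
    envelope = np.hanning(length)[None, :]
    motif *= envelope
    rms = np.sqrt((motif**2).mean(axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return motif / rms


def _template_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two motifs, resampled to a common length."""
    length = max(a.shape[1], b.shape[1])

    def resample(x: np.ndarray) -> np.ndarray:
        src = np.linspace(0, 1, x.shape[1])
        dst = np.linspace(0, 1, length)
        return np.vstack([np.interp(dst, src, row) for row in x])

    fa, fb = resample(a).ravel(), resample(b).ravel()
    fa = fa - fa.mean()
    fb = fb - fb.mean()
    denom = np.linalg.norm(fa) * np.linalg.norm(fb)
    if denom == 0:
        return 0.0
    return float(fa @ fb / denom)


def make_templates(cfg: SyntheticConfig) -> dict[int, np.ndarray]:
    """Per-class motif bank ``{class_id: (D, L_class) array}``.

    Motifs include the per-modality amplitude ladder. Mirrored pairs
    share one motif, the second class being its exact time reversal.
    Non-paired class pairs are redrawn until their pairwise correlation
    falls below ``cfg.max_template_correlation``.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.n_channels
    amp = cfg._per_channel(cfg.template_amp)[:, None]
    lo, hi = cfg.template_len_range
    mirror_of = {b: a for a, b in cfg.mirrored_pairs}

    templates: dict[int, np.ndarray] = {}
    free_classes = [
        c for c in range(1, cfg.n_classes) if c not in mirror_of
    ]
    for c in free_classes:
        length = int(rng.integers(lo, hi + 1))
        templates[c] = _smooth_motif(rng, d, length) * amp

    # redraw until all non-mirrored pairs decorrelate
    for _ in range(100):
        offender = None
        for i, a in enumerate(free_classes):
            for b in free_classes[i + 1 :]:
                corr = abs(_template_correlation(templates[a], templates[b]))
                if corr > cfg.max_template_correlation:
                    offender = b
                    break
            if offender is not None:
                break
        if offender is None:
            break
        length = templates[offender].shape[1]
        templates[offender] = _smooth_motif(rng, d, length) * amp
    else:
        raise RuntimeError(
            "could not decorrelate class templates below the cap"
        )

    for b, a in mirror_of.items():
        templates[b] = templates[a][:, ::-1].copy()
    return dict(sorted(templates.items()))


def _time_warp(template: np.ndarray, new_len: int) -> np.ndarray:
    """Resample a (D, L) motif to a new duration."""
    length = template.shape[1]
    if new_len == length:
        return template.copy()
    src = np.linspace(0.0, 1.0, length)
    dst = np.linspace(0.0, 1.0, new_len)
    return np.vstack([np.interp(dst, src, row) for row in template])


def generate_recording(
    cfg: SyntheticConfig, seed: int | None = None
) -> SensorRecording:
    """One labelled synthetic recording.

    A Null background (per-modality Gaussian noise plus slow sinusoidal
    drift) carries ``gestures_per_class`` instances of every gesture
    class at non-overlapping positions, each amplitude-jittered and
    time-warped. Per-sample labels mark the gesture spans, 0 elsewhere.
    The stream length is chosen so the realised Null fraction matches
    ``cfg.null_fraction`` up to rounding. Deterministic per seed
    (``cfg.seed`` unless overridden).
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    # The motif bank depends on cfg.seed only, so recordings generated
    # with different override seeds (train/validation/test splits) share
    # one set of class motifs and differ only in placement and noise.
    templates = make_templates(cfg)
    d = cfg.n_channels

    # draw all instances (class, warped length, amplitude)
    instances = []
    for c in range(1, cfg.n_classes):
        base = templates[c]
        for _ in range(cfg.gestures_per_class):
            warp = rng.uniform(1 - cfg.time_warp, 1 + cfg.time_warp)
            new_len = max(2, int(round(base.shape[1] * warp)))
            amp = rng.uniform(1 - cfg.amp_jitter, 1 + cfg.amp_jitter)
            instances.append((c, new_len, amp))
    rng.shuffle(instances)

    gesture_mass = sum(length for _, length, _ in instances)
    n_total = int(np.ceil(gesture_mass / (1.0 - cfg.null_fraction)))
    null_total = n_total - gesture_mass
    n_gaps = len(instances) + 1
    min_gap = cfg.min_gap_samples
    spare = null_total - n_gaps * min_gap
    if spare < 0:
        raise ValueError(
            "requested gesture mass exceeds stream capacity: "
            f"{null_total} Null samples cannot hold {n_gaps} gaps of "
            f">= {min_gap} samples; lower gestures_per_class or "
            "min_gap_samples, or raise null_fraction"
        )
    shares = rng.random(n_gaps)
    gaps = min_gap + np.floor(shares / shares.sum() * spare).astype(int)
    gaps[-1] += null_total - gaps.sum()  # absorb rounding in the tail gap

    # Null background: slow drift + modality-dependent noise
    noise_sd = cfg._per_channel(cfg.noise_sd)
    t = np.arange(n_total)[:, None] / n_total
    drift_freq = rng.uniform(1.0, 4.0, size=d)
    drift_phase = rng.uniform(0, 2 * np.pi, size=d)
    samples = cfg.drift_amplitude * np.sin(
        2 * np.pi * drift_freq[None, :] * t + drift_phase[None, :]
    )
    samples += rng.standard_normal((n_total, d)) * noise_sd[None, :]
    labels = np.zeros(n_total, dtype=np.int64)

    pos = 0
    for gap, (c, length, amp) in zip(gaps, instances):
        pos += int(gap)
        warped = _time_warp(templates[c], length)
        samples[pos : pos + length, :] += amp * warped.T
        labels[pos : pos + length] = c
        pos += length

    if cfg.missing_rate > 0:
        mean_run = 5
        n_runs = int(round(cfg.missing_rate * n_total * d / mean_run))
        for _ in range(n_runs):
            ch = int(rng.integers(d))
            run = int(rng.integers(1, 2 * mean_run))
            start = int(rng.integers(max(1, n_total - run)))
            samples[start : start + run, ch] = np.nan

    return SensorRecording(
        samples=samples,
        labels=labels,
        sample_rate_hz=cfg.sample_rate_hz,
        channel_names=cfg.channel_names,
        modality_tags=cfg.modality_tags,
    )


def modality_subset(
    recording: SensorRecording, tags: list[str] | tuple
) -> SensorRecording:
    """Channel subset of one or more modality groups, labels preserved.

    Channel order relative to the source recording is kept; used for
    sensor-fusion ablations (accelerometers alone, then + gyroscopes,
    then + magnetometers, ...).
    """
    if recording.modality_tags is None:
        raise ValueError("recording has no modality tags")
    tags = list(tags)
    if not tags:
        raise ValueError("empty modality selection")
    unknown = set(tags) - set(recording.modality_tags)
    if unknown:
        raise ValueError(f"unknown modality tags: {sorted(unknown)}")
    keep = [i for i, t in enumerate(recording.modality_tags) if t in tags]
    return SensorRecording(
        samples=recording.samples[:, keep],
        labels=recording.labels.copy(),
        sample_rate_hz=recording.sample_rate_hz,
        channel_names=(
            [recording.channel_names[i] for i in keep]
            if recording.channel_names
            else None
        ),
        modality_tags=[recording.modality_tags[i] for i in keep],
    )
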