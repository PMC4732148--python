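"""End-to-end study protocols on synthetic sensor streams.

Each protocol generates independent train/validation/test recordings
from one motif bank, runs the full preprocessing pipeline, trains a
model and scores it on the held-out split:

* :func:`learnability_run` — can a scaled-down DeepConvLSTM solve the
  default 5-class, 75 %-Null, three-modality task?
* :func:`order_disambiguation_run` — when the only cue separating two
  class pairs is time reversal of their motifs, does the recurrent
  readout beat an equally sized flattened-CNN baseline?
* :func:`fusion_ladder_run` — does performance grow as modality groups
  are added (accelerometers, + gyroscopes, + magnetometers)?

Problem sizes are deliberately modest (a few thousand windows, 8–16
feature maps, 16–32 cells) so a protocol finishes in minutes on one CPU
core while keeping the structure of the full-scale task.
"""

from __future__ import annotations

import numpy as np

from .evaluation import EvaluationReport, evaluate
from .network import BASELINE, RECURRENT, ModelSpec, build_model
from .preprocessing import (
    SensorRecording,
    WindowBatch,
    WindowConfig,
    interpolate_missing,
    normalize_channels,
    sliding_windows,
)
from .synthetic import (
    SyntheticConfig,
    generate_recording,
    mirrored_pair_config,
    modality_subset,
)
from .training import TrainingConfig, TrainingHistory, train

__all__ = [
    "prepare_batch",
    "synthetic_splits",
    "train_and_score",
    "learnability_run",
    "order_disambiguation_run",
    "fusion_ladder_run",
]


def prepare_batch(
    recording: SensorRecording,
    window_cfg: WindowConfig,
    bounds: np.ndarray | None = None,
) -> tuple[WindowBatch, np.ndarray]:
    """Interpolate, normalise and window one recording.

    Pass ``bounds=None`` for training data; reuse the returned bounds
    for validation and test recordings so the [0, 1] mapping is fit on
    training data only.
    """
    rec = interpolate_missing(recording)
    rec, bounds = normalize_channels(rec, bounds)
    return sliding_windows(rec, window_cfg), bounds


def synthetic_splits(
    cfg: SyntheticConfig,
    window_cfg: WindowConfig,
    seed: int,
) -> tuple[WindowBatch, WindowBatch, WindowBatch]:
    """Generate and preprocess train/validation/test window batches.

    The three recordings share the motif bank fixed by ``cfg.seed`` but
    use independent placement-and-noise seeds derived from ``seed``.
    """
    sub = np.random.default_rng(seed).integers(2**31 - 4, size=3)
    train_rec = generate_recording(cfg, seed=int(sub[0]) + 1)
    val_rec = generate_recording(cfg, seed=int(sub[1]) + 2)
    test_rec = generate_recording(cfg, seed=int(sub[2]) + 3)
    train_batch, bounds = prepare_batch(train_rec, window_cfg)
    val_batch, _ = prepare_batch(val_rec, window_cfg, bounds)
    test_batch, _ = prepare_batch(test_rec, window_cfg, bounds)
    return train_batch, val_batch, test_batch


def train_and_score(
    spec: ModelSpec,
    batches: tuple[WindowBatch, WindowBatch, WindowBatch],
    training_cfg: TrainingConfig,
) -> tuple[EvaluationReport, TrainingHistory]:
    """Build, train and score a model on prepared splits."""
    train_batch, val_batch, test_batch = batches
    model = build_model(spec, seed=training_cfg.seed)
    history = train(model, train_batch, val_batch, training_cfg)
    return evaluate(model, test_batch), history


def learnability_run(
    seed: int = 0,
    cfg: SyntheticConfig | None = None,
    max_epochs: int = 50,
) -> tuple[EvaluationReport, TrainingHistory]:
    """Scaled DeepConvLSTM on the default synthetic task.

    Default conditions: 5 classes including Null, three modality groups
    of five channels, 75 % Null share; model scaled to 16 feature maps
    and 32 cells.
    """
    if cfg is None:
        cfg = SyntheticConfig(seed=seed)
    window_cfg = WindowConfig()
    batches = synthetic_splits(cfg, window_cfg, seed)
    spec = ModelSpec(
        variant=RECURRENT,
        n_channels=cfg.n_channels,
        n_classes=cfg.n_classes,
        window_len=window_cfg.window_len_samples,
        n_maps=16,
        n_hidden=32,
    )
    tcfg = TrainingConfig(seed=seed, max_epochs=max_epochs, patience=12)
    return train_and_score(spec, batches, tcfg)


def _mean_f1_over(report: EvaluationReport, classes) -> float:
    return float(np.mean([report.f1[c] for c in classes]))


def order_disambiguation_run(
    seed: int = 0,
    max_epochs: int = 100,
) -> dict[str, float]:
    """Recurrent vs flattened readout on time-mirrored gesture pairs.

    Both models share the convolutional stack size (8 maps) and readout
    width (16 cells / units) and see identical data: a single
    accelerometer-like group carrying two mirrored class pairs. Returns
    the mean per-class F1 over the four mirrored classes for each
    architecture.
    """
    cfg = mirrored_pair_config(
        channels_per_modality=(("acc", 6),),
        noise_sd=(("acc", 0.05),),
        template_amp=(("acc", 1.0),),
        gestures_per_class=25,
        seed=seed,
    )
    window_cfg = WindowConfig()
    batches = synthetic_splits(cfg, window_cfg, seed)
    mirrored_classes = [c for pair in cfg.mirrored_pairs for c in pair]
    out = {}
    for variant in (RECURRENT, BASELINE):
        spec = ModelSpec(
            variant=variant,
            n_channels=cfg.n_channels,
            n_classes=cfg.n_classes,
            window_len=window_cfg.window_len_samples,
            n_maps=8,
            n_hidden=16,
        )
        tcfg = TrainingConfig(seed=seed, max_epochs=max_epochs, patience=max_epochs)
        report, _ = train_and_score(spec, batches, tcfg)
        out[variant] = _mean_f1_over(report, mirrored_classes)
    return out


def fusion_ladder_run(
    seed: int = 0,
    max_epochs: int = 110,
    patience: int = 25,
) -> list[float]:
    """Weighted F1 as modality groups are added: acc, +gyro, +mag.

    All three models are trained and scored on channel subsets of the
    same recordings, so the only difference along the ladder is the
    sensor set. Each rung trains to convergence under early stopping:
    models with more channels have more parameters and need more
    epochs, so a fixed small epoch budget would confound the sensor
    set with optimisation progress.
    """
    cfg = SyntheticConfig(gestures_per_class=20, seed=seed)
    window_cfg = WindowConfig()
    sub = np.random.default_rng(seed).integers(2**31 - 4, size=3)
    recs = [
        generate_recording(cfg, seed=int(s) + k + 1)
        for k, s in enumerate(sub)
    ]
    ladder = [("acc",), ("acc", "gyro"), ("acc", "gyro", "mag")]
    scores = []
    for tags in ladder:
        subset = [modality_subset(r, list(tags)) for r in recs]
        train_batch, bounds = prepare_batch(subset[0], window_cfg)
        val_batch, _ = prepare_batch(subset[1], window_cfg, bounds)
        test_batch, _ = prepare_batch(subset[2], window_cfg, bounds)
        spec = ModelSpec(
            variant=RECURRENT,
            n_channels=subset[0].n_channels,
            n_classes=cfg.n_classes,
            window_len=window_cfg.window_len_samples,
            n_maps=8,
            n_hidden=16,
        )
        tcfg = TrainingConfig(
            seed=seed, max_epochs=max_epochs, patience=patience
        )
        report, _ = train_and_score(
            spec, (train_batch, val_batch, test_batch), tcfg
        )
        scores.append(report.weighted_f1)
    return scores
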