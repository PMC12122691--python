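"""Seeded optimization of the paired model under the combined objective.

Training follows a sliding-window + random-clipping scheme: each epoch
visits every training excerpt's stride grid once, with a fresh random
clip offset per grid point, so over many epochs every part of the signal
is seen.  The EEG side of each pair is delayed relative to the stimulus
by the configured stimulus-to-response latency.  Validation accuracy is
window-level EEG classification accuracy at the (finer) evaluation
stride; the best-validation parameters are kept.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from autograd import grad, value_and_grad

from . import nn
from .losses import LossConfig, classification_loss, predann_loss, total_loss
from .models import PairedModel, EncoderSpec, ProjectionHeads, forward_pair
from .nn import Adam, tree_copy


@dataclass
class TrainConfig:
    """Optimization settings.

    ``epochs`` defaults to the convergence-scale setting of the full
    study; desk-scale experiments pass far smaller values.  Strides are
    in samples at the EEG rate; ``delay_ms`` is the assumed
    stimulus-to-response latency applied when pairing windows.
    """

    epochs: int = 6000
    batch_size: int = 64
    train_stride_samples: int = 200
    eval_stride_samples: int = 1
    window_seconds: float = 3.0
    delay_ms: float = 200.0
    seed: int = 0
    learning_rate: float = 1e-3
    eval_every: int = 5

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.train_stride_samples < 1 or self.eval_stride_samples < 1:
            raise ValueError("strides must be >= 1")


@dataclass
class PairedExcerpt:
    """One delay-alignable excerpt pair at a common sampling rate."""

    eeg: np.ndarray       # [channels, samples]
    audio: np.ndarray     # [samples]
    song_id: int
    subject_id: int
    fs: float


@dataclass
class TrainState:
    seed: int
    epochs_completed: int = 0
    loss_trace: list = field(default_factory=list)       # LossBreakdown per epoch
    val_trace: list = field(default_factory=list)        # (epoch, accuracy)
    best_val_accuracy: float = float("nan")
    best_epoch: int = -1
    best_params: dict | None = None
    final_params: dict | None = None
    gradient_audit: dict | None = None


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed every RNG stream used here (legacy numpy state included)."""
    np.random.seed(seed)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))


def _window_geometry(cfg: TrainConfig, fs: float):
    W = int(round(cfg.window_seconds * fs))
    d = int(round(cfg.delay_ms * fs / 1000.0))
    return W, d


def _grid_starts(n_samples: int, W: int, d: int, stride: int):
    max_start = n_samples - W - d
    if max_start < 0:
        return None
    return np.arange(0, max_start + 1, stride), max_start


def sample_training_batch(train_set, cfg: TrainConfig, rng: np.random.Generator):
    """One random paired batch from the stride grid with random clip offsets."""
    if not train_set:
        raise ValueError("empty training set")
    pool = list(_epoch_positions(train_set, cfg, rng))
    idx = rng.choice(len(pool), size=min(cfg.batch_size, len(pool)), replace=False)
    return _gather([pool[i] for i in idx], train_set, cfg)


def _epoch_positions(train_set, cfg: TrainConfig, rng: np.random.Generator):
    """(excerpt index, audio start) pairs covering every excerpt's stride grid."""
    W, d = _window_geometry(cfg, train_set[0].fs)
    for i, exc in enumerate(train_set):
        geom = _grid_starts(exc.audio.size, W, d, cfg.train_stride_samples)
        if geom is None:
            warnings.warn(
                f"excerpt {i} shorter than window+delay; skipped", RuntimeWarning
            )
            continue
        grid, max_start = geom
        offsets = rng.integers(0, cfg.train_stride_samples, size=grid.size)
        for s in np.minimum(grid + offsets, max_start):
            yield (i, int(s))


def _gather(positions, train_set, cfg: TrainConfig):
    W, d = _window_geometry(cfg, train_set[0].fs)
    eeg, audio, labels = [], [], []
    for i, s in positions:
        exc = train_set[i]
        eeg.append(exc.eeg[:, s + d : s + d + W])
        audio.append(exc.audio[s : s + W])
        labels.append(exc.song_id)
    return np.stack(eeg), np.stack(audio), np.asarray(labels)


def evaluate_window_accuracy(
    model: PairedModel, excerpts, cfg: TrainConfig, params: dict | None = None
) -> float:
    """Window-level EEG classification accuracy at the evaluation stride."""
    from .models import encode, project

    W, d = _window_geometry(cfg, excerpts[0].fs)
    p = model.params if params is None else params
    correct = total = 0
    for exc in excerpts:
        geom = _grid_starts(exc.audio.size, W, d, cfg.eval_stride_samples)
        if geom is None:
            continue
        grid, _ = geom
        windows = np.stack([exc.eeg[:, s + d : s + d + W] for s in grid])
        feats = encode(model.spec, p["eeg"], windows, "eeg")
        logits, _ = project(p["eeg"], feats)
        pred = np.argmax(logits, axis=1)
        correct += int(np.sum(pred == exc.song_id))
        total += pred.size
    return correct / total if total else float("nan")


def _loss_parts(model, params, eeg, audio, labels, loss_cfg: LossConfig):
    emb = forward_pair(model, eeg, audio, labels, labels, params=params)
    cls_e = classification_loss(emb.z_E_I, labels)
    cls_m = classification_loss(emb.z_M_I, labels)
    pred = predann_loss(emb.z_M_II, emb.z_E_II, loss_cfg)
    return cls_e, cls_m, pred


def predann_gradient_norms(
    model: PairedModel, eeg, audio, labels, loss_cfg: LossConfig
) -> dict:
    """L2 norms of the contrastive term's gradient on each branch.

    The stop-gradient contract: with it enabled, the music-branch norm is
    exactly zero while the EEG-branch norm is generically nonzero.
    """

    def predann_only(params):
        _, _, pred = _loss_parts(model, params, eeg, audio, labels, loss_cfg)
        return pred

    g = grad(predann_only)(model.params)
    from autograd.misc import flatten

    return {
        "eeg": float(np.linalg.norm(flatten(g["eeg"])[0])),
        "music": float(np.linalg.norm(flatten(g["music"])[0])),
    }


def train(
    model: PairedModel,
    train_set,
    val_set,
    cfg: TrainConfig,
    loss_cfg: LossConfig,
    verbose: bool = False,
) -> TrainState:
    """Optimize the paired model; returns the state with traces and best params.

    On return ``model.params`` holds the best-validation parameters.
    """
    if not train_set:
        raise ValueError("empty training set")
    rng = set_global_seed(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    state = TrainState(seed=cfg.seed)

    from autograd.tracer import getval

    last_parts = [0.0, 0.0, 0.0]

    def objective(params, eeg, audio, labels):
        cls_e, cls_m, pred = _loss_parts(model, params, eeg, audio, labels, loss_cfg)
        last_parts[:] = [float(getval(cls_e)), float(getval(cls_m)), float(getval(pred))]
        return cls_e + cls_m + loss_cfg.lambda_predann * pred

    vag = value_and_grad(objective)
    params = model.params

    # one-time gradient-isolation audit at the initial parameters
    eeg0, audio0, labels0 = sample_training_batch(train_set, cfg, rng)
    state.gradient_audit = predann_gradient_norms(model, eeg0, audio0, labels0, loss_cfg)

    for epoch in range(cfg.epochs):
        positions = list(_epoch_positions(train_set, cfg, rng))
        rng.shuffle(positions)
        sums = np.zeros(3)
        n_batches = 0
        for b0 in range(0, len(positions), cfg.batch_size):
            batch = positions[b0 : b0 + cfg.batch_size]
            if len(batch) < 2:
                continue
            eeg, audio, labels = _gather(batch, train_set, cfg)
            value, grads = vag(params, eeg, audio, labels)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; "
                    f"trace so far: {[lb.total for lb in state.loss_trace]}"
                )
            params = opt.step(params, grads)
            model.params = params
            sums += last_parts
            n_batches += 1
        mean = sums / max(n_batches, 1)
        state.loss_trace.append(
            total_loss(mean[0], mean[1], mean[2], loss_cfg)
        )
        state.epochs_completed = epoch + 1
        if (epoch + 1) % cfg.eval_every == 0 or epoch == cfg.epochs - 1:
            acc = evaluate_window_accuracy(model, val_set, cfg, params=params)
            state.val_trace.append((epoch + 1, acc))
            if not (acc <= state.best_val_accuracy):  # NaN-safe strict improvement
                state.best_val_accuracy = acc
                state.best_epoch = epoch + 1
                state.best_params = tree_copy(params)
            if verbose:
                print(f"epoch {epoch + 1}: loss {mean.sum():.4f} val_acc {acc:.3f}")

    state.final_params = tree_copy(params)
    if state.best_params is not None:
        model.params = state.best_params
    return state


def config_hash(*cfgs) -> str:
    blob = json.dumps([asdict(c) for c in cfgs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_checkpoint(model: PairedModel, path, cfg: TrainConfig | None = None,
                    loss_cfg: LossConfig | None = None, extra: dict | None = None):
    """Single-file checkpoint: weights plus an embedded manifest."""
    arrays = {}
    for branch, p in model.params.items():
        for k, v in p.items():
            arrays[f"{branch}/{k}"] = v
    manifest = {
        "spec": asdict(model.spec),
        "heads": asdict(model.heads),
        "eeg_channels": model.eeg_channels,
        "extra": extra or {},
    }
    cfgs = [c for c in (cfg, loss_cfg) if c is not None]
    if cfgs:
        manifest["config"] = [asdict(c) for c in cfgs]
        manifest["config_hash"] = config_hash(*cfgs)
    arrays["__manifest__"] = np.frombuffer(
        json.dumps(manifest, default=str).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> PairedModel:
    with np.load(path) as z:
        manifest = json.loads(bytes(z["__manifest__"].tobytes()).decode())
        spec = EncoderSpec(**{**manifest["spec"],
                              "channels_per_block": tuple(manifest["spec"]["channels_per_block"])})
        heads = ProjectionHeads(**manifest["heads"])
        params: dict = {"eeg": {}, "music": {}}
        for key in z.files:
            if key == "__manifest__":
                continue
            branch, name = key.split("/", 1)
            params[branch][name] = z[key]
    return PairedModel(spec=spec, heads=heads,
                       eeg_channels=manifest["eeg_channels"], params=params)
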