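"""Paired encoder + dual-projector model for EEG and stimulus branches.

Two structurally identical convolutional encoders — one per modality,
sharing no parameters — feed two projection heads each: Projector I maps
the encoder feature to class logits (song identification) and Projector
II to a contrastive embedding.  Two encoder families are provided:

* ``cnn1d`` — temporal convolutions over a [channels, time] signal;
* ``cnn2d`` — 2-D convolutions over the signal laid out as a single-plane
  [height, width] grid (EEG: electrodes x time; audio: a height-1 grid,
  so 2-D kernels act temporally).

All convolutions use kernel 3, stride 1, padding 1, which preserves the
temporal (and spatial) extent; downsampling happens only in the pooling
steps.  The model is functional: parameters live in a nested dict so the
whole forward pass can be differentiated with autograd, and gradient
isolation between branches can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import autograd.numpy as anp

from . import nn


@dataclass
class EncoderSpec:
    """Architecture of one encoder branch.

    channels_per_block: feature maps per conv block; its length is the
        number of blocks.  pool: downsampling factor after each block.
    With kernel 3, stride 1, padding 1 every convolution preserves extent.
    """

    family: str = "cnn1d"
    channels_per_block: tuple = (16, 32)
    kernel_size: int = 3
    padding: int = 1
    pool: int = 4
    embedding_dim: int = 64

    def __post_init__(self):
        if self.family not in ("cnn1d", "cnn2d"):
            raise ValueError(f"unknown encoder family: {self.family!r}")
        if self.kernel_size != 2 * self.padding + 1:
            raise ValueError(
                "kernel/padding must satisfy K = 2p + 1 to preserve extent"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.channels_per_block)


@dataclass
class ProjectionHeads:
    """Projector I (class logits) and Projector II (contrastive embedding)."""

    n_classes: int = 5
    contrastive_dim: int = 32
    hidden_dim: int = 64


@dataclass
class EmbeddingBatch:
    """The four projector outputs and labels for one mini-batch."""

    z_E_I: np.ndarray
    z_E_II: np.ndarray
    z_M_I: np.ndarray
    z_M_II: np.ndarray
    labels_E: np.ndarray
    labels_M: np.ndarray

    @property
    def batch_size(self) -> int:
        return len(self.labels_E)


@dataclass
class PairedModel:
    spec: EncoderSpec
    heads: ProjectionHeads
    eeg_channels: int
    params: dict = field(default_factory=dict)


def _init_branch(spec: EncoderSpec, heads: ProjectionHeads, in_channels: int, rng):
    params = {}
    K = spec.kernel_size
    c_in = in_channels
    for i, c_out in enumerate(spec.channels_per_block):
        if spec.family == "cnn1d":
            fan_in = c_in * K
            params[f"conv{i}_w"] = nn.he_init(rng, (c_out, c_in, K), fan_in)
        else:
            fan_in = c_in * K * K
            params[f"conv{i}_w"] = nn.he_init(rng, (c_out, c_in, K, K), fan_in)
        params[f"conv{i}_b"] = np.zeros(c_out)
        c_in = c_out
    d = spec.embedding_dim
    params["feat_w"] = nn.he_init(rng, (c_in, d), c_in)
    params["feat_b"] = np.zeros(d)
    params["pI_w"] = nn.he_init(rng, (d, heads.n_classes), d)
    params["pI_b"] = np.zeros(heads.n_classes)
    params["pII_w1"] = nn.he_init(rng, (d, heads.hidden_dim), d)
    params["pII_b1"] = np.zeros(heads.hidden_dim)
    params["pII_w2"] = nn.he_init(rng, (heads.hidden_dim, heads.contrastive_dim), heads.hidden_dim)
    params["pII_b2"] = np.zeros(heads.contrastive_dim)
    return params


def init_paired_model(
    spec: EncoderSpec, heads: ProjectionHeads, eeg_channels: int, seed: int = 0
) -> PairedModel:
    """Seeded initialization of both branches (structurally identical)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
    eeg_in = eeg_channels if spec.family == "cnn1d" else 1
    params = {
        "eeg": _init_branch(spec, heads, eeg_in, rng),
        "music": _init_branch(spec, heads, 1, rng),
    }
    return PairedModel(spec=spec, heads=heads, eeg_channels=eeg_channels, params=params)


def _as_grid(spec: EncoderSpec, x, modality: str):
    """Lay a batch out in the family's expected shape."""
    x = anp.asarray(x) if isinstance(x, np.ndarray) else x
    if spec.family == "cnn1d":
        if modality == "music" and x.ndim == 2:  # [B, T] -> [B, 1, T]
            x = anp.reshape(x, (x.shape[0], 1, x.shape[1]))
        if x.ndim != 3:
            raise ValueError(f"cnn1d expects [B, C, T], got shape {x.shape}")
        return x
    # cnn2d: single-plane grid
    if modality == "music" and x.ndim == 2:  # [B, T] -> [B, 1, 1, T]
        x = anp.reshape(x, (x.shape[0], 1, 1, x.shape[1]))
    elif x.ndim == 3:  # [B, H, W] -> [B, 1, H, W]
        x = anp.reshape(x, (x.shape[0], 1, x.shape[1], x.shape[2]))
    if x.ndim != 4:
        raise ValueError(f"cnn2d expects a [B, H, W] grid, got shape {x.shape}")
    return x


def encode(spec: EncoderSpec, params: dict, x, modality: str = "eeg"):
    """Run one branch's encoder; returns a [B, embedding_dim] feature block."""
    h = _as_grid(spec, x, modality)
    for i in range(spec.n_blocks):
        w, b = params[f"conv{i}_w"], params[f"conv{i}_b"]
        if spec.family == "cnn1d":
            h = nn.relu(nn.conv1d(h, w, b, padding=spec.padding))
            h = nn.avg_pool1d(h, spec.pool)
        else:
            h = nn.relu(nn.conv2d(h, w, b, padding=spec.padding))
            h = nn.avg_pool2d(h, spec.pool, spec.pool)
    # global average pooling over the remaining extent(s)
    axes = (2,) if spec.family == "cnn1d" else (2, 3)
    h = anp.mean(h, axis=axes)
    return nn.relu(nn.linear(h, params["feat_w"], params["feat_b"]))


def project(params: dict, feats):
    """Both heads: (class logits, contrastive embedding)."""
    logits = nn.linear(feats, params["pI_w"], params["pI_b"])
    hidden = nn.relu(nn.linear(feats, params["pII_w1"], params["pII_b1"]))
    emb = nn.linear(hidden, params["pII_w2"], params["pII_b2"])
    return logits, emb


def forward_pair(
    model: PairedModel,
    eeg_batch,
    music_batch,
    labels_eeg,
    labels_music,
    params: dict | None = None,
    strict: bool = True,
) -> EmbeddingBatch:
    """Forward both branches on a paired batch (row i shares a stimulus).

    ``params`` overrides the model's stored parameters so the same
    function can be traced for gradients.
    """
    p = model.params if params is None else params
    n_e = eeg_batch.shape[0]
    n_m = music_batch.shape[0]
    if n_e != n_m:
        raise ValueError(f"batch sizes differ: EEG {n_e} vs music {n_m}")
    labels_eeg = np.asarray(labels_eeg)
    labels_music = np.asarray(labels_music)
    if len(labels_eeg) != n_e or len(labels_music) != n_m:
        raise ValueError("label vectors must match the batch size")
    if strict and not np.array_equal(labels_eeg, labels_music):
        raise ValueError("paired batch has mismatched EEG/music labels")
    fe = encode(model.spec, p["eeg"], eeg_batch, modality="eeg")
    fm = encode(model.spec, p["music"], music_batch, modality="music")
    z_E_I, z_E_II = project(p["eeg"], fe)
    z_M_I, z_M_II = project(p["music"], fm)
    return EmbeddingBatch(
        z_E_I=z_E_I, z_E_II=z_E_II, z_M_I=z_M_I, z_M_II=z_M_II,
        labels_E=labels_eeg, labels_M=labels_music,
    )


def predict_proba(model: PairedModel, eeg_windows) -> np.ndarray:
    """Softmax class scores from the EEG branch for a stack of windows."""
    feats = encode(model.spec, model.params["eeg"], np.asarray(eeg_windows), "eeg")
    logits, _ = project(model.params["eeg"], feats)
    return nn.softmax(logits, axis=1)


def parameter_counts(model: PairedModel) -> dict:
    """Trainable parameter totals per branch (used by the gradient audit)."""
    return {
        "eeg": nn.parameter_count(model.params["eeg"]),
        "music": nn.parameter_count(model.params["music"]),
        "total": nn.parameter_count(model.params),
    }
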