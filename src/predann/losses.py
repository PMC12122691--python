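"""Training objectives for the paired EEG/stimulus model.

The total objective is

    L = L_clsE + L_clsM + lambda * L_pred

where ``L_clsE`` and ``L_clsM`` are summed cross-entropy losses on the
class logits of the EEG and music branches (Projector I outputs), and
``L_pred`` is a symmetric InfoNCE term on the Projector II embeddings in
which the music-side embeddings pass through a stop-gradient: the EEG
encoder is trained to *predict* the stimulus-network representation,
while the stimulus branch receives no gradient from the contrastive term.

Cosine similarity divided by a temperature ``tau`` scores each
(music anchor, EEG candidate) pair; matched pairs sit on the diagonal of
the in-batch similarity matrix and every off-diagonal pair is a negative,
regardless of class label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import autograd.numpy as anp

from .nn import log_softmax, stop_gradient


@dataclass
class LossConfig:
    """Weights and constants of the combined objective.

    lambda_predann: weight of the contrastive term (0 recovers the
        classification-only baseline).
    temperature: positive scalar dividing cosine similarities before the
        softmax; smaller values sharpen the contrast.
    stop_gradient: when True (default), the music branch receives zero
        gradient from the contrastive term.
    """

    lambda_predann: float = 0.05
    temperature: float = 0.1
    stop_gradient: bool = True

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.lambda_predann < 0:
            raise ValueError("lambda_predann must be >= 0")


@dataclass
class LossBreakdown:
    cls_eeg: float
    cls_music: float
    predann: float
    total: float


def _is_concrete(x) -> bool:
    return isinstance(x, np.ndarray)


def classification_loss(logits, labels):
    """Summed (not averaged) cross-entropy over the batch.

    logits: [B, K]; labels: length-B integer vector in [0, K).
    """
    labels = np.asarray(labels)
    K = logits.shape[1]
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"labels must lie in [0, {K})")
    logp = log_softmax(logits, axis=1)
    B = labels.shape[0]
    return -anp.sum(logp[anp.arange(B), labels])


def cosine_similarity(u, v):
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    if isinstance(u, (list, tuple)):
        u = np.asarray(u, dtype=float)
    if isinstance(v, (list, tuple)):
        v = np.asarray(v, dtype=float)
    nu = anp.sqrt(anp.sum(u * u))
    nv = anp.sqrt(anp.sum(v * v))
    if _is_concrete(u) and _is_concrete(v) and (float(nu) == 0.0 or float(nv) == 0.0):
        raise ValueError("cosine similarity undefined for a zero vector")
    return anp.sum(u * v) / (nu * nv)


def cosine_similarity_matrix(A, B, eps=0.0):
    """Pairwise cosine similarities: out[i, j] = cos(A_i, B_j)."""
    na = anp.sqrt(anp.sum(A * A, axis=1, keepdims=True))
    nb = anp.sqrt(anp.sum(B * B, axis=1, keepdims=True))
    return anp.dot(A / (na + eps), anp.transpose(B / (nb + eps)))


def predann_loss(z_music, z_eeg, cfg: LossConfig):
    """Symmetric stop-gradient InfoNCE between paired embedding blocks.

    z_music, z_eeg: [B, d] Projector II outputs, row i of each coming
    from the same underlying stimulus interval.  Both softmax directions
    share the matched-pair numerator; the first normalizes over EEG
    candidates for a fixed music anchor, the second over music anchors
    for a fixed EEG candidate.  Returns a scalar >= 0 (0 when B = 1).
    """
    if z_music.shape != z_eeg.shape:
        raise ValueError(f"shape mismatch: {z_music.shape} vs {z_eeg.shape}")
    if _is_concrete(z_music) and _is_concrete(z_eeg):
        if np.any(np.linalg.norm(z_music, axis=1) == 0) or np.any(
            np.linalg.norm(z_eeg, axis=1) == 0
        ):
            raise ValueError("embedding rows must be nonzero")
    zm = stop_gradient(z_music) if cfg.stop_gradient else z_music
    S = cosine_similarity_matrix(zm, z_eeg) / cfg.temperature  # [B, B]
    # over EEG candidates (rows) and over music anchors (columns)
    log_p_rows = log_softmax(S, axis=1)
    log_p_cols = log_softmax(S, axis=0)
    diag = anp.arange(S.shape[0])
    return -anp.sum(log_p_rows[diag, diag] + log_p_cols[diag, diag])


def total_loss(cls_eeg, cls_music, predann, cfg: LossConfig) -> LossBreakdown:
    """Assemble the weighted combined objective from its parts."""
    for p in (cls_eeg, cls_music, predann):
        if isinstance(p, (int, float, np.floating, np.ndarray)) and not np.all(
            np.isfinite(p)
        ):
            raise ValueError("non-finite loss component")
    total = cls_eeg + cls_music + cfg.lambda_predann * predann
    return LossBreakdown(
        cls_eeg=cls_eeg, cls_music=cls_music, predann=predann, total=total
    )
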