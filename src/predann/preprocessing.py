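"""Normalization, excerpting, splitting, delay alignment and windowing.

The pipeline mirrors standard practice for continuous-listening EEG:
robust per-channel scaling (median / interquartile range), clamping to a
fixed amplitude band, truncation of every recording to a shared duration,
partitioning into fixed-length excerpts, a stratified train/validation
split on the song label, and extraction of stimulus-aligned analysis
windows with a configurable stimulus-to-response delay.

Conventions: sample indices are 0-based, windows are half-open
``[start, start + W)``, and delays round to the nearest sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import resample_poly
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import RobustScaler


@dataclass
class EEGRecording:
    """A multichannel EEG recording with identity metadata.

    data: [n_channels, n_samples] array in amplitude units.
    fs: sampling rate in Hz.
    subject_id: subject identifier.
    song_id: stimulus class label in [0, n_classes).
    """

    data: np.ndarray
    fs: float
    subject_id: int = 0
    song_id: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("EEG data must be a non-empty [channels, samples] matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AudioStimulus:
    """A mono stimulus waveform with its class label."""

    waveform: np.ndarray
    fs: float
    song_id: int = 0

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()
        if self.waveform.size < 1:
            raise ValueError("empty stimulus waveform")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class PairedSegment:
    """A delay-aligned (EEG window, audio window, label) unit.

    The audio window covers ``[start, start + window)`` in stimulus time;
    the EEG window covers the same interval shifted later by ``delay_ms``.
    """

    eeg: np.ndarray
    audio: np.ndarray
    label_eeg: int
    label_music: int
    delay_ms: float = 0.0
    subject_id: int = 0

    def __post_init__(self):
        if self.delay_ms < 0:
            raise ValueError("delay must be non-negative")


@dataclass
class SplitSpec:
    """Excerpting and stratified-split settings (75:25 by default)."""

    excerpt_seconds: float = 30.0
    train_fraction: float = 0.75
    stratify_on: str = "song_id"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def robust_scale_channels(rec: EEGRecording) -> EEGRecording:
    """Scale each channel to median 0 and unit interquartile range.

    Channels with zero IQR (constant or near-constant) are centered only;
    a warning names them.  Quartiles use linear interpolation.
    """
    if rec.n_samples < 2:
        raise ValueError("each channel needs at least 2 samples to estimate an IQR")
    scaler = RobustScaler(with_centering=True, with_scaling=True)
    scaled = scaler.fit_transform(rec.data.T).T
    q1, q3 = np.percentile(rec.data, [25, 75], axis=1)
    zero_iqr = np.flatnonzero((q3 - q1) == 0)
    if zero_iqr.size:
        warnings.warn(
            f"channels with zero IQR centered only: {zero_iqr.tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not np.all(np.isfinite(scaled)):
        raise ValueError("non-finite values after scaling")
    return replace(rec, data=scaled)


def clamp_values(rec: EEGRecording, bound: float = 20.0) -> EEGRecording:
    """Clip every sample into [-bound, +bound]."""
    if bound <= 0:
        raise ValueError("bound must be positive")
    return replace(rec, data=np.clip(rec.data, -bound, bound))


def truncate_and_excerpt(
    rec: EEGRecording, total_seconds: float = 240.0, excerpt_seconds: float = 30.0
) -> list[EEGRecording]:
    """Truncate to ``total_seconds`` and cut contiguous non-overlapping excerpts.

    The excerpts concatenate exactly to the truncated recording; any tail
    beyond ``total_seconds`` is discarded.
    """
    total = int(round(total_seconds * rec.fs))
    if rec.n_samples < total:
        deficit = (total - rec.n_samples) / rec.fs
        raise ValueError(
            f"recording is {deficit:.3f} s shorter than the requested {total_seconds} s"
        )
    exc = int(round(excerpt_seconds * rec.fs))
    n = total // exc
    return [
        replace(rec, data=rec.data[:, i * exc : (i + 1) * exc]) for i in range(n)
    ]


def truncate_and_excerpt_audio(
    stim: AudioStimulus, total_seconds: float = 240.0, excerpt_seconds: float = 30.0
) -> list[AudioStimulus]:
    """Audio counterpart of :func:`truncate_and_excerpt`."""
    total = int(round(total_seconds * stim.fs))
    if stim.waveform.size < total:
        deficit = (total - stim.waveform.size) / stim.fs
        raise ValueError(
            f"stimulus is {deficit:.3f} s shorter than the requested {total_seconds} s"
        )
    exc = int(round(excerpt_seconds * stim.fs))
    n = total // exc
    return [
        replace(stim, waveform=stim.waveform[i * exc : (i + 1) * exc])
        for i in range(n)
    ]


def stratified_split(excerpts: Sequence, spec: SplitSpec):
    """Split excerpt-like items into train/validation, stratified on song label.

    Items need a ``song_id`` attribute (or a ``label`` attribute as a
    fallback).  Assignment is reproducible from ``spec.seed``; per-class
    counts follow ``train_fraction`` within integer rounding.
    """
    items = list(excerpts)
    labels = [getattr(x, spec.stratify_on, getattr(x, "label", None)) for x in items]
    if any(l is None for l in labels):
        raise ValueError(f"items lack a '{spec.stratify_on}' label")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 excerpts to stratify")
    train, val = train_test_split(
        items,
        train_size=spec.train_fraction,
        stratify=labels,
        random_state=spec.seed,
        shuffle=True,
    )
    return train, val


def apply_delay(
    eeg: EEGRecording,
    audio: AudioStimulus,
    delay_ms: float,
    window_seconds: float,
    start_seconds: float,
) -> PairedSegment:
    """Cut a paired window with the EEG side shifted later by ``delay_ms``.

    The audio window covers ``[start, start + window)``; the EEG window
    covers the same interval delayed, starting at sample
    ``round((start + delay_ms / 1000) * fs_eeg)``.
    """
    if delay_ms < 0:
        raise ValueError("delay must be non-negative")
    a0 = int(round(start_seconds * audio.fs))
    a1 = a0 + int(round(window_seconds * audio.fs))
    if a0 < 0 or a1 > audio.waveform.size:
        raise ValueError("audio window out of range")
    e0 = int(round((start_seconds + delay_ms / 1000.0) * eeg.fs))
    e1 = e0 + int(round(window_seconds * eeg.fs))
    if e0 < 0 or e1 > eeg.n_samples:
        raise ValueError(
            f"delayed EEG window [{e0}, {e1}) exceeds recording of "
            f"{eeg.n_samples} samples"
        )
    return PairedSegment(
        eeg=eeg.data[:, e0:e1],
        audio=audio.waveform[a0:a1],
        label_eeg=eeg.song_id,
        label_music=audio.song_id,
        delay_ms=delay_ms,
        subject_id=eeg.subject_id,
    )


def extract_windows(
    rec: EEGRecording, window_samples: int, stride_samples: int
) -> list[np.ndarray]:
    """All [channels, window] views on the stride grid, in temporal order.

    Returns ``floor((n_samples - window) / stride) + 1`` windows.
    """
    if window_samples > rec.n_samples:
        raise ValueError(
            f"window of {window_samples} samples exceeds recording of "
            f"{rec.n_samples}"
        )
    if stride_samples < 1:
        raise ValueError("stride must be >= 1")
    n = (rec.n_samples - window_samples) // stride_samples + 1
    return [
        rec.data[:, i * stride_samples : i * stride_samples + window_samples]
        for i in range(n)
    ]


def resample_recording(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase resampling to ``target_fs`` (e.g. raw 1000 Hz down to 125 Hz)."""
    if target_fs <= 0:
        raise ValueError("target rate must be positive")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, fs=target_fs)
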