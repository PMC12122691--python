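"""HDF5 container for paired EEG/audio datasets.

Layout: ``/eeg/{subject}/{song}`` holds a [channels, samples] dataset
with an ``fs`` attribute; ``/audio/{song}`` holds the stimulus waveform
with its ``fs``.  An optional best-effort reader for MATLAB v7.3 files
(which are HDF5 underneath) is provided for real-data containers; it is
never used unless called explicitly.
"""

from __future__ import annotations

import h5py
import numpy as np

from .preprocessing import AudioStimulus, EEGRecording
from .synthetic import SyntheticDataset


def save_dataset(path, data: SyntheticDataset) -> None:
    with h5py.File(path, "w") as f:
        for rec in data.recordings:
            ds = f.create_dataset(f"eeg/{rec.subject_id}/{rec.song_id}", data=rec.data)
            ds.attrs["fs"] = rec.fs
        for stim in data.stimuli:
            ds = f.create_dataset(f"audio/{stim.song_id}", data=stim.waveform)
            ds.attrs["fs"] = stim.fs


def load_dataset(path) -> SyntheticDataset:
    recordings, stimuli = [], []
    with h5py.File(path, "r") as f:
        for subject in sorted(f["eeg"], key=int):
            for song in sorted(f["eeg"][subject], key=int):
                ds = f["eeg"][subject][song]
                recordings.append(
                    EEGRecording(data=ds[...], fs=float(ds.attrs["fs"]),
                                 subject_id=int(subject), song_id=int(song))
                )
        for song in sorted(f["audio"], key=int):
            ds = f["audio"][song]
            stimuli.append(
                AudioStimulus(waveform=ds[...], fs=float(ds.attrs["fs"]),
                              song_id=int(song))
            )
    return SyntheticDataset(stimuli=stimuli, recordings=recordings)


def read_matlab_v73(path, variable: str, fs: float,
                    subject_id: int = 0, song_id: int = 0,
                    channels_axis: int = 0) -> EEGRecording:
    """Read one array variable from a MATLAB v7.3 (HDF5-based) container.

    MATLAB stores arrays column-major, so 2-D variables usually arrive
    transposed; set ``channels_axis=1`` if channels end up on the second
    axis.
    """
    with h5py.File(path, "r") as f:
        if variable not in f:
            raise KeyError(
                f"variable {variable!r} not found; available: {list(f.keys())}"
            )
        arr = np.asarray(f[variable])
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D EEG array, got shape {arr.shape}")
    if channels_axis == 1:
        arr = arr.T
    return EEGRecording(data=arr, fs=fs, subject_id=subject_id, song_id=song_id)
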