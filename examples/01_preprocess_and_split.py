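"""Preprocess a synthetic paired dataset and build a stratified split.

Generates a small 5-song, 2-subject dataset, robust-scales and clamps the
EEG, cuts 30-s excerpts, and splits them 75:25 stratified on the song
label.  The printed counts show every song contributing the same number
of excerpts to each side of the split.
"""

import numpy as np

from predann.experiments import build_excerpt_sets
from predann.preprocessing import SplitSpec, clamp_values, robust_scale_channels
from predann.synthetic import SyntheticConfig, make_dataset

cfg = SyntheticConfig(seed=0)
data = make_dataset(cfg)
rec = data.recordings[0]
print(f"{len(data.recordings)} recordings of {rec.n_channels} channels x "
      f"{rec.n_samples} samples at {rec.fs:g} Hz")

scaled = clamp_values(robust_scale_channels(rec))
med = np.median(scaled.data, axis=1)
q1, q3 = np.percentile(scaled.data, [25, 75], axis=1)
print(f"after scaling: per-channel median ~{np.abs(med).max():.2e}, "
      f"IQR ~{(q3 - q1).mean():.6f}, max |value| {np.abs(scaled.data).max():.2f}")

train, val = build_excerpt_sets(data, SplitSpec(excerpt_seconds=30.0, seed=0))
per_song = {c: sum(1 for x in train if x.song_id == c) for c in range(cfg.n_classes)}
print(f"{len(train)} training and {len(val)} validation excerpts; "
      f"training excerpts per song: {per_song}")
print("Each 30-s excerpt is one sampling unit; the 75:25 split keeps the "
      "song distribution identical on both sides.")
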