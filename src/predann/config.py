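"""YAML configuration loading.

A config file may contain any of the sections ``synthetic``,
``preprocessing``, ``split``, ``model``, ``train`` and ``loss``; each
maps onto the corresponding dataclass, with unspecified fields keeping
their defaults.
"""

from __future__ import annotations

import yaml

from .losses import LossConfig
from .models import EncoderSpec, ProjectionHeads
from .preprocessing import SplitSpec
from .synthetic import SyntheticConfig
from .training import TrainConfig


def load_config(path) -> dict:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    out = {"raw": raw}
    out["synthetic"] = SyntheticConfig(**raw.get("synthetic", {}))
    out["split"] = SplitSpec(**raw.get("split", {}))
    out["loss"] = LossConfig(**raw.get("loss", {}))
    out["train"] = TrainConfig(**raw.get("train", {}))
    model = dict(raw.get("model", {}))
    heads = {k: model.pop(k) for k in ("n_classes", "contrastive_dim", "hidden_dim")
             if k in model}
    if "channels_per_block" in model:
        model["channels_per_block"] = tuple(model["channels_per_block"])
    out["encoder"] = EncoderSpec(**model)
    out["heads"] = ProjectionHeads(
        **{"n_classes": out["synthetic"].n_classes, **heads}
    )
    out["preprocessing"] = {
        "clamp_bound": raw.get("preprocessing", {}).get("clamp_bound", 20.0),
    }
    return out
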