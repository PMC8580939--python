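"""Configuration objects for the network, the loss and the optimizer.

The architecture is controlled by :class:`ModelConfig`; its stage flags
(``use_encoder``, ``use_decoder``, ``use_attention``, ``use_pooling``,
``use_skill_head``) select which stages of the full network run, which is
how the ablation presets in :data:`ABLATION_PRESETS` are expressed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ModelConfig",
    "LossConfig",
    "TrainConfig",
    "ABLATION_PRESETS",
    "ablation_config",
    "load_config",
    "save_config",
]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Parameters
    ----------
    n_layers:
        Number of dilated residual layers in each of the encoder and
        decoder stacks (``L``). Layer ``l`` (0-based) uses dilation
        ``2**l``, so the stack's receptive field grows exponentially.
    in_dim:
        Dimensionality of the per-frame input features (128 for the
        spatial-CNN features the network nominally consumes).
    channels:
        Internal channel width ``f``; the input is mapped to this width by
        a 1x1 convolution before the encoder.
    kernel:
        Temporal kernel width of the dilated convolutions; must be odd
        because the convolutions are acausal (centered).
    pool:
        Temporal max-pooling factor applied after the encoder; the decoder
        undoes it with nearest-neighbour unpooling.
    d_k, d_v:
        Query/key and value dimensions of the scaled dot-product
        self-attention at the bottleneck (single head).
    ffn_hidden:
        Hidden width of the position-wise feed-forward layer inside the
        attention block.
    n_gestures, n_skills:
        Output class counts of the per-frame gesture head and the
        per-video skill head.
    """

    n_layers: int = 10
    in_dim: int = 128
    channels: int = 128
    kernel: int = 3
    pool: int = 4
    d_k: int = 16
    d_v: int = 16
    ffn_hidden: int = 512
    n_gestures: int = 10
    n_skills: int = 3
    use_encoder: bool = True
    use_decoder: bool = True
    use_attention: bool = True
    use_pooling: bool = True
    use_skill_head: bool = True
    dilations: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be a positive odd integer (acausal mode)")
        if self.pool < 1:
            raise ValueError("pool must be >= 1")
        for name in ("in_dim", "channels", "d_k", "d_v", "ffn_hidden", "n_gestures", "n_skills"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (self.use_encoder or self.use_decoder or self.use_attention):
            raise ValueError("at least one of encoder/decoder/attention must be enabled")
        if self.dilations is None:
            self.dilations = tuple(2**l for l in range(self.n_layers))
        else:
            self.dilations = tuple(int(d) for d in self.dilations)
            if len(self.dilations) != self.n_layers or any(d < 1 for d in self.dilations):
                raise ValueError("dilations must list one rate >= 1 per layer")


@dataclass
class LossConfig:
    """Weights of the multi-task loss  L = alpha * L_gesture + beta * L_skill.

    Gesture segmentation is the main task and skill assessment the
    auxiliary one, hence the default 0.9 / 0.1 split.
    """

    alpha: float = 0.9
    beta: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive")


@dataclass
class TrainConfig:
    """Optimization settings: Adam, one full-length sequence per step."""

    epochs: int = 30
    learning_rate: float = 0.01
    seed: int = 0
    shuffle: bool = True
    grad_clip: float | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# Ablation presets, ordered from the attention-only baseline to the full
# multi-task network.  Keys are (use_encoder, use_decoder, use_attention,
# use_pooling, use_skill_head).
ABLATION_PRESETS: dict[str, dict[str, bool]] = {
    "attention_only": dict(
        use_encoder=False, use_decoder=False, use_attention=True,
        use_pooling=False, use_skill_head=False),
    "dilation_only": dict(
        use_encoder=True, use_decoder=False, use_attention=False,
        use_pooling=False, use_skill_head=False),
    "encoder_attention": dict(
        use_encoder=True, use_decoder=False, use_attention=True,
        use_pooling=False, use_skill_head=False),
    "attention_decoder": dict(
        use_encoder=False, use_decoder=True, use_attention=True,
        use_pooling=False, use_skill_head=False),
    "symmetric_attention": dict(
        use_encoder=True, use_decoder=True, use_attention=True,
        use_pooling=False, use_skill_head=False),
    "symmetric_attention_pooling": dict(
        use_encoder=True, use_decoder=True, use_attention=True,
        use_pooling=True, use_skill_head=False),
    "multitask_full": dict(
        use_encoder=True, use_decoder=True, use_attention=True,
        use_pooling=True, use_skill_head=True),
}


def ablation_config(preset: str, base: ModelConfig | None = None) -> ModelConfig:
    """Return a copy of ``base`` with the stage flags of an ablation preset."""
    if preset not in ABLATION_PRESETS:
        raise KeyError(f"unknown ablation preset {preset!r}; "
                       f"choose from {sorted(ABLATION_PRESETS)}")
    base = base if base is not None else ModelConfig()
    return dataclasses.replace(base, **ABLATION_PRESETS[preset])


_SECTIONS = {"model": ModelConfig, "loss": LossConfig, "train": TrainConfig}


def load_config(path: str | Path) -> dict[str, object]:
    """Load a YAML config file with optional ``model``/``loss``/``train`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    out: dict[str, object] = {}
    for section, cls in _SECTIONS.items():
        kwargs = raw.get(section, {})
        if not isinstance(kwargs, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown keys in {section!r}: {sorted(unknown)}")
        out[section] = cls(**kwargs)
    return out


def save_config(configs: dict[str, object], path: str | Path) -> None:
    raw = {}
    for section, obj in configs.items():
        d = dataclasses.asdict(obj)
        if isinstance(obj, ModelConfig):
            d["dilations"] = list(obj.dilations)
        raw[section] = d
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
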