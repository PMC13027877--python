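"""YAML configuration loading and the two built-in presets.

Schema (all keys optional; omitted keys fall back to defaults)::

    preset: tiny | paper
    encoder:
      channels: [16, 32, 64, 96, 128]
      use_ssm_stages: [false, false, false, true, true]
      fba_enabled: true
    asm:
      state_dim: 16
      ffn_expansion: 4
    lalga:
      ggca_reduction: 4
    tpff:
      enabled_paths: [cp, sp, dp]
      init_coefficients: [0.4, 0.2, 0.4]
    ablation: {fba: true, asm: true, lalga: true, tpff: true}
    head: {threshold: 0.5}
    train:
      lr: 0.001
      lr_min: 0.00001
      batch_size: 32
      epochs: 100
      input_size: [256, 256]
      augment: true
      seed: 0
      max_steps: null
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .encoder import EncoderConfig
from .exceptions import ConfigurationError
from .losses import LossWeights
from .network import PAPER_PRESET, TINY_PRESET, ModelConfig
from .train import TrainConfig

__all__ = ["load_config", "model_config_from_dict", "train_config_from_dict",
           "resolve_preset"]

TINY_TRAIN = TrainConfig(batch_size=8, epochs=30, input_size=(64, 64))
PAPER_TRAIN = TrainConfig()


def resolve_preset(name: str) -> tuple[ModelConfig, TrainConfig]:
    presets = {"tiny": (TINY_PRESET, TINY_TRAIN), "paper": (PAPER_PRESET, PAPER_TRAIN)}
    if name not in presets:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]


def load_config(path_or_dict) -> tuple[ModelConfig, TrainConfig]:
    """Load a YAML file (or pre-parsed dict) into the two config objects."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    model_cfg, train_cfg = resolve_preset(raw.get("preset", "paper"))

    enc = dict(raw.get("encoder", {}))
    enc_cfg = EncoderConfig(
        channels=tuple(enc.get("channels", model_cfg.encoder.channels)),
        use_ssm_stages=tuple(enc.get("use_ssm_stages", model_cfg.encoder.use_ssm_stages)),
        fba_enabled=bool(enc.get("fba_enabled", model_cfg.encoder.fba_enabled)),
        state_dim=int(raw.get("asm", {}).get("state_dim", model_cfg.encoder.state_dim)),
    )
    asm = dict(raw.get("asm", {}))
    lalga = dict(raw.get("lalga", {}))
    tpff = dict(raw.get("tpff", {}))
    ablation = dict(raw.get("ablation", {}))
    head = dict(raw.get("head", {}))
    model_cfg = ModelConfig(
        encoder=enc_cfg,
        state_dim=int(asm.get("state_dim", model_cfg.state_dim)),
        ffn_expansion=int(asm.get("ffn_expansion", model_cfg.ffn_expansion)),
        ggca_reduction=int(lalga.get("ggca_reduction", model_cfg.ggca_reduction)),
        tpff_enabled_paths=tuple(tpff.get("enabled_paths", model_cfg.tpff_enabled_paths)),
        tpff_init_coefficients=tuple(
            tpff.get("init_coefficients", model_cfg.tpff_init_coefficients)),
        use_fba=bool(ablation.get("fba", model_cfg.use_fba)),
        use_asm=bool(ablation.get("asm", model_cfg.use_asm)),
        use_lalga=bool(ablation.get("lalga", model_cfg.use_lalga)),
        use_tpff=bool(ablation.get("tpff", model_cfg.use_tpff)),
        threshold=float(head.get("threshold", model_cfg.threshold)),
    )

    tr = dict(raw.get("train", {}))
    train_cfg = TrainConfig(
        lr=float(tr.get("lr", train_cfg.lr)),
        lr_min=float(tr.get("lr_min", train_cfg.lr_min)),
        weight_decay=float(tr.get("weight_decay", train_cfg.weight_decay)),
        batch_size=int(tr.get("batch_size", train_cfg.batch_size)),
        epochs=int(tr.get("epochs", train_cfg.epochs)),
        input_size=tuple(tr.get("input_size", train_cfg.input_size)),
        augment=bool(tr.get("augment", train_cfg.augment)),
        seed=int(tr.get("seed", train_cfg.seed)),
        loss=LossWeights(float(tr.get("lambda1", 1.0)), float(tr.get("lambda2", 1.0))),
        max_steps=tr.get("max_steps", train_cfg.max_steps),
    )
    return model_cfg, train_cfg


def model_config_from_dict(d: dict) -> ModelConfig:
    enc = d.get("encoder", {})
    return ModelConfig(
        encoder=EncoderConfig(
            channels=tuple(enc.get("channels", (16, 32, 64, 96, 128))),
            use_ssm_stages=tuple(enc.get("use_ssm_stages", (False,) * 5)),
            fba_enabled=bool(enc.get("fba_enabled", True)),
            in_channels=int(enc.get("in_channels", 3)),
            state_dim=int(enc.get("state_dim", 16)),
            gn_groups=int(enc.get("gn_groups", 8)),
        ),
        state_dim=int(d.get("state_dim", 16)),
        ffn_expansion=int(d.get("ffn_expansion", 4)),
        bottleneck_ratio=int(d.get("bottleneck_ratio", 4)),
        ggca_reduction=int(d.get("ggca_reduction", 4)),
        gn_groups=int(d.get("gn_groups", 8)),
        tpff_enabled_paths=tuple(d.get("tpff_enabled_paths", ("cp", "sp", "dp"))),
        tpff_init_coefficients=tuple(d.get("tpff_init_coefficients", (0.4, 0.2, 0.4))),
        use_fba=bool(d.get("use_fba", True)),
        use_asm=bool(d.get("use_asm", True)),
        use_lalga=bool(d.get("use_lalga", True)),
        use_tpff=bool(d.get("use_tpff", True)),
        threshold=float(d.get("threshold", 0.5)),
    )


def train_config_from_dict(d: dict) -> TrainConfig:
    loss = d.get("loss", {})
    return TrainConfig(
        lr=float(d.get("lr", 1e-3)),
        lr_min=float(d.get("lr_min", 1e-5)),
        weight_decay=float(d.get("weight_decay", 1e-2)),
        batch_size=int(d.get("batch_size", 32)),
        epochs=int(d.get("epochs", 100)),
        input_size=tuple(d.get("input_size", (256, 256))),
        augment=bool(d.get("augment", True)),
        seed=int(d.get("seed", 0)),
        loss=LossWeights(float(loss.get("lambda1", 1.0)), float(loss.get("lambda2", 1.0))),
        max_steps=d.get("max_steps"),
    )
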