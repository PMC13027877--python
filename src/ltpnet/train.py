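"""Training loop, checkpointing and evaluation.

The loop follows the published protocol at configurable scale: AdamW at
initial learning rate 1e-3 decayed by a cosine schedule fixed a priori,
batched flip/rotation augmentation, and the hybrid BCE+Dice objective.
The fusion-coefficient simplex invariant is re-asserted after every
optimizer step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import LesionDataset, augment, channel_stats
from .exceptions import ConfigurationError
from .losses import LossWeights, hybrid_loss
from .metrics import confusion, pr_roc, segmentation_metrics
from .network import LTPNet, ModelConfig
from .nn import AdamW, Tensor, cosine_lr

__all__ = ["TrainConfig", "train", "evaluate", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    lr_min: float = 1e-5
    weight_decay: float = 1e-2
    batch_size: int = 32
    epochs: int = 100
    input_size: tuple[int, int] = (256, 256)
    augment: bool = True
    seed: int = 0
    loss: LossWeights = field(default_factory=LossWeights)
    max_steps: int | None = None  # overrides epochs * steps_per_epoch when set

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigurationError("batch_size and epochs must be >= 1")


# ---------------------------------------------------------------------------
# checkpoints: one .npz archive holding weights + configs + channel stats
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: LTPNet, train_cfg: TrainConfig,
                    stats: tuple[np.ndarray, np.ndarray]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    meta = {
        "model_config": _cfg_to_jsonable(model.cfg),
        "train_config": _cfg_to_jsonable(train_cfg),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             __mean__=stats[0], __std__=stats[1],
             **{f"w/{k}": v for k, v in state.items()})


def load_checkpoint(path):
    """Return (model, train_cfg, (mean, std)) rebuilt from an archive."""
    from .config import model_config_from_dict, train_config_from_dict

    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        mean, std = z["__mean__"], z["__std__"]
        state = {k[2:]: z[k] for k in z.files if k.startswith("w/")}
    model = LTPNet(model_config_from_dict(meta["model_config"]))
    model.load_state_dict(state)
    model.eval()
    train_cfg = train_config_from_dict(meta["train_config"])
    return model, train_cfg, (mean, std)


def _cfg_to_jsonable(cfg):
    def conv(v):
        if dataclasses.is_dataclass(v):
            return {k: conv(getattr(v, k)) for k in v.__dataclass_fields__}
        if isinstance(v, tuple):
            return list(v)
        return v

    return conv(cfg)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _normalise(images: np.ndarray, stats) -> np.ndarray:
    mean, std = stats
    return (images - mean[None, :, None, None]) / std[None, :, None, None]


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, data_dir,
          out_dir=None, log_fn=None):
    """Train a fresh model; returns (model, history, stats).

    ``history`` is a list of per-step records (step, lr, loss).  If
    ``out_dir`` is given, a checkpoint and a JSONL log are written there.
    """
    dataset = LesionDataset(data_dir, size=train_cfg.input_size)
    if len(dataset) == 0:
        raise ConfigurationError(f"no training pairs found under {data_dir}")
    images, masks = dataset.load_all()
    stats = channel_stats(images)

    nn.manual_seed(train_cfg.seed)
    model = LTPNet(model_cfg)
    opt = AdamW(model.parameters(), lr=train_cfg.lr,
                weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)

    n = len(dataset)
    bs = min(train_cfg.batch_size, n)
    steps_per_epoch = max(1, n // bs)
    if train_cfg.max_steps is not None:
        total_steps = train_cfg.max_steps  # explicit desk-scale override
    else:
        total_steps = train_cfg.epochs * steps_per_epoch

    history = []
    step = 0
    model.train()
    while step < total_steps:
        order = rng.permutation(n)
        for start in range(0, steps_per_epoch * bs, bs):
            if step >= total_steps:
                break
            idx = order[start:start + bs]
            xb, gb = images[idx], masks[idx]
            if train_cfg.augment:
                pairs = [augment(x, g, rng) for x, g in zip(xb, gb)]
                xb = np.stack([p[0] for p in pairs])
                gb = np.stack([p[1] for p in pairs])
            opt.lr = cosine_lr(step, total_steps, train_cfg.lr, train_cfg.lr_min)
            probs = model(Tensor(_normalise(xb, stats)))
            loss = hybrid_loss(probs, Tensor(gb), train_cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at step {step}: {loss.item()} "
                    f"(lr={opt.lr:.2e}); aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            model.assert_simplex()
            record = {"step": step, "lr": opt.lr, "loss": loss.item()}
            history.append(record)
            if log_fn:
                log_fn(record)
            step += 1

    model.eval()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "checkpoint.npz", model, train_cfg, stats)
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for record in history:
                fh.write(json.dumps(record) + "\n")
    return model, history, stats


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(model: LTPNet, data_dir, stats, size=(256, 256), threshold: float = 0.5,
             out_dir=None, batch_size: int = 8):
    """Aggregate pixel metrics plus PR/ROC curves over a dataset.

    Writes ``metrics.json`` and curve CSVs to ``out_dir`` when given.
    Returns (report, curves, per_image_dsc).
    """
    dataset = LesionDataset(data_dir, size=size)
    if len(dataset) == 0:
        raise ConfigurationError(f"no evaluation pairs found under {data_dir}")
    images, masks = dataset.load_all()
    model.eval()
    all_probs = []
    for start in range(0, len(dataset), batch_size):
        xb = _normalise(images[start:start + batch_size], stats)
        all_probs.append(model(Tensor(xb)).data)
    probs = np.concatenate(all_probs)
    preds = (probs >= threshold).astype(int)
    gt = masks.astype(int)

    counts = confusion(preds, gt)
    report = segmentation_metrics(counts)
    curves = pr_roc(probs, gt)
    report = dataclasses.replace(report, auc_pr=curves.auc_pr, auc_roc=curves.auc_roc)
    per_image = [
        segmentation_metrics(confusion(preds[i], gt[i])).dsc
        if gt[i].any() and not gt[i].all() else float("nan")
        for i in range(len(dataset))
    ]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = report.as_dict()
        payload["counts"] = dataclasses.asdict(counts)
        payload["per_image_dsc"] = per_image
        (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2))
        header = "threshold,precision,recall,tpr,fpr"
        rows = np.column_stack([curves.thresholds, curves.precision, curves.recall,
                                curves.tpr, curves.fpr])
        np.savetxt(out_dir / "curves.csv", rows, delimiter=",", header=header, comments="")
    return report, curves, per_image
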