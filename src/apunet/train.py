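"""Training and evaluation: multi-head cross-entropy + Adam.

Both subnetworks are supervised with pixelwise cross-entropy against the
lesion mask; models with a multiscale-aggregation head additionally
supervise that head. Default hyperparameters: Adam, learning rate 0.005,
batch size 8, weight decay 1e-7, 150 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import metrics, nn
from .models import model_inputs, predict_mask
from .nn import Tensor
from .phantom import ImageTriplet

__all__ = ["TrainConfig", "TrainLog", "loss", "train", "evaluate"]

HEAD_ORDER = ("main", "decoder_a", "decoder_b")


class TrainConfig(BaseModel):
    """Optimization hyperparameters.

    ``loss_weights`` maps head names to non-negative weights in the order
    (main, decoder_a, decoder_b); heads absent from the model are ignored
    when their weight is zero but it is an error to weight a missing head.
    """

    model_config = ConfigDict(extra="forbid")

    learning_rate: float = Field(0.005, gt=0)
    batch_size: int = Field(8, ge=1)
    epochs: int = Field(150, ge=1)
    weight_decay: float = Field(1e-7, ge=0)
    seed: int = 0
    loss_weights: dict[str, float] = {"main": 1.0, "decoder_a": 1.0,
                                      "decoder_b": 1.0}
    device: Literal["cpu", "accelerator"] = "cpu"


@dataclass
class TrainLog:
    """Per-epoch mean loss and training-set Dice."""

    epochs: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def final_loss(self) -> float:
        return self.epochs[-1]["loss"]

    @property
    def best_train_dsc(self) -> float:
        return max(e["train_dsc"] for e in self.epochs)


def loss(outputs: dict[str, Tensor], mask: np.ndarray,
         weights: dict[str, float] | None = None) -> Tensor:
    """Weighted sum of per-head pixelwise cross-entropies.

    ``mask`` is (H, W) or (N, H, W) integer labels. Heads with zero weight
    are skipped; weighting a head the model does not emit is an error.
    """
    if weights is None:
        weights = {k: 1.0 for k in outputs}
    active = {k: w for k, w in weights.items() if w != 0.0}
    missing = set(active) - set(outputs)
    if missing:
        raise ValueError(
            f"loss weights name heads the model lacks: {sorted(missing)} "
            f"(model heads: {sorted(outputs)})")
    target = np.asarray(mask)
    if target.ndim == 2:
        target = target[None]
    total = None
    for name, w in active.items():
        term = nn.cross_entropy_with_logits(outputs[name], target) * w
        total = term if total is None else total + term
    if total is None:
        raise ValueError("all loss weights are zero")
    return total


def _batch_inputs(model, samples: Sequence[ImageTriplet]):
    """Stack triplets into the batched argument list of the variant."""

    def stack(attr):
        arr = np.stack([np.asarray(getattr(s, attr), dtype=np.float32)
                        for s in samples])
        return Tensor(arr[:, None])

    args = model_inputs(model, samples[0])
    if len(args) == 1:  # single/multi-encoder U-Net takes a list of images
        mods = ["ct"] if len(args[0]) == 1 else ["ct", "pet", "fused"]
        return ([stack(m) for m in mods],)
    return (stack("ct"), stack("pet"), stack("fused"))


def _batch_dice(logits: np.ndarray, masks: np.ndarray) -> float:
    """Mean Dice of argmax predictions over a batch (1.0 on double-empty)."""
    pred = logits.argmax(axis=1)
    scores = []
    for p, g in zip(pred, masks):
        denom = p.sum() + g.sum()
        scores.append(1.0 if denom == 0 else 2.0 * np.sum((p == 1) & (g == 1)) / denom)
    return float(np.mean(scores))


def train(model, samples: Sequence[ImageTriplet], config: TrainConfig
          ) -> TrainLog:
    """Mini-batch Adam training; deterministic given (model seed, config.seed).

    Shuffles each epoch from a generator seeded by ``config.seed``,
    reseeds the model's dropout streams from the same seed, checkpoints
    the best-train-Dice parameters, and restores them before returning.
    Aborts with a diagnostic if the loss goes non-finite.
    """
    if not samples:
        raise ValueError("empty training set")
    if config.device != "cpu":
        raise NotImplementedError("only CPU training is supported")
    rng = np.random.default_rng(config.seed)
    for i, m in enumerate(mod for mod in model.modules()
                          if isinstance(mod, nn.Dropout)):
        m.reseed(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2 ** 31))

    masks = np.stack([s.mask.astype(np.int64) for s in samples])
    log = TrainLog()
    best = (-1.0, None)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    model.train()
    n = len(samples)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, dices = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [samples[i] for i in idx]
            outputs = model(*_batch_inputs(model, batch))
            batch_loss = loss(outputs, masks[idx], config.loss_weights)
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            losses.append(float(batch_loss.data))
            dices.append(_batch_dice(outputs["main"].data, masks[idx]))
        entry = {"epoch": epoch, "loss": float(np.mean(losses)),
                 "train_dsc": float(np.mean(dices))}
        log.epochs.append(entry)
        # ties keep the latest epoch so normalization statistics are the
        # most converged ones
        if entry["train_dsc"] >= best[0]:
            best = (entry["train_dsc"], model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return log


def evaluate(model, samples: Sequence[ImageTriplet],
             out_path: str | Path | None = None) -> metrics.MetricReport:
    """Predict every sample and report DSC/Recall/VOE/RVD (CSV optional)."""
    preds = [(predict_mask(model, s), s.mask) for s in samples]
    report = metrics.report_from_pairs(
        preds, sample_ids=[s.sample_id or f"sample_{i:04d}"
                           for i, s in enumerate(samples)])
    if out_path is not None:
        report.to_csv(out_path)
    return report
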