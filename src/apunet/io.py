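"""Disk formats: PNG triplets, CSV manifests, YAML configs, checkpoints."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .models import ModelSpec
from .phantom import ImageTriplet, PhantomConfig
from .train import TrainConfig

__all__ = ["RunConfig", "load_config", "dump_config", "read_triplet",
           "load_manifest", "load_dataset", "save_checkpoint",
           "load_checkpoint"]

MASK_THRESHOLD = 128  # 8-bit masks binarize at half scale


class RunConfig(BaseModel):
    """Top-level YAML config: phantom + model + training sections."""

    model_config = ConfigDict(extra="forbid")

    phantom: PhantomConfig = PhantomConfig()
    model: ModelSpec = ModelSpec()
    train: TrainConfig = TrainConfig()


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config; empty file means all defaults.

    Unknown keys and invalid values raise ``ValueError`` naming the field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        locs = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors())
        raise ValueError(f"invalid config {path}: {locs}") from err


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))


def _read_png(path: Path) -> np.ndarray:
    from PIL import Image

    if not path.exists():
        raise FileNotFoundError(f"missing image file: {path}")
    return np.asarray(Image.open(path).convert("L"))


def read_triplet(row, root: str | Path = ".") -> ImageTriplet:
    """Load one manifest row into an in-memory triplet.

    Intensities are scaled to [0, 1]; the mask binarizes at 128. All four
    images must agree in size.
    """
    root = Path(root)
    imgs = {}
    for mod in ("ct", "pet", "fused", "mask"):
        imgs[mod] = _read_png(root / row[mod])
    shapes = {m: a.shape for m, a in imgs.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"modalities disagree in size: {shapes}")
    return ImageTriplet(
        ct=imgs["ct"].astype(np.float64) / 255.0,
        pet=imgs["pet"].astype(np.float64) / 255.0,
        fused=imgs["fused"].astype(np.float64) / 255.0,
        mask=(imgs["mask"] >= MASK_THRESHOLD).astype(np.uint8),
        sample_id=str(row["sample_id"]),
    )


def load_manifest(data_dir: str | Path) -> pd.DataFrame:
    path = Path(data_dir) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.csv in {data_dir}")
    return pd.read_csv(path)


def load_dataset(data_dir: str | Path
                 ) -> tuple[list[ImageTriplet], list[ImageTriplet]]:
    """Read a generated dataset directory into (train, test) triplet lists."""
    data_dir = Path(data_dir)
    manifest = load_manifest(data_dir)
    train, test = [], []
    for _, row in manifest.iterrows():
        (train if row["split"] == "train" else test).append(
            read_triplet(row, data_dir))
    return train, test


def save_checkpoint(model, path: str | Path) -> None:
    """Write parameters + batch-norm statistics as a compressed .npz."""
    np.savez_compressed(path, **model.state_dict())


def load_checkpoint(model, path: str | Path) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
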