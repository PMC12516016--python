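"""Dataset folder reading, image loading and run configuration.

Datasets use the class-folder convention: a root directory containing
``fracture/`` (label 1) and ``non_fracture/`` (label 0) image folders.
Files that cannot be decoded are skipped with a logged warning.  Run
configuration round-trips losslessly through YAML; unknown keys are
rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize

from fracband.evaluation import SplitSpec
from fracband.model import BranchConfig, DecompositionConfig, TrainConfig

__all__ = ["LabelledImageSet", "RunConfig", "load_dataset", "load_image"]

logger = logging.getLogger("fracband")

CLASS_FOLDERS = {"fracture": 1, "non_fracture": 0}
IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass
class LabelledImageSet:
    images: np.ndarray          # (n, H, W, 3) floats in [0, 1]
    labels: np.ndarray          # (n,) ints, 1 = fracture
    paths: list[Path] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)


def load_image(path: str | Path, size: int = 128) -> np.ndarray:
    """Decode a PNG/JPEG into a (size, size, 3) float array in [0, 1].

    Grayscale inputs are replicated to three channels; resizing is
    bilinear with anti-aliasing.
    """
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=float) / 255.0
    if arr.shape[:2] != (size, size):
        arr = resize(arr, (size, size), order=1, anti_aliasing=True, preserve_range=True)
    return arr


def load_dataset(root: str | Path, size: int = 128) -> LabelledImageSet:
    """Read every decodable image under the class folders.

    Undecodable files are excluded with a warning (mirroring the manual
    exclusion of unreadable files during dataset preparation); an absent
    or empty class folder raises an error naming the folder.
    """
    root = Path(root)
    folders = {name: root / name for name in CLASS_FOLDERS}
    missing = [str(p) for p in folders.values() if not p.is_dir()]
    if missing:
        raise ValueError(f"dataset root {root} is missing class folders: {missing}")
    images, labels, paths = [], [], []
    for name, folder in folders.items():
        files = sorted(p for p in folder.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        count = 0
        for path in files:
            try:
                arr = load_image(path, size=size)
            except (OSError, UnidentifiedImageError, ValueError) as exc:
                logger.warning("skipping undecodable image %s: %s", path, exc)
                continue
            images.append(arr)
            labels.append(CLASS_FOLDERS[name])
            paths.append(path)
            count += 1
        if count == 0:
            raise ValueError(f"class folder {folder} contains no decodable images")
    return LabelledImageSet(images=np.stack(images), labels=np.array(labels, dtype=int),
                            paths=paths)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Complete experiment description; every ablation axis (decomposition
    method, wavelet family, backbone, subband subset) is a config field."""

    data_root: str = ""
    output_dir: str = "runs/run"
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    branch: BranchConfig = field(default_factory=BranchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "data_root": self.data_root,
            "output_dir": self.output_dir,
            "decomposition": dataclasses.asdict(self.decomposition),
            "branch": {
                "backbone_id": self.branch.backbone_id,
                "frozen": self.branch.frozen,
                "dense_units": list(self.branch.dense_units),
                "dropout_rates": list(self.branch.dropout_rates),
            },
            "train": {
                "learning_rate": self.train.learning_rate,
                "batch_size": self.train.batch_size,
                "max_epochs": self.train.max_epochs,
                "early_stop_patience": self.train.early_stop_patience,
                "optimiser": self.train.optimiser,
                "seed": self.train.seed,
                "subbands": list(self.train.subbands),
            },
            "split": dataclasses.asdict(self.split),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key in ("data_root", "output_dir", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        if "decomposition" in data:
            kwargs["decomposition"] = _from_mapping(DecompositionConfig,
                                                    data["decomposition"], "decomposition")
        if "branch" in data:
            branch = dict(data["branch"])
            for key in ("dense_units", "dropout_rates"):
                if key in branch:
                    branch[key] = tuple(branch[key])
            kwargs["branch"] = _from_mapping(BranchConfig, branch, "branch")
        if "train" in data:
            train = dict(data["train"])
            if "subbands" in train:
                train["subbands"] = tuple(train["subbands"])
            kwargs["train"] = _from_mapping(TrainConfig, train, "train")
        if "split" in data:
            kwargs["split"] = _from_mapping(SplitSpec, data["split"], "split")
        return cls(**kwargs)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
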