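"""Multiband classifier: one frozen-backbone scoring branch per subband,
probability-vector fusion, end-to-end training of the trainable heads.

Each branch maps one full-size subband image tensor through a frozen
convolutional backbone, a flatten layer and two dense / batch-norm /
dropout blocks to a sigmoid score.  The per-subband scores are
concatenated in the fixed order (LL, LH, HL, HH) restricted to the
configured subset, passed through a 128-unit ReLU dense layer and a
final sigmoid, and trained with a single binary cross-entropy loss using
Adam and early stopping on validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from fracband import nn
from fracband.backbones import Backbone, create_backbone
from fracband.decomposition import BAND_ORDER, decompose
from fracband.nn import Adam, bce_grad, bce_loss

__all__ = [
    "Branch",
    "BranchConfig",
    "DecompositionConfig",
    "FractureClassifier",
    "TrainConfig",
    "assemble_model",
    "bce_loss",
    "build_branch",
    "preprocess_band",
]

INPUT_SIZE = 128
FUSION_UNITS = 128
_FEATURE_BATCH = 16  # images per backbone forward chunk (memory bound)


@dataclass
class BranchConfig:
    """Configuration of one per-subband scoring branch."""

    backbone_id: str = "efficientnetv2b2"
    frozen: bool = True
    dense_units: tuple[int, int] = (256, 128)
    dropout_rates: tuple[float, float] = (0.3, 0.3)

    def __post_init__(self) -> None:
        self.dense_units = tuple(int(u) for u in self.dense_units)
        self.dropout_rates = tuple(float(r) for r in self.dropout_rates)
        if len(self.dense_units) != 2 or any(u <= 0 for u in self.dense_units):
            raise ValueError("dense_units must be two positive integers")
        if len(self.dropout_rates) != 2 or any(not 0 <= r < 1 for r in self.dropout_rates):
            raise ValueError("dropout_rates must be two reals in [0, 1)")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 50
    early_stop_patience: int = 5
    optimiser: str = "adam"
    seed: int = 0
    subbands: tuple[str, ...] = BAND_ORDER

    def __post_init__(self) -> None:
        self.subbands = tuple(self.subbands)
        unknown = set(self.subbands) - set(BAND_ORDER)
        if unknown:
            raise ValueError(f"unknown subbands {sorted(unknown)}; valid: {BAND_ORDER}")
        if not self.subbands:
            raise ValueError("subband subset must be nonempty")
        # canonical fixed order regardless of how the subset was written
        self.subbands = tuple(b for b in BAND_ORDER if b in self.subbands)
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be < max_epochs")
        if self.optimiser.lower() != "adam":
            raise ValueError(f"unsupported optimiser {self.optimiser!r}")


@dataclass
class DecompositionConfig:
    method: str = "dwt2"
    wavelet: str = "haar"
    grouping: list | None = None


def preprocess_band(images: np.ndarray) -> np.ndarray:
    """Rescale each image of one subband batch to [0, 1] by per-image
    min-max (signed detail bands included); zero-range images map to 0."""
    x = np.asarray(images, dtype=np.float64)
    lo = x.min(axis=(1, 2, 3), keepdims=True)
    hi = x.max(axis=(1, 2, 3), keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0
    out = (x - lo) / span
    out[(hi == lo).ravel()] = 0.0
    return out


def _build_head(feature_shape: tuple[int, int, int], config: BranchConfig,
                rng: np.random.Generator) -> nn.Sequential:
    flat = int(np.prod(feature_shape))
    u1, u2 = config.dense_units
    d1, d2 = config.dropout_rates
    return nn.Sequential([
        nn.Flatten(),
        nn.Dense(flat, u1, rng), nn.BatchNorm1d(u1), nn.ReLU(), nn.Dropout(d1, rng),
        nn.Dense(u1, u2, rng), nn.BatchNorm1d(u2), nn.ReLU(), nn.Dropout(d2, rng),
        nn.Dense(u2, 1, rng), nn.Sigmoid(),
    ])


class Branch:
    """Frozen backbone + trainable head scoring one subband tensor."""

    def __init__(self, config: BranchConfig, backbone: Backbone, head: nn.Sequential):
        if not config.frozen:
            raise NotImplementedError("backbone fine-tuning is not supported; set frozen=True")
        self.config = config
        self.backbone = backbone
        self.head = head

    def features(self, images: np.ndarray) -> np.ndarray:
        """Frozen feature maps for a (n, H, W, 3) batch, chunked for memory."""
        chunks = [
            self.backbone.features(images[i:i + _FEATURE_BATCH])
            for i in range(0, len(images), _FEATURE_BATCH)
        ]
        return np.concatenate(chunks, axis=0)

    def score(self, images: np.ndarray) -> np.ndarray:
        """Sigmoid scores in (0, 1) for raw subband image tensors."""
        feats = self.features(preprocess_band(images))
        return self.head.forward(feats, training=False).ravel()


def build_branch(config: BranchConfig, input_shape: tuple[int, int, int] = (INPUT_SIZE, INPUT_SIZE, 3),
                 seed: int = 0, backbone: Backbone | None = None) -> Branch:
    """Construct one scoring branch for the given input shape."""
    if tuple(input_shape[:2]) != (INPUT_SIZE, INPUT_SIZE) or input_shape[2] != 3:
        raise ValueError(f"branch input shape must be {(INPUT_SIZE, INPUT_SIZE, 3)}, got {input_shape}")
    backbone = backbone or create_backbone(config.backbone_id, seed=seed)
    rng = np.random.default_rng(seed)
    head = _build_head(backbone.feature_shape(input_shape[:2]), config, rng)
    return Branch(config, backbone, head)


def _layer_states(seq: nn.Sequential) -> list[np.ndarray]:
    arrays = list(seq.parameters())
    for layer in seq.layers:
        if isinstance(layer, nn.BatchNorm1d):
            arrays.extend([layer.running_mean, layer.running_var])
    return arrays


class FractureClassifier:
    """Assembled multiband model: SubbandImageSet batch -> score in (0, 1)."""

    def __init__(self, branches: dict[str, Branch], train_config: TrainConfig,
                 decomposition: DecompositionConfig | None = None, seed: int = 0):
        if not branches:
            raise ValueError("at least one branch is required")
        if set(branches) != set(train_config.subbands):
            raise ValueError(
                f"branches {sorted(branches)} do not match configured subbands {train_config.subbands}"
            )
        self.subbands = train_config.subbands  # fixed canonical order
        self.branches = {band: branches[band] for band in self.subbands}
        self.train_config = train_config
        self.decomposition = decomposition or DecompositionConfig()
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF510]))
        self.fusion = nn.Sequential([
            nn.Dense(len(self.subbands), FUSION_UNITS, rng), nn.ReLU(),
            nn.Dense(FUSION_UNITS, 1, rng), nn.Sigmoid(),
        ])
        self.history: dict[str, list[float]] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def create(cls, branch_config: BranchConfig | None = None,
               train_config: TrainConfig | None = None,
               decomposition: DecompositionConfig | None = None,
               seed: int = 0) -> "FractureClassifier":
        branch_config = branch_config or BranchConfig()
        train_config = train_config or TrainConfig(seed=seed)
        backbone = create_backbone(branch_config.backbone_id, seed=seed)  # shared, frozen
        branches = {}
        for i, band in enumerate(train_config.subbands):
            rng_seed = np.random.SeedSequence([seed, 1 + i])
            rng = np.random.default_rng(rng_seed)
            head = _build_head(backbone.feature_shape((INPUT_SIZE, INPUT_SIZE)), branch_config, rng)
            branches[band] = Branch(branch_config, backbone, head)
        return cls(branches, train_config, decomposition, seed=seed)

    # -- data plumbing ----------------------------------------------------

    def subband_tensors(self, images: np.ndarray) -> dict[str, np.ndarray]:
        """Decompose a (n, H, W, 3) image batch into per-band preprocessed
        (n, H, W, 3) batches, restricted to the configured subset."""
        images = np.asarray(images, dtype=np.float64)
        per_band = {band: [] for band in self.subbands}
        for img in images:
            sset = decompose(img, method=self.decomposition.method,
                             wavelet=self.decomposition.wavelet,
                             grouping=self.decomposition.grouping)
            for band in self.subbands:
                per_band[band].append(sset[band])
        return {band: preprocess_band(np.stack(stack)) for band, stack in per_band.items()}

    def band_features(self, images: np.ndarray) -> dict[str, np.ndarray]:
        tensors = self.subband_tensors(images)
        return {band: self.branches[band].features(tensors[band]).astype(np.float32)
                for band in self.subbands}

    # -- forward / backward ----------------------------------------------

    def _forward_features(self, feats: dict[str, np.ndarray], training: bool
                          ) -> tuple[np.ndarray, np.ndarray]:
        scores = [
            self.branches[band].head.forward(feats[band].astype(np.float64), training=training)
            for band in self.subbands
        ]
        p_vec = np.concatenate(scores, axis=1)  # (n, n_bands), order (LL, LH, HL, HH)
        y_hat = self.fusion.forward(p_vec, training=training).ravel()
        return p_vec, y_hat

    def _backward(self, d_yhat: np.ndarray) -> dict[str, np.ndarray]:
        d_p = self.fusion.backward(d_yhat.reshape(-1, 1))
        return {
            band: self.branches[band].head.backward(d_p[:, [j]])
            for j, band in enumerate(self.subbands)
        }

    def probability_vector(self, image: np.ndarray) -> np.ndarray:
        """Per-subband sigmoid scores of one image, fixed band order."""
        feats = self.band_features(image[None])
        p_vec, _ = self._forward_features(feats, training=False)
        return p_vec[0]

    # -- training ---------------------------------------------------------

    def _trainable_sequences(self) -> list[nn.Sequential]:
        return [self.branches[band].head for band in self.subbands] + [self.fusion]

    def fit(self, train_images: np.ndarray, train_labels: np.ndarray,
            val_images: np.ndarray, val_labels: np.ndarray) -> dict[str, list[float]]:
        """Train heads and fusion with Adam + early stopping; backbones stay
        frozen.  Returns the per-epoch history and restores the weights of
        the best validation-accuracy epoch."""
        y_tr = np.asarray(train_labels, dtype=float).ravel()
        y_val = np.asarray(val_labels, dtype=float).ravel()
        if y_tr.size == 0 or y_val.size == 0:
            raise ValueError("training and validation sets must be nonempty")
        for y in (y_tr, y_val):
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError("labels must be binary (0/1)")

        cfg = self.train_config
        feats_tr = self.band_features(train_images)
        feats_val = self.band_features(val_images)

        seqs = self._trainable_sequences()
        params = [p for s in seqs for p in s.parameters()]
        grads = [g for s in seqs for g in s.gradients()]
        optimiser = Adam(params, grads, lr=cfg.learning_rate)
        shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5A]))

        state_arrays = [a for s in seqs for a in _layer_states(s)]
        best_state = [a.copy() for a in state_arrays]
        best_val_acc, best_val_loss, best_epoch = -np.inf, np.inf, 0
        history = {k: [] for k in ("loss", "accuracy", "val_loss", "val_accuracy")}

        n = y_tr.size
        for epoch in range(1, cfg.max_epochs + 1):
            order = shuffle_rng.permutation(n)
            batch_losses, batch_hits, seen = [], 0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = {band: feats_tr[band][idx] for band in self.subbands}
                yb = y_tr[idx]
                _, y_hat = self._forward_features(batch, training=True)
                batch_losses.append(bce_loss(yb, y_hat) * len(idx))
                batch_hits += int(np.sum((y_hat >= 0.5) == (yb == 1.0)))
                seen += len(idx)
                self._backward(bce_grad(yb, y_hat))
                optimiser.step()

            _, y_hat_val = self._forward_features(feats_val, training=False)
            val_loss = bce_loss(y_val, y_hat_val)
            val_acc = float(np.mean((y_hat_val >= 0.5) == (y_val == 1.0)))
            history["loss"].append(sum(batch_losses) / seen)
            history["accuracy"].append(batch_hits / seen)
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(val_acc)

            if val_acc > best_val_acc:
                # strict improvement resets the early-stopping counter
                best_val_acc, best_val_loss, best_epoch = val_acc, val_loss, epoch
                best_state = [a.copy() for a in state_arrays]
            else:
                if val_acc == best_val_acc and val_loss < best_val_loss:
                    # tie on accuracy: keep the better-calibrated weights
                    best_val_loss = val_loss
                    best_state = [a.copy() for a in state_arrays]
                if epoch - best_epoch >= cfg.early_stop_patience:
                    break

        for live, saved in zip(state_arrays, best_state):
            live[...] = saved
        self.history = history
        return history

    # -- inference --------------------------------------------------------

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        feats = self.band_features(np.asarray(images))
        _, y_hat = self._forward_features(feats, training=False)
        return y_hat

    def predict(self, images: np.ndarray, threshold: float = 0.5
                ) -> tuple[np.ndarray, np.ndarray]:
        """Labels (1 = fracture iff probability >= threshold) + raw scores."""
        probs = self.predict_proba(images)
        return (probs >= threshold).astype(int), probs

    # -- persistence ------------------------------------------------------

    def save(self, run_dir: str | Path) -> None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for band in self.subbands:
            for i, a in enumerate(_layer_states(self.branches[band].head)):
                arrays[f"head_{band}_{i}"] = a
        for i, a in enumerate(_layer_states(self.fusion)):
            arrays[f"fusion_{i}"] = a
        np.savez(run_dir / "weights.npz", **arrays)
        bc = next(iter(self.branches.values())).config
        sidecar = {
            "branch": {
                "backbone_id": bc.backbone_id,
                "frozen": bc.frozen,
                "dense_units": list(bc.dense_units),
                "dropout_rates": list(bc.dropout_rates),
            },
            "train": {
                "learning_rate": self.train_config.learning_rate,
                "batch_size": self.train_config.batch_size,
                "max_epochs": self.train_config.max_epochs,
                "early_stop_patience": self.train_config.early_stop_patience,
                "optimiser": self.train_config.optimiser,
                "seed": self.train_config.seed,
                "subbands": list(self.train_config.subbands),
            },
            "decomposition": {
                "method": self.decomposition.method,
                "wavelet": self.decomposition.wavelet,
                "grouping": self.decomposition.grouping,
            },
            "seed": self.seed,
        }
        (run_dir / "model.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))

    @classmethod
    def load(cls, run_dir: str | Path) -> "FractureClassifier":
        run_dir = Path(run_dir)
        sidecar = yaml.safe_load((run_dir / "model.yaml").read_text())
        model = cls.create(
            branch_config=BranchConfig(
                backbone_id=sidecar["branch"]["backbone_id"],
                frozen=sidecar["branch"]["frozen"],
                dense_units=tuple(sidecar["branch"]["dense_units"]),
                dropout_rates=tuple(sidecar["branch"]["dropout_rates"]),
            ),
            train_config=TrainConfig(**sidecar["train"]),
            decomposition=DecompositionConfig(**sidecar["decomposition"]),
            seed=sidecar["seed"],
        )
        with np.load(run_dir / "weights.npz") as arrays:
            for band in model.subbands:
                for i, a in enumerate(_layer_states(model.branches[band].head)):
                    a[...] = arrays[f"head_{band}_{i}"]
            for i, a in enumerate(_layer_states(model.fusion)):
                a[...] = arrays[f"fusion_{i}"]
        return model


def assemble_model(branches: dict[str, Branch], train_config: TrainConfig | None = None,
                   decomposition: DecompositionConfig | None = None,
                   seed: int = 0) -> FractureClassifier:
    """Assemble a classifier from pre-built branches; the probability vector
    follows the fixed band order restricted to the given branches."""
    subset = tuple(b for b in BAND_ORDER if b in branches)
    train_config = train_config or TrainConfig(seed=seed, subbands=subset)
    return FractureClassifier(branches, train_config, decomposition, seed=seed)
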