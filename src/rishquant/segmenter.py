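"""Double U-Net segmentation estimator (one binary model per chromogen).

``DoubleUNetSegmenter`` follows the scikit-learn estimator contract:
hyperparameters in ``__init__``, learned state in trailing-underscore
attributes set by ``fit``, ``get_params``/``set_params`` inherited from
``BaseEstimator``. Training minimizes the dice loss of the final sigmoid
map with Adam on an internal seeded train/test split (80/20 by default);
the held-out metrics land in ``report_``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import SegMetrics, evaluate_batch
from .nn import Adam, DoubleUNet, dice_loss, dice_loss_grad
from .postprocess import MorphConfig, binarize
from .preprocess import PreprocessConfig, extract_patches, preprocess_field, stitch_patches

__all__ = ["DoubleUNetSegmenter", "TrainReport", "CHANNELS"]

CHANNELS = ("blue_WT", "red_TR")


@dataclass
class TrainReport:
    """Per-epoch losses and final held-out metrics of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    test_metrics: SegMetrics | None = None
    test_metrics_macro: dict | None = None
    config: dict = field(default_factory=dict)
    wall_seconds: float = 0.0
    n_train: int = 0
    n_test: int = 0

    def as_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "test_metrics": self.test_metrics.as_dict() if self.test_metrics else None,
            "test_metrics_macro": self.test_metrics_macro,
            "config": self.config,
            "wall_seconds": self.wall_seconds,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


class DoubleUNetSegmenter(BaseEstimator):
    """Patch-based binary dot segmentation with a stacked Double U-Net.

    Parameters
    ----------
    channel:
        Which chromogen this model segments: ``"blue_WT"`` (HRP,
        wild-type) or ``"red_TR"`` (AP, truncated).
    depth, base_filters:
        Encoder levels and first-level filter count of each U-Net.
    learning_rate, epochs, batch_size:
        Adam settings; the loss is the dice loss of the final output.
    train_fraction:
        Seeded random fraction of patches used for training; the
        remainder is the held-out test split reported in ``report_``.
    dice_smooth:
        Smoothing epsilon of the dice loss.
    bridge:
        How U-Net 2 receives U-Net 1's map: ``"multiply"`` (input times
        probability, the canonical stacked form) or ``"concat"``.
    """

    def __init__(
        self,
        channel: str = "blue_WT",
        depth: int = 3,
        base_filters: int = 16,
        learning_rate: float = 0.001,
        epochs: int = 50,
        batch_size: int = 32,
        train_fraction: float = 0.8,
        dice_smooth: float = 1.0,
        bridge: str = "multiply",
        patch_size: int = 64,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.channel = channel
        self.depth = depth
        self.base_filters = base_filters
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.train_fraction = train_fraction
        self.dice_smooth = dice_smooth
        self.bridge = bridge
        self.patch_size = patch_size
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.patch_size % 2**self.depth:
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by "
                f"2^depth = {2**self.depth}: max-pooling cannot halve evenly"
            )

    def _build(self) -> DoubleUNet:
        self._validate()
        return DoubleUNet(
            in_channels=3,
            depth=self.depth,
            base_filters=self.base_filters,
            bridge=self.bridge,
            seed=self.seed,
        )

    @staticmethod
    def _check_xy(X: np.ndarray, y: np.ndarray | None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n_patches, ps, ps, 3)")
        if X.min() < 0 or X.max() > 1.0 + 1e-6:
            raise ValueError("patches must be preprocessed to [0, 1]")
        if y is None:
            return X, None
        y = np.asarray(y, dtype=np.float32)
        if y.ndim == 4 and y.shape[-1] == 1:
            y = y[..., 0]
        if y.shape != X.shape[:3]:
            raise ValueError("y must be (n_patches, ps, ps) masks matching X")
        if not np.all(np.isin(np.unique(y), (0.0, 1.0))):
            raise ValueError("masks must be binary")
        return X, y[..., None]

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "DoubleUNetSegmenter":
        """Train on preprocessed patches X (n, ps, ps, 3) and masks y."""
        t0 = time.time()
        X, y = self._check_xy(X, y)
        n = X.shape[0]
        if n < 2:
            raise ValueError("need at least 2 patches to split and train")
        self.net_ = self._build()
        opt = Adam(self.net_.layers(), self.learning_rate)

        split_rng = np.random.default_rng((self.seed, 17))
        perm = split_rng.permutation(n)
        n_train = max(1, int(round(n * self.train_fraction)))
        n_train = min(n_train, n - 1)
        self.train_idx_, self.test_idx_ = perm[:n_train], perm[n_train:]
        Xtr, ytr = X[self.train_idx_], y[self.train_idx_]
        Xte, yte = X[self.test_idx_], y[self.test_idx_]
        if ytr.sum() == 0:
            import warnings

            warnings.warn("training split contains no foreground pixels")

        report = TrainReport(config=self.get_params(), n_train=n_train, n_test=n - n_train)
        shuffle_rng = np.random.default_rng((self.seed, 29))
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n_train)
            losses = []
            for start in range(0, n_train, self.batch_size):
                sel = order[start : start + self.batch_size]
                xb, yb = Xtr[sel], ytr[sel]
                p = self.net_.forward(xb, train=True)
                losses.append(dice_loss(p, yb, eps=self.dice_smooth))
                self.net_.backward(dice_loss_grad(p, yb, eps=self.dice_smooth))
                opt.step()
            report.train_loss.append(float(np.mean(losses)))
            pv = self._forward_batched(Xte)
            report.val_loss.append(dice_loss(pv, yte, eps=self.dice_smooth))
            if self.verbose:
                print(
                    f"[{self.channel}] epoch {epoch + 1}/{self.epochs} "
                    f"train dice loss {report.train_loss[-1]:.4f} "
                    f"val dice loss {report.val_loss[-1]:.4f}"
                )

        cfg = MorphConfig()
        preds = binarize(self._forward_batched(Xte)[..., 0], cfg)
        ev = evaluate_batch(list(zip(preds, yte[..., 0].astype(np.uint8))))
        report.test_metrics = ev["micro"]
        report.test_metrics_macro = ev["macro"]
        report.wall_seconds = time.time() - t0
        self.report_ = report
        return self

    # ------------------------------------------------------------------
    def _forward_batched(self, X: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [
            self.net_.forward(X[i : i + batch], train=False)
            for i in range(0, X.shape[0], batch)
        ]
        return np.concatenate(out, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probabilities for patches X."""
        self._require_fitted()
        X, _ = self._check_xy(X, None)
        return self._forward_batched(X)[..., 0]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Binary masks for patches X at the given threshold."""
        return (self.predict_proba(X) >= threshold).astype(np.uint8)

    def predict_field(
        self, image: np.ndarray, cfg: PreprocessConfig | None = None
    ) -> np.ndarray:
        """Whole-field probability map: preprocess, tile, infer, stitch.

        ``image`` is a raw (H, W, 3) micrograph; the output spans the
        original field exactly.
        """
        self._require_fitted()
        cfg = cfg or PreprocessConfig(patch_size=self.patch_size)
        if cfg.patch_size != self.patch_size:
            raise ValueError("preprocess patch_size differs from the model's")
        pre = preprocess_field(image, cfg)
        grid = extract_patches(pre, cfg)
        probs = self._forward_batched(np.asarray(grid.patches, dtype=np.float32))
        prob_grid = type(grid)(
            patches=probs[..., 0],
            origins=grid.origins,
            padded_shape=grid.padded_shape,
            original_shape=grid.original_shape,
            patch_size=grid.patch_size,
            pad_mode=grid.pad_mode,
        )
        return stitch_patches(prob_grid)

    def _require_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted; call fit() or load()")

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar echoing the config."""
        self._require_fitted()
        path = Path(path)
        with open(path, "wb") as fh:  # keep the exact filename (no .npz suffixing)
            np.savez(fh, **self.net_.state_arrays())
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = {
            "params": self.get_params(),
            "report": self.report_.as_dict() if hasattr(self, "report_") else None,
        }
        sidecar.write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def load(cls, path: str | Path) -> "DoubleUNetSegmenter":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        est = cls(**meta["params"])
        est.net_ = est._build()
        with np.load(path) as state:
            est.net_.load_state_arrays(dict(state))
        return est
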