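"""Patch-level tumor segmentation.

Two predictors share one interface:

* :class:`UNetSegmenter` — a compact fully-convolutional U-shaped
  encoder–decoder (skip connections, 2-class softmax head) written in plain
  numpy with manual backpropagation, trained from scratch with softmax
  cross-entropy, batch size 32 and an initial learning rate of 0.01 under
  exponential decay. Because the network is fully convolutional, training
  patches and inference tiles may have different sizes.
* :class:`OracleSegmenter` — returns the ground-truth lesion mask of a
  synthetic slide as probabilities, degraded by Gaussian noise and by
  flipping a fraction of connected components to negative (emulating the
  false negatives of a trained model), so downstream stages can be tested
  independently of training quality.

The network is deliberately small (4 resolution levels, 8 base channels by
default) so CPU training on synthetic patches finishes in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from skimage.measure import label as cc_label
from sklearn.base import BaseEstimator

from .synthetic import SlideRecord

__all__ = [
    "SegTrainConfig",
    "UNetSegmenter",
    "OracleSegmenter",
    "train_segmenter",
    "predict_tiles",
    "oracle_segmenter",
]


@dataclass(frozen=True)
class SegTrainConfig:
    """Training hyperparameters (softmax cross-entropy loss is fixed)."""

    batch_size: int = 32
    initial_lr: float = 0.01
    lr_decay_rate: float = 0.94
    lr_decay_steps: int = 1000
    max_epochs: int = 20
    patience: int = 5
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.initial_lr > 0:
            raise ValueError("initial_lr must be positive")
        if not 0 < self.lr_decay_rate <= 1:
            raise ValueError("lr_decay_rate must lie in (0, 1]")


# ---------------------------------------------------------------- layers ----


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """3x3 (or 1x1) same-padding convolution via im2col. Returns (out, cols)."""
    n, c, h, w = x.shape
    cout, cin, k, _ = W.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = sliding_window_view(x, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
    cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)
    out = cols @ W.reshape(cout, -1).T + b
    return out.reshape(n, h, w, cout).transpose(0, 3, 1, 2), cols


class _Conv:
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.W = (rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out, cols = _conv_forward(x, self.W, self.b)
        if train:
            self._cols, self._in_shape = cols, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, cout, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        self.dW = (dflat.T @ self._cols).reshape(self.W.shape)
        self.db = dflat.sum(axis=0)
        self._cols = None
        # input gradient = convolution of dout with the transposed, flipped kernel
        Wt = np.ascontiguousarray(self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dx, _ = _conv_forward(dout, Wt, np.zeros(Wt.shape[0], dtype=np.float32))
        return dx

    def step(self, lr: float, momentum: float = 0.9):
        self.vW = momentum * self.vW - lr * self.dW
        self.vb = momentum * self.vb - lr * self.db
        self.W += self.vW
        self.b += self.vb


class _ReLU:
    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class _MaxPool2:
    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dxr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


def _upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _downsum2(d):
    n, c, h, w = d.shape
    return d.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


# ----------------------------------------------------------------- U-Net ----


class _UNet:
    """Minimal U-shaped network: per level a double 3x3 conv block, 2x2 max
    pooling down, nearest-neighbor upsampling + 3x3 conv and skip
    concatenation up, 1x1 two-class head."""

    def __init__(self, in_channels: int, base_channels: int, depth: int, rng):
        self.depth = depth
        ch = [base_channels * 2**i for i in range(depth)]
        self.enc = []
        cin = in_channels
        for c in ch:
            self.enc.append(
                [_Conv(cin, c, 3, rng), _ReLU(), _Conv(c, c, 3, rng), _ReLU()]
            )
            cin = c
        self.pools = [_MaxPool2() for _ in range(depth - 1)]
        self.up_convs = []  # channel-halving conv after upsampling
        self.dec = []
        for i in range(depth - 2, -1, -1):
            self.up_convs.append([_Conv(ch[i + 1], ch[i], 3, rng), _ReLU()])
            self.dec.append(
                [_Conv(2 * ch[i], ch[i], 3, rng), _ReLU(), _Conv(ch[i], ch[i], 3, rng), _ReLU()]
            )
        self.head = _Conv(ch[0], 2, 1, rng)

    def _block(self, layers, x, train):
        for layer in layers:
            x = layer.forward(x, train)
        return x

    def _block_back(self, layers, d):
        for layer in reversed(layers):
            d = layer.backward(d)
        return d

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for i, block in enumerate(self.enc):
            x = self._block(block, x, train)
            if i < self.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for j, (up, dec) in enumerate(zip(self.up_convs, self.dec)):
            x = self._block(up, _upsample2(x), train)
            x = np.concatenate([skips[-1 - j], x], axis=1)
            x = self._block(dec, x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray):
        d = self.head.backward(dlogits)
        # decoder stages were applied deepest-first, so walk them in reverse;
        # dskips[i] ends up holding the gradient flowing into encoder level i
        dskips = []
        for j in range(len(self.dec) - 1, -1, -1):
            d = self._block_back(self.dec[j], d)
            c_skip = self._skip_channels[-1 - j]
            dskips.append(d[:, :c_skip])
            d = _downsum2(self._block_back(self.up_convs[j], d[:, c_skip:]))
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                d = self.pools[i].backward(d) + dskips[i]
            d = self._block_back(self.enc[i], d)

    def convs(self) -> list[_Conv]:
        out = []
        for block in self.enc + self.up_convs + self.dec:
            out += [l for l in block if isinstance(l, _Conv)]
        return out + [self.head]

    def step(self, lr: float):
        for conv in self.convs():
            conv.step(lr)


def _softmax_ce(logits: np.ndarray, targets: np.ndarray):
    """Mean per-pixel softmax cross-entropy and its logits gradient."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sm = ez / ez.sum(axis=1, keepdims=True)
    n_pix = targets.size
    t = targets.astype(np.int64)
    picked = np.take_along_axis(sm, t[:, None], axis=1)[:, 0]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    dlogits = sm.copy()
    np.put_along_axis(
        dlogits, t[:, None], np.take_along_axis(dlogits, t[:, None], axis=1) - 1.0, axis=1
    )
    return loss, (dlogits / n_pix).astype(np.float32)


class UNetSegmenter(BaseEstimator):
    """Trainable patch segmenter with pixel-mask supervision.

    Parameters mirror :class:`SegTrainConfig`; ``base_channels`` and ``depth``
    size the network. Fitted attributes: ``net_``, ``history_`` (epoch,
    train_loss, val_loss) and ``n_steps_``.
    """

    def __init__(
        self,
        base_channels: int = 8,
        depth: int = 4,
        batch_size: int = 32,
        initial_lr: float = 0.01,
        lr_decay_rate: float = 0.94,
        lr_decay_steps: int = 1000,
        max_epochs: int = 20,
        patience: int = 5,
        val_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.base_channels = base_channels
        self.depth = depth
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.lr_decay_rate = lr_decay_rate
        self.lr_decay_steps = lr_decay_steps
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- helpers -------------------------------------------------------

    def _validate_size(self, h: int, w: int):
        m = 2 ** (self.depth - 1)
        if h % m or w % m:
            raise ValueError(
                f"tile size {h}x{w} not divisible by {m} (2**(depth-1)); "
                "pad or choose a compatible size"
            )

    @staticmethod
    def _to_nchw(images) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("expected images of shape (n, h, w, 3)")
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        # center and rescale so stained pixels sit near zero mean, unit-ish sd
        x = (x - 0.5) / 0.25
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=np.float32)

    # -- sklearn-style surface ------------------------------------------

    def fit(self, X, y):
        """Train on patches ``X`` (n, h, w, 3) with pixel masks ``y`` (n, h, w)."""
        # validate through the config object so bad values fail identically
        cfg = SegTrainConfig(
            batch_size=self.batch_size,
            initial_lr=self.initial_lr,
            lr_decay_rate=self.lr_decay_rate,
            lr_decay_steps=self.lr_decay_steps,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.random_state,
        )
        x = self._to_nchw(X)
        t = np.asarray(y).astype(np.int64)
        if t.shape != x.shape[:1] + x.shape[2:]:
            raise ValueError("masks must match patch dimensions")
        if np.unique(t).size < 2:
            raise ValueError("training patches contain a single class; both required")
        self._validate_size(x.shape[2], x.shape[3])

        rng = np.random.default_rng(cfg.seed)
        self.net_ = _UNet(3, self.base_channels, self.depth, rng)

        n = x.shape[0]
        order = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        if train_idx.size == 0:
            train_idx, val_idx = order, order[:0]

        history = []
        best_val = np.inf
        best_weights = None
        bad_epochs = 0
        self.n_steps_ = 0
        for epoch in range(cfg.max_epochs):
            train_idx = rng.permutation(train_idx)
            losses = []
            for start in range(0, train_idx.size, cfg.batch_size):
                batch = train_idx[start : start + cfg.batch_size]
                logits = self.net_.forward(x[batch], train=True)
                loss, dlogits = _softmax_ce(logits, t[batch])
                self.net_.backward(dlogits)
                lr = cfg.initial_lr * cfg.lr_decay_rate ** (
                    self.n_steps_ / cfg.lr_decay_steps
                )
                self.net_.step(lr)
                self.n_steps_ += 1
                losses.append(loss)
            if val_idx.size:
                val_loss = self._eval_loss(x[val_idx], t[val_idx], cfg.batch_size)
            else:
                val_loss = float(np.mean(losses))
            history.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = [(c.W.copy(), c.b.copy()) for c in self.net_.convs()]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > cfg.patience:
                    break
        if best_weights is not None:
            for conv, (W, b) in zip(self.net_.convs(), best_weights):
                conv.W, conv.b = W, b
        self.history_ = pd.DataFrame(history)
        return self

    def _eval_loss(self, x, t, batch_size) -> float:
        losses, weights = [], []
        for start in range(0, x.shape[0], batch_size):
            logits = self.net_.forward(x[start : start + batch_size], train=False)
            loss, _ = _softmax_ce(logits, t[start : start + batch_size])
            losses.append(loss)
            weights.append(min(batch_size, x.shape[0] - start))
        return float(np.average(losses, weights=weights))

    def predict_proba(self, tiles) -> np.ndarray:
        """Tumor-class probability rasters, one per input tile (n, h, w)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("segmenter is not fitted")
        x = self._to_nchw(tiles)
        self._validate_size(x.shape[2], x.shape[3])
        out = []
        for i in range(x.shape[0]):
            logits = self.net_.forward(x[i : i + 1], train=False)
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            out.append((ez[:, 1] / ez.sum(axis=1))[0])
        return np.asarray(out, dtype=np.float64)

    def score(self, X, y) -> float:
        """Pixel accuracy."""
        probs = self.predict_proba(X)
        return float(((probs >= 0.5) == np.asarray(y).astype(bool)).mean())

    # -- persistence ----------------------------------------------------

    def save(self, directory: str | Path):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = self.get_params()
        (d / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
        arrays = {}
        for i, conv in enumerate(self.net_.convs()):
            arrays[f"W{i}"] = conv.W
            arrays[f"b{i}"] = conv.b
        np.savez(d / "weights.npz", **arrays)
        if hasattr(self, "history_"):
            self.history_.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "UNetSegmenter":
        d = Path(directory)
        model = cls(**json.loads((d / "config.json").read_text()))
        model.net_ = _UNet(3, model.base_channels, model.depth, np.random.default_rng(0))
        with np.load(d / "weights.npz") as z:
            for i, conv in enumerate(model.net_.convs()):
                conv.W = z[f"W{i}"].copy()
                conv.b = z[f"b{i}"].copy()
        log = d / "training_log.csv"
        if log.exists():
            model.history_ = pd.read_csv(log)
        return model


# ---------------------------------------------------------------- oracle ----


class OracleSegmenter:
    """Ground-truth-backed predictor for one slide.

    The slide's lesion mask is returned as a probability map after (1)
    flipping each connected component to negative with probability
    ``flip_rate`` and (2) adding pixelwise Gaussian noise of sd ``noise_sd``,
    then clipping to [0, 1]. ``flip_rate=1`` suppresses every lesion.
    """

    def __init__(self, slide: SlideRecord, noise_sd: float = 0.0, flip_rate: float = 0.0, seed: int = 0):
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= flip_rate <= 1.0:
            raise ValueError("flip_rate must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        probs = slide.lesion_mask.astype(np.float64)
        if flip_rate > 0:
            labels = cc_label(slide.lesion_mask, connectivity=2)
            for comp in range(1, labels.max() + 1):
                if rng.random() < flip_rate:
                    probs[labels == comp] = 0.0
        if noise_sd > 0:
            probs = probs + rng.normal(0.0, noise_sd, size=probs.shape)
        self.probs_ = np.clip(probs, 0.0, 1.0)
        self.slide_id = slide.slide_id

    def predict_slide(self) -> np.ndarray:
        return self.probs_

    def tile_probs(self, grid) -> list[np.ndarray]:
        """Slice the slide-level probability map into the grid's tiles
        (borders padded with 0), so stitching is exercised end to end."""
        from .tiling import extract_tiles

        return extract_tiles(self.probs_, grid, fill=0.0)


# ------------------------------------------------------- operation surface --


def train_segmenter(patches, masks, config: SegTrainConfig | None = None) -> UNetSegmenter:
    """Fit a :class:`UNetSegmenter` from patch images and pixel masks."""
    cfg = config or SegTrainConfig()
    model = UNetSegmenter(
        batch_size=cfg.batch_size,
        initial_lr=cfg.initial_lr,
        lr_decay_rate=cfg.lr_decay_rate,
        lr_decay_steps=cfg.lr_decay_steps,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        val_fraction=cfg.val_fraction,
        random_state=cfg.seed,
    )
    return model.fit(patches, masks)


def predict_tiles(model: UNetSegmenter, tiles, tile_size: int = 512) -> list[np.ndarray]:
    """Run the segmenter over inference tiles; every tile must be
    ``tile_size`` × ``tile_size`` RGB."""
    tiles = list(tiles)
    for t in tiles:
        if t.shape[:2] != (tile_size, tile_size):
            raise ValueError(
                f"expected {tile_size}x{tile_size} tiles, got {t.shape[:2]}"
            )
    probs = model.predict_proba(np.stack(tiles))
    return [probs[i] for i in range(probs.shape[0])]


def oracle_segmenter(
    slide: SlideRecord, noise_sd: float = 0.0, flip_rate: float = 0.0, seed: int = 0
) -> OracleSegmenter:
    return OracleSegmenter(slide, noise_sd=noise_sd, flip_rate=flip_rate, seed=seed)
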