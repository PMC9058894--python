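"""Tile-level MSI probability scorers.

The scorer contract is minimal so backbones are pluggable: anything with an
``input_px`` attribute and a ``score_array(batch) -> probabilities`` method
can score tiles. Three scorers are provided:

* :class:`SmallConvNet` — a compact from-scratch convolutional network
  (two 3x3 conv blocks, global average pooling, softmax head) trained with
  Adam and cross-entropy, with support for freezing the first fraction of
  parameterized layers. This is the desk-scale training path.
* :class:`MockRedScorer` — a stateless scorer (mean red-channel intensity)
  used to test the pipeline plumbing independently of any training.
* :class:`TextureStatScorer` — a hand-crafted morphology statistic that
  separates filled-disc textures from ring textures without training.

The full-scale recipe (ImageNet-pretrained ResNet18, last half of the
layers fine-tuned for five epochs at batch 1024, lr 1e-4, weight decay
1e-5, 224 px inputs) is available through the optional
:mod:`msiprescreen.resnet_backbone` plugin when torch is installed; its
hyperparameters are the defaults of :class:`ScorerConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage import transform

from .types import Tile, TileScore

__all__ = [
    "ScorerConfig",
    "TileScorer",
    "SmallConvNet",
    "MockRedScorer",
    "TextureStatScorer",
    "sample_patient_tiles",
    "balance_training_tiles",
    "train_tile_scorer",
    "score_tiles",
    "TrainingSetupError",
]


class TrainingSetupError(ValueError):
    """Raised when the training set cannot be assembled (e.g. an empty class)."""


@dataclass
class ScorerConfig:
    """Training hyperparameters.

    Defaults are the full transfer-learning recipe (five epochs, batch
    1024, lr 1e-4, weight decay 1e-5, first half of the layers frozen,
    224 px inputs). :meth:`desk_scale` returns the reduced configuration
    used with the small from-scratch backbone.
    """

    epochs: int = 5
    batch_size: int = 1024
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    frozen_fraction: float = 0.5
    input_px: int = 224
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.frozen_fraction <= 1.0:
            raise ValueError("frozen_fraction must be in [0, 1]")
        if self.input_px < 8:
            raise ValueError("input_px must be >= 8")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 5) -> "ScorerConfig":
        # Small-backbone defaults: modest batch and input size, and a
        # learning rate suited to a from-scratch head rather than
        # fine-tuning a pretrained network.
        return cls(
            epochs=epochs,
            batch_size=32,
            learning_rate=1e-2,
            weight_decay=1e-5,
            frozen_fraction=0.5,
            input_px=64,
            seed=seed,
        )


@runtime_checkable
class TileScorer(Protocol):
    """Scorer plugin contract."""

    input_px: Optional[int]

    def score_array(self, batch: np.ndarray) -> np.ndarray:
        """Map a (N, H, W, 3) uint8 batch to N probabilities in [0, 1]."""
        ...


# ---------------------------------------------------------------------------
# Tile set assembly
# ---------------------------------------------------------------------------

def sample_patient_tiles(
    tiles: Sequence[Tile], cap: int = 500, rng: Optional[np.random.Generator] = None
) -> list[Tile]:
    """Cap a patient's tile count at ``cap`` by uniform sampling.

    Patients with more than ``cap`` tiles contribute a uniform random
    subset without replacement (original order preserved); all others
    contribute every tile. Reproducible for a fixed generator state.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    tiles = list(tiles)
    if len(tiles) <= cap:
        return tiles
    rng = np.random.default_rng() if rng is None else rng
    idx = np.sort(rng.choice(len(tiles), size=cap, replace=False))
    return [tiles[i] for i in idx]


def balance_training_tiles(
    class0_tiles: Sequence[Tile],
    class1_tiles: Sequence[Tile],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Tile], np.ndarray]:
    """Undersample the larger class to the smaller class's size.

    Applied to training data only — test tiles are never balanced.
    Returns the pooled tiles and their 0/1 labels.
    """
    if len(class0_tiles) == 0 or len(class1_tiles) == 0:
        raise TrainingSetupError("both classes must be non-empty for training")
    rng = np.random.default_rng() if rng is None else rng
    n = min(len(class0_tiles), len(class1_tiles))

    def _sub(tiles: Sequence[Tile]) -> list[Tile]:
        tiles = list(tiles)
        if len(tiles) == n:
            return tiles
        idx = np.sort(rng.choice(len(tiles), size=n, replace=False))
        return [tiles[i] for i in idx]

    t0, t1 = _sub(class0_tiles), _sub(class1_tiles)
    labels = np.array([0] * n + [1] * n)
    return t0 + t1, labels


def _resize_batch(tiles: Sequence[Tile], input_px: Optional[int]) -> np.ndarray:
    imgs = []
    for t in tiles:
        px = t.pixels
        if input_px is not None and px.shape[0] != input_px:
            px = transform.resize(
                px.astype(float),
                (input_px, input_px),
                order=1,
                anti_aliasing=False,
                preserve_range=True,
            )
            px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
        imgs.append(px)
    return np.stack(imgs)


def score_tiles(scorer: TileScorer, tiles: Sequence[Tile]) -> list[TileScore]:
    """Score tiles with any scorer plugin; batched equals per-tile scoring."""
    if not tiles:
        return []
    batch = _resize_batch(tiles, getattr(scorer, "input_px", None))
    probs = np.asarray(scorer.score_array(batch), dtype=float)
    if probs.shape != (len(tiles),):
        raise ValueError("scorer returned wrong number of probabilities")
    return [TileScore(tile=t, p_msi=float(p)) for t, p in zip(tiles, probs)]


# ---------------------------------------------------------------------------
# Deterministic scorers (no training)
# ---------------------------------------------------------------------------

class MockRedScorer:
    """Stateless mock: p_msi = mean red-channel intensity / 255."""

    input_px: Optional[int] = None

    def score_array(self, batch: np.ndarray) -> np.ndarray:
        return batch[..., 0].mean(axis=(1, 2)) / 255.0


class TextureStatScorer:
    """Morphology statistic separating disc-like from ring-like textures.

    Computes the ratio of stained (dark) area to its hole-filled area:
    filled discs (lymphocyte-like, the MSI-associated texture) score near
    1, while rings and gland-like structures enclose unstained lumina and
    score low. Pure and deterministic.
    """

    input_px: Optional[int] = None

    def __init__(self, dark_threshold: float = 150.0):
        self.dark_threshold = dark_threshold

    def score_array(self, batch: np.ndarray) -> np.ndarray:
        probs = np.empty(len(batch))
        for i, img in enumerate(batch):
            gray = img.astype(float).mean(axis=2)
            dark = gray < self.dark_threshold
            if not dark.any():
                probs[i] = 0.0
                continue
            filled = ndimage.binary_fill_holes(dark)
            probs[i] = dark.sum() / max(int(filled.sum()), 1)
        return np.clip(probs, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Small from-scratch convolutional backbone (NumPy)
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padding 3x3 convolution. x: (N,H,W,Cin), w: (3,3,Cin,Cout)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N,H,W,Cin,3,3)
    out = np.einsum("nhwcij,ijco->nhwo", cols, w, optimize=True) + b
    return out, cols


def _conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    N, H, W, _ = x_shape
    dw = np.einsum("nhwcij,nhwo->ijco", cols, dout, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    dxp = np.zeros((N, H + 2, W + 2, x_shape[3]))
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + H, j : j + W, :] += np.einsum(
                "nhwo,co->nhwc", dout, w[i, j], optimize=True
            )
    return dxp[:, 1 : H + 1, 1 : W + 1, :], dw, db


def _pool2_forward(x: np.ndarray):
    N, H, W, C = x.shape
    x6 = x.reshape(N, H // 2, 2, W // 2, 2, C)
    out = x6.max(axis=(2, 4))
    return out, x6


def _pool2_backward(dout: np.ndarray, x6: np.ndarray):
    mask = x6 == x6.max(axis=(2, 4), keepdims=True)
    cnt = mask.sum(axis=(2, 4), keepdims=True)
    dx6 = mask * (dout[:, :, None, :, None, :] / cnt)
    N, Hh, _, Wh, _, C = x6.shape
    return dx6.reshape(N, Hh * 2, Wh * 2, C)


class SmallConvNet:
    """Two-block CNN with global average pooling and a softmax head.

    Parameterized layers in definition order: conv1 (3->c1), conv2
    (c1->c2), fc (c2->2). ``frozen_fraction`` freezes the first
    ``floor(frozen_fraction * 3)`` of them (the default 0.5 freezes conv1,
    whose random filters then act as a fixed feature bank). Input images
    must be square with an edge divisible by 4.
    """

    def __init__(self, config: ScorerConfig, c1: int = 8, c2: int = 16):
        if config.input_px % 4 != 0:
            raise ValueError("input_px must be divisible by 4")
        self.config = config
        self.input_px = config.input_px
        rng = np.random.default_rng(config.seed)
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.params = [
            [he(27, (3, 3, 3, c1)), np.zeros(c1)],
            [he(9 * c1, (3, 3, c1, c2)), np.zeros(c2)],
            [he(c2, (c2, 2)), np.zeros(2)],
        ]
        self.n_frozen = int(np.floor(config.frozen_fraction * len(self.params)))
        self._rng = rng
        self._adam_m = [[np.zeros_like(p) for p in layer] for layer in self.params]
        self._adam_v = [[np.zeros_like(p) for p in layer] for layer in self.params]
        self._adam_t = 0
        self.training_log: list[dict] = []

    # -- forward / backward --------------------------------------------------

    @staticmethod
    def _prep(batch: np.ndarray) -> np.ndarray:
        return batch.astype(float) / 255.0 - 0.5

    def _forward(self, x: np.ndarray, need_cache: bool):
        cache = {}
        (w1, b1), (w2, b2), (wf, bf) = self.params
        z1, cols1 = _conv_forward(x, w1, b1)
        a1 = np.maximum(z1, 0.0)
        p1, x6_1 = _pool2_forward(a1)
        z2, cols2 = _conv_forward(p1, w2, b2)
        a2 = np.maximum(z2, 0.0)
        p2, x6_2 = _pool2_forward(a2)
        feat = p2.mean(axis=(1, 2))  # global average pooling
        logits = feat @ wf + bf
        if need_cache:
            cache = dict(
                x=x, cols1=cols1, z1=z1, x6_1=x6_1, p1=p1, cols2=cols2,
                z2=z2, x6_2=x6_2, p2=p2, feat=feat,
            )
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict):
        (w1, _), (w2, _), (wf, _) = self.params
        feat = cache["feat"]
        dwf = feat.T @ dlogits
        dbf = dlogits.sum(axis=0)
        grads = [None, None, [dwf, dbf]]
        if self.n_frozen >= 2:
            return grads
        p2 = cache["p2"]
        dfeat = dlogits @ wf.T
        dp2 = np.broadcast_to(
            dfeat[:, None, None, :] / (p2.shape[1] * p2.shape[2]), p2.shape
        )
        da2 = _pool2_backward(dp2, cache["x6_2"])
        dz2 = da2 * (cache["z2"] > 0)
        dp1, dw2, db2 = _conv_backward(dz2, cache["cols2"], w2, cache["p1"].shape)
        grads[1] = [dw2, db2]
        if self.n_frozen >= 1:
            return grads
        da1 = _pool2_backward(dp1, cache["x6_1"])
        dz1 = da1 * (cache["z1"] > 0)
        _, dw1, db1 = _conv_backward(dz1, cache["cols1"], w1, cache["x"].shape)
        grads[0] = [dw1, db1]
        return grads

    def _adam_step(self, grads) -> None:
        cfg = self.config
        self._adam_t += 1
        t, lr = self._adam_t, cfg.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        for li in range(len(self.params)):
            if li < self.n_frozen or grads[li] is None:
                continue
            for pi in range(len(self.params[li])):
                g = grads[li][pi] + cfg.weight_decay * self.params[li][pi]
                m = self._adam_m[li][pi]
                v = self._adam_v[li][pi]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1**t)
                vhat = v / (1 - b2**t)
                self.params[li][pi] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ----------------------------------------------------------

    def fit(self, batch: np.ndarray, labels: np.ndarray) -> "SmallConvNet":
        """Train on a (N, E, E, 3) uint8 batch with 0/1 labels."""
        cfg = self.config
        n = len(batch)
        if n == 0:
            raise TrainingSetupError("empty training set")
        batch_size = cfg.batch_size
        if batch_size > n:
            warnings.warn(
                f"batch size {batch_size} exceeds training set size {n}; shrinking",
                stacklevel=2,
            )
            batch_size = n
        x_all = self._prep(batch)
        y_all = np.asarray(labels, dtype=int)
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                x, y = x_all[idx], y_all[idx]
                logits, cache = self._forward(x, need_cache=True)
                shifted = logits - logits.max(axis=1, keepdims=True)
                probs = np.exp(shifted)
                probs /= probs.sum(axis=1, keepdims=True)
                loss = -np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12))
                losses.append(loss * len(y))
                correct += int((logits.argmax(axis=1) == y).sum())
                dlogits = probs.copy()
                dlogits[np.arange(len(y)), y] -= 1.0
                dlogits /= len(y)
                grads = self._backward(dlogits, cache)
                self._adam_step(grads)
            self.training_log.append(
                {
                    "epoch": epoch + 1,
                    "loss": float(np.sum(losses) / n),
                    "accuracy": correct / n,
                }
            )
        return self

    def score_array(self, batch: np.ndarray) -> np.ndarray:
        probs = np.empty(len(batch))
        for start in range(0, len(batch), 256):
            chunk = self._prep(batch[start : start + 256])
            logits, _ = self._forward(chunk, need_cache=False)
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            probs[start : start + 256] = e[:, 1] / e.sum(axis=1)
        return probs


_BACKBONES = {"small_cnn": SmallConvNet}


def train_tile_scorer(
    tiles: Sequence[Tile],
    labels: Sequence[int],
    config: ScorerConfig,
    backbone: str = "small_cnn",
) -> TileScorer:
    """Train a tile scorer on a (balanced) labeled tile set.

    ``backbone`` selects the architecture: ``"small_cnn"`` is the
    from-scratch NumPy network; ``"resnet18"`` dispatches to the optional
    torch plugin with the ImageNet-pretrained backbone.
    """
    if backbone == "resnet18":
        from .resnet_backbone import train_resnet18  # lazy: optional dependency

        return train_resnet18(tiles, labels, config)
    if backbone not in _BACKBONES:
        raise ValueError(f"unknown backbone {backbone!r}")
    if len(tiles) == 0:
        raise TrainingSetupError("no training tiles")
    net = _BACKBONES[backbone](config)
    batch = _resize_batch(tiles, config.input_px)
    net.fit(batch, np.asarray(labels, dtype=int))
    return net
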