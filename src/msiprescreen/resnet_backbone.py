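"""Optional full-scale scorer: ImageNet-pretrained ResNet18 fine-tuning.

Implements the full transfer-learning recipe — freeze the first half of the
parameterized layers, fine-tune the rest with Adam and cross-entropy for a
fixed number of epochs at the configured batch size, learning rate and
weight decay, on tiles resized to ``config.input_px``. Requires the
``torch`` extra; everything else in the package works without it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .scoring import ScorerConfig, _resize_batch
from .types import Tile


def _require_torch():
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the resnet18 backbone requires the optional 'torch' extra "
            "(pip install msiprescreen[torch]); use backbone='small_cnn' otherwise"
        ) from exc
    return torch, torchvision


class ResNet18Scorer:
    """Wraps a fine-tuned ResNet18 behind the TileScorer contract."""

    def __init__(self, model, config: ScorerConfig):
        self.model = model
        self.config = config
        self.input_px = config.input_px

    def score_array(self, batch: np.ndarray) -> np.ndarray:  # pragma: no cover
        torch, _ = _require_torch()
        self.model.eval()
        x = torch.from_numpy(batch.astype(np.float32) / 255.0).permute(0, 3, 1, 2)
        with torch.no_grad():
            probs = torch.softmax(self.model(x), dim=1)[:, 1]
        return probs.numpy()


def train_resnet18(
    tiles: Sequence[Tile], labels: Sequence[int], config: ScorerConfig
) -> ResNet18Scorer:  # pragma: no cover - exercised only with torch installed
    torch, torchvision = _require_torch()
    torch.manual_seed(config.seed)
    model = torchvision.models.resnet18(weights="IMAGENET1K_V1")
    model.fc = torch.nn.Linear(model.fc.in_features, 2)
    named = [p for _, p in model.named_parameters()]
    n_frozen = int(np.floor(config.frozen_fraction * len(named)))
    for p in named[:n_frozen]:
        p.requires_grad_(False)
    opt = torch.optim.Adam(
        [p for p in model.parameters() if p.requires_grad],
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    loss_fn = torch.nn.CrossEntropyLoss()
    batch = _resize_batch(tiles, config.input_px)
    x_all = torch.from_numpy(batch.astype(np.float32) / 255.0).permute(0, 3, 1, 2)
    y_all = torch.as_tensor(np.asarray(labels, dtype=np.int64))
    n = len(x_all)
    bs = min(config.batch_size, n)
    gen = torch.Generator().manual_seed(config.seed)
    model.train()
    for _ in range(config.epochs):
        order = torch.randperm(n, generator=gen)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            opt.zero_grad()
            loss = loss_fn(model(x_all[idx]), y_all[idx])
            loss.backward()
            opt.step()
    return ResNet18Scorer(model, config)
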