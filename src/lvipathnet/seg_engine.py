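"""Vessel segmentation: ComboLoss, encoder-decoder model, training, inference.

The loss is a weighted combination of pixel-level weighted cross-entropy
(WCE) and region-level Dice losses for the foreground and background
classes::

    Loss = alpha * WCE + beta * DSC_FG + gamma * DSC_BG

with default weights (0.5, 0.2, 0.3). WCE handles the strong class
imbalance of vessel pixels against background by up-weighting the rare
class; the Dice terms reward region overlap, which matters for small
vessels whose pixel count barely registers in a cross-entropy mean.

The segmenter is a fully convolutional encoder-decoder: one downsampling
stage, an optional atrous (dilated) context block that aggregates
multi-scale context without further resolution loss, and a decoder that
upsamples and refines against an encoder skip connection. All three
annotation categories collapse to a single "vessel" foreground here;
invasion status is decided by the second-stage classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import nn
from ._rng import substream
from .geometry_tiling import crop_padded, grid_tiles, reflect_pad, stitch
from .stain_augment import tta_forward, tta_inverse_average
from .types import SlidePlane, TileSpec

__all__ = [
    "LossWeights",
    "TrainConfig",
    "SegModelSpec",
    "TinySegNet",
    "wce",
    "dice_loss",
    "combo_loss",
    "combo_loss_grad",
    "binary_iou",
    "train_segmenter",
    "predict_tile",
    "predict_slide",
]

_CLIP = 1e-7


@dataclass
class LossWeights:
    """ComboLoss coefficients and WCE class weights.

    ``alpha``/``beta``/``gamma`` weight the WCE, foreground-Dice and
    background-Dice terms; ``wce_class_weights`` is (foreground,
    background); ``dice_smooth`` is the epsilon added to the Dice
    numerator and denominator.
    """

    alpha: float = 0.5
    beta: float = 0.2
    gamma: float = 0.3
    wce_class_weights: tuple[float, float] = (1.0, 1.0)
    dice_smooth: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be non-negative")
        if any(w < 0 for w in self.wce_class_weights):
            raise ValueError("WCE class weights must be non-negative")
        if not self.dice_smooth > 0:
            raise ValueError("dice_smooth must be positive")


@dataclass
class TrainConfig:
    """Optimization hyperparameters for the segmentation stage.

    Defaults follow the study protocol: Adam with initial learning rate
    1e-4 and batch size 16, the rate multiplied by 0.3 at epoch 12, up to
    250 epochs with early stopping on validation IoU.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 250
    lr_decay_factor: float = 0.3
    lr_decay_epoch: int = 12
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.lr_decay_factor, self.lr_decay_epoch) <= 0:
            raise ValueError("all training hyperparameters must be positive")
        if not 0 < self.early_stop_patience < self.max_epochs:
            raise ValueError("patience must be positive and < max_epochs")


@dataclass
class SegModelSpec:
    """Architecture knobs for the encoder-decoder segmenter.

    ``base_channels`` scales width (tiny ... full); ``use_aspp`` enables
    the atrous context block with the given dilation rates.
    """

    base_channels: int = 8
    use_aspp: bool = True
    aspp_dilations: tuple[int, ...] = (1, 2, 4)

    def __post_init__(self) -> None:
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.use_aspp and not self.aspp_dilations:
            raise ValueError("aspp_dilations must be non-empty when enabled")


# ---------------------------------------------------------------------------
# ComboLoss
# ---------------------------------------------------------------------------


def _check_pair(prob_map: np.ndarray, truth_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(prob_map, dtype=np.float64)
    y = np.asarray(truth_mask, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return np.clip(p, _CLIP, 1.0 - _CLIP), y


def wce(prob_map: np.ndarray, truth_mask: np.ndarray,
        class_weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Weighted cross-entropy, mean over pixels.

    ``-mean[w_fg * y * log p + w_bg * (1-y) * log(1-p)]``; probabilities
    are clipped to (1e-7, 1 - 1e-7).
    """
    p, y = _check_pair(prob_map, truth_mask)
    w_fg, w_bg = class_weights
    return float(-np.mean(w_fg * y * np.log(p) + w_bg * (1 - y) * np.log(1 - p)))


def dice_loss(prob_map: np.ndarray, truth_mask: np.ndarray,
              target_class: str = "foreground", smooth: float = 1.0) -> float:
    """Soft Dice loss ``1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps)``.

    For ``target_class="background"`` both prediction and truth are
    complemented first.
    """
    p, y = _check_pair(prob_map, truth_mask)
    if target_class == "background":
        p, y = 1.0 - p, 1.0 - y
    elif target_class != "foreground":
        raise ValueError("target_class must be 'foreground' or 'background'")
    num = 2.0 * np.sum(p * y) + smooth
    den = np.sum(p) + np.sum(y) + smooth
    return float(1.0 - num / den)


def combo_loss(prob_map: np.ndarray, truth_mask: np.ndarray,
               weights: LossWeights | None = None) -> float:
    """``alpha*WCE + beta*Dice_fg + gamma*Dice_bg``."""
    w = weights or LossWeights()
    return (
        w.alpha * wce(prob_map, truth_mask, w.wce_class_weights)
        + w.beta * dice_loss(prob_map, truth_mask, "foreground", w.dice_smooth)
        + w.gamma * dice_loss(prob_map, truth_mask, "background", w.dice_smooth)
    )


def _dice_grad(p: np.ndarray, y: np.ndarray, smooth: float) -> np.ndarray:
    # d/dp_i of 1 - (2*sum(py)+eps)/(sum(p)+sum(y)+eps)
    num = 2.0 * np.sum(p * y) + smooth
    den = np.sum(p) + np.sum(y) + smooth
    return -(2.0 * y * den - num) / den**2


def combo_loss_grad(prob_map: np.ndarray, truth_mask: np.ndarray,
                    weights: LossWeights | None = None) -> np.ndarray:
    """Analytic d(combo_loss)/d(prob) used by the training loop."""
    w = weights or LossWeights()
    p, y = _check_pair(prob_map, truth_mask)
    w_fg, w_bg = w.wce_class_weights
    n = p.size
    g = w.alpha * (-(w_fg * y / p) + w_bg * (1 - y) / (1 - p)) / n
    g = g + w.beta * _dice_grad(p, y, w.dice_smooth)
    g = g - w.gamma * _dice_grad(1.0 - p, 1.0 - y, w.dice_smooth)
    # zero the gradient where clipping is active, matching the flat loss
    raw = np.asarray(prob_map, dtype=np.float64)
    g[(raw <= _CLIP) | (raw >= 1.0 - _CLIP)] = 0.0
    return g


def binary_iou(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 if both empty)."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(truth_mask, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class TinySegNet:
    """Fully convolutional encoder-decoder with an optional atrous block.

    encoder: conv-relu -> maxpool -> conv-relu
    context: parallel dilated convs, summed (atrous spatial pyramid, lite)
    decoder: 2x nearest upsample, concat encoder skip, conv-relu, 1x1 head

    Input is an (H, W, 3) RGB image with even H, W; output a per-pixel
    foreground probability of the same spatial shape.
    """

    def __init__(self, spec: SegModelSpec | None = None, seed: int = 0):
        self.spec = spec or SegModelSpec()
        rng = substream(seed, "init")
        C = self.spec.base_channels
        self.enc1 = nn.Conv2d(3, C, rng=rng)
        self.relu1 = nn.ReLU()
        self.pool = nn.MaxPool2()
        self.enc2 = nn.Conv2d(C, 2 * C, rng=rng)
        self.relu2 = nn.ReLU()
        self.aspp: list[nn.Conv2d] = []
        if self.spec.use_aspp:
            self.aspp = [nn.Conv2d(2 * C, 2 * C, dilation=d, rng=rng)
                         for d in self.spec.aspp_dilations]
            self.relu_aspp = nn.ReLU()
        self.up = nn.Upsample2()
        self.dec = nn.Conv2d(3 * C, C, rng=rng)
        self.relu3 = nn.ReLU()
        self.head = nn.Conv2d(C, 1, k=1, rng=rng)

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for layer in [self.enc1, self.enc2, *self.aspp, self.dec, self.head]:
            ps.extend(layer.params())
        return ps

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W) float in [0, 1] -> logits (N, 1, H, W)."""
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("input spatial dimensions must be even")
        e1 = self.relu1.forward(self.enc1.forward(x))
        z = self.relu2.forward(self.enc2.forward(self.pool.forward(e1)))
        if self.aspp:
            z = self.relu_aspp.forward(sum(conv.forward(z) for conv in self.aspp))
        u = self.up.forward(z)
        self._split = (u.shape[1], e1.shape[1])
        d = self.relu3.forward(self.dec.forward(np.concatenate([u, e1], axis=1)))
        return self.head.forward(d)

    def backward(self, dlogits: np.ndarray) -> None:
        dd = self.relu3.backward(self.head.backward(dlogits))
        dcat = self.dec.backward(dd)
        cu, _ = self._split
        du, de1_skip = dcat[:, :cu], dcat[:, cu:]
        dz = self.up.backward(du)
        if self.aspp:
            dz = self.relu_aspp.backward(dz)
            dz = sum(conv.backward(dz) for conv in self.aspp)
        dp = self.pool.backward(self.enc2.backward(self.relu2.backward(dz)))
        de1 = self.relu1.backward(dp + de1_skip)
        self.enc1.backward(de1)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel foreground probability for one (H, W, 3) image."""
        x = _image_to_input(image)[None]
        logits = self.forward(x.transpose(0, 3, 1, 2))
        return nn.sigmoid(logits[0, 0])

    def save(self, path) -> None:
        """Persist weights and architecture to an .npz file."""
        import json

        meta = json.dumps({"base_channels": self.spec.base_channels,
                           "use_aspp": self.spec.use_aspp,
                           "aspp_dilations": list(self.spec.aspp_dilations)})
        np.savez(path, __spec__=meta,
                 **{f"p{i}": v for i, v in enumerate(self.get_state())})

    @classmethod
    def load(cls, path) -> "TinySegNet":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__spec__"]))
        model = cls(SegModelSpec(base_channels=meta["base_channels"],
                                 use_aspp=meta["use_aspp"],
                                 aspp_dilations=tuple(meta["aspp_dilations"])))
        model.set_state([data[f"p{i}"] for i in range(len(model.params()))])
        return model


def _image_to_input(image: np.ndarray) -> np.ndarray:
    """RGB image -> standardized floats in [-1, 1].

    Centering matters: H&E tiles are mostly pale (mean near 0.9 in unit
    range), and an uncentered input biases every ReLU path, slowing
    convergence noticeably.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    return (img - 0.5) * 2.0


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train_segmenter(
    train_tiles: Sequence[tuple[np.ndarray, np.ndarray]],
    val_tiles: Sequence[tuple[np.ndarray, np.ndarray]],
    model_spec: SegModelSpec | None = None,
    train_config: TrainConfig | None = None,
    loss_weights: LossWeights | None = None,
) -> tuple[TinySegNet, list[dict]]:
    """Train the segmenter with Adam on ComboLoss.

    ``train_tiles``/``val_tiles`` are (image, binary mask) pairs, already
    normalized/augmented. The learning rate is multiplied by
    ``lr_decay_factor`` at ``lr_decay_epoch`` (1-based); training stops at
    ``max_epochs`` or when validation IoU has not improved for
    ``early_stop_patience`` epochs. Returns the best-validation model and
    a per-epoch history of learning rate, training loss and validation
    IoU. WCE class weights default to inverse class frequency per batch.

    Raises on an empty dataset and aborts if the loss goes non-finite.
    """
    if not train_tiles or not val_tiles:
        raise ValueError("training and validation sets must be non-empty")
    cfg = train_config or TrainConfig()
    base_weights = loss_weights or LossWeights()
    model = TinySegNet(model_spec, seed=cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = substream(cfg.seed, "seg-train")

    X = np.stack([_image_to_input(img).transpose(2, 0, 1) for img, _ in train_tiles])
    Y = np.stack([np.asarray(m, dtype=np.float64) for _, m in train_tiles])

    history: list[dict] = []
    best_iou, best_state, since_best = -1.0, model.get_state(), 0
    for epoch in range(1, cfg.max_epochs + 1):
        if epoch == cfg.lr_decay_epoch:
            opt.lr *= cfg.lr_decay_factor
        order = rng.permutation(len(X))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            logits = model.forward(xb)
            p = nn.sigmoid(logits[:, 0])
            w = _batch_class_weights(yb, base_weights)
            loss = combo_loss(p, yb, w)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            dp = combo_loss_grad(p, yb, w)
            dlogits = (dp * p * (1.0 - p))[:, None]
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_iou = float(np.mean([
            binary_iou(model.predict_proba(img) >= 0.5, msk)
            for img, msk in val_tiles
        ]))
        history.append({
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_iou": val_iou,
        })
        if val_iou > best_iou:
            best_iou, best_state, since_best = val_iou, model.get_state(), 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    model.set_state(best_state)
    return model, history


def _batch_class_weights(yb: np.ndarray, base: LossWeights) -> LossWeights:
    """Inverse-class-frequency WCE weights, normalized to mean 1."""
    n_fg = float(yb.sum())
    n = float(yb.size)
    n_bg = n - n_fg
    if n_fg == 0 or n_bg == 0:
        w_fg, w_bg = base.wce_class_weights
    else:
        w_fg, w_bg = n / (2.0 * n_fg), n / (2.0 * n_bg)
    return LossWeights(base.alpha, base.beta, base.gamma, (w_fg, w_bg),
                       base.dice_smooth)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

SegPredictor = Callable[[np.ndarray], np.ndarray]


def _raw_predict(model, image: np.ndarray) -> np.ndarray:
    fn = model.predict_proba if hasattr(model, "predict_proba") else model
    prob = np.asarray(fn(image), dtype=np.float64)
    if prob.shape != image.shape[:2]:
        raise ValueError("model output shape must match the input footprint")
    return prob


def predict_tile(model, tile_image: np.ndarray, use_tta: bool = True,
                 use_reflect_pad: bool = True) -> np.ndarray:
    """Segment one tile, optionally with reflection padding and D4 TTA.

    With padding, the tile is doubled by reflection, predicted, and the
    original (top-left) footprint cropped back — the mirrored context
    stabilizes vessels cut by the tile edge. With TTA, the 8 dihedral
    transforms are predicted and averaged after exact inversion.
    """
    img = np.asarray(tile_image)
    work = reflect_pad(img) if use_reflect_pad else img
    if use_tta:
        branches = tta_forward(work)
        maps = [_raw_predict(model, t) for t, _ in branches]
        prob = tta_inverse_average(maps, [r for _, r in branches])
    else:
        prob = _raw_predict(model, work)
    if use_reflect_pad:
        prob = crop_padded(prob)
    return prob


def predict_slide(model, plane: SlidePlane, tile_size: int = 128,
                  overlap: float = 0.5, threshold: float = 0.5,
                  use_tta: bool = True, use_reflect_pad: bool = True,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Segment a whole plane: tile, predict, stitch, threshold.

    Returns the stitched probability plane and the binary vessel mask at
    ``threshold``. A tile larger than the plane collapses to one clamped
    tile.
    """
    specs = grid_tiles(plane.shape, tile_size, overlap, source=plane.name)
    tile_probs: list[tuple[TileSpec, np.ndarray]] = []
    for spec in specs:
        crop = spec.crop(plane.pixels)
        pad_ok = use_reflect_pad and crop.shape[0] % 2 == 0 and crop.shape[1] % 2 == 0
        prob = predict_tile(model, crop, use_tta=use_tta, use_reflect_pad=pad_ok)
        tile_probs.append((spec, prob))
    prob_plane = stitch(tile_probs, plane.shape)
    return prob_plane, prob_plane >= threshold
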