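"""Stain normalization, training augmentations, and invertible TTA.

H&E staining intensity drifts between laboratories and scanners; models
that key on absolute color overfit to the source lab. The normalizer here
follows the random-target scheme: fit the distribution of per-channel
mean/std statistics over a reference image set in a decorrelated (LAB)
color space, then map each training image to a *sampled* target statistic
rather than a single fixed one, so the model sees a controlled spread of
plausible stains.

Test-time augmentation (TTA) uses the 8-element dihedral group of the
square — the only image transforms that are exactly invertible on a pixel
grid — so predictions can be averaged after inverse transformation with no
interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import lab2rgb, rgb2lab

from ._rng import substream

__all__ = [
    "StainTemplate",
    "TTARecord",
    "AugmentPolicy",
    "fit_stain_stats",
    "randstain_normalize",
    "stain_normalize",
    "augment",
    "D4_TRANSFORMS",
    "apply_d4",
    "invert_d4",
    "tta_forward",
    "tta_inverse_average",
]


def _as_float_rgb(image: np.ndarray) -> tuple[np.ndarray, bool]:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0, True
    return img.astype(np.float64), False


@dataclass
class StainTemplate:
    """Distributional summary of per-channel LAB statistics over a set.

    For each LAB channel the template stores the mean and spread of the
    per-image channel means, and likewise for the per-image channel stds.
    Sampling a Gaussian from these four numbers per channel yields a
    random but realistic stain target.
    """

    mean_of_means: np.ndarray
    std_of_means: np.ndarray
    mean_of_stds: np.ndarray
    std_of_stds: np.ndarray

    def __post_init__(self) -> None:
        for name in ("mean_of_means", "std_of_means", "mean_of_stds", "std_of_stds"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"{name} must have 3 channels")
            setattr(self, name, arr)
        if np.any(self.std_of_means < 0) or np.any(self.std_of_stds < 0):
            raise ValueError("spread statistics must be non-negative")
        if np.any(self.mean_of_stds < 0):
            raise ValueError("mean_of_stds must be non-negative")


def fit_stain_stats(images: list[np.ndarray]) -> StainTemplate:
    """Fit a :class:`StainTemplate` from one or more RGB reference images."""
    if not images:
        raise ValueError("need at least one image to fit stain statistics")
    means, stds = [], []
    for image in images:
        img, _ = _as_float_rgb(image)
        lab = rgb2lab(img)
        means.append(lab.reshape(-1, 3).mean(axis=0))
        stds.append(lab.reshape(-1, 3).std(axis=0))
    means = np.asarray(means)
    stds = np.asarray(stds)
    return StainTemplate(
        mean_of_means=means.mean(axis=0),
        std_of_means=means.std(axis=0),
        mean_of_stds=stds.mean(axis=0),
        std_of_stds=stds.std(axis=0),
    )


def randstain_normalize(
    image: np.ndarray, template: StainTemplate, seed: int
) -> np.ndarray:
    """Map an image's LAB channel statistics to a randomly sampled target.

    Targets are drawn per channel from ``N(mean_of_means, std_of_means)``
    and ``N(mean_of_stds, std_of_stds)`` (std clipped at 0), then each
    channel is affinely remapped ``(x - mu_in)/sigma_in * sigma_tgt +
    mu_tgt``. A constant input channel is shifted only. Deterministic
    given ``seed``; output dtype matches the input.
    """
    img, was_uint8 = _as_float_rgb(image)
    rng = substream(seed, "randstain")
    tgt_mean = rng.normal(template.mean_of_means, template.std_of_means)
    tgt_std = np.clip(rng.normal(template.mean_of_stds, template.std_of_stds), 0, None)
    lab = rgb2lab(img)
    out = np.empty_like(lab)
    for c in range(3):
        ch = lab[..., c]
        mu, sigma = ch.mean(), ch.std()
        if sigma < 1e-8:
            out[..., c] = ch - mu + tgt_mean[c]
        else:
            out[..., c] = (ch - mu) / sigma * tgt_std[c] + tgt_mean[c]
    rgb = np.clip(lab2rgb(out), 0.0, 1.0)
    if was_uint8:
        return (rgb * 255.0 + 0.5).astype(np.uint8)
    return rgb


def stain_normalize(image: np.ndarray, template: StainTemplate) -> np.ndarray:
    """Deterministic variant: map to the template's mean statistics.

    Equivalent to :func:`randstain_normalize` with the target spread set
    to zero — the right choice at inference time, where reproducibility
    beats augmentation.
    """
    det = StainTemplate(template.mean_of_means, np.zeros(3),
                        template.mean_of_stds, np.zeros(3))
    return randstain_normalize(image, det, seed=0)


# ---------------------------------------------------------------------------
# Training augmentations
# ---------------------------------------------------------------------------


@dataclass
class AugmentPolicy:
    """Per-op application probabilities and magnitudes.

    Geometric ops (flip, rotate, grid/optical distortion) are applied
    identically to image and mask; photometric ops (blur, noise) touch the
    image only. Distortion magnitudes default to mild (<= 5% of the image
    side) so mask areas are approximately preserved.
    """

    p_flip: float = 0.5
    p_rotate: float = 0.5
    p_grid_distortion: float = 0.3
    grid_distortion_mag: float = 0.01  # fraction of image side
    grid_distortion_cells: int = 4
    p_optical_distortion: float = 0.3
    optical_distortion_k: float = 0.05  # radial coefficient bound
    p_gaussian_blur: float = 0.2
    blur_sigma_max: float = 1.5
    p_gaussian_noise: float = 0.2
    noise_std_max: float = 8.0  # in 8-bit intensity levels

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(
            p_flip=0, p_rotate=0, p_grid_distortion=0,
            p_optical_distortion=0, p_gaussian_blur=0, p_gaussian_noise=0,
        )


def _smooth_displacement(
    shape: tuple[int, int], cells: int, mag_px: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse random vector field upsampled to a smooth displacement grid."""
    coarse = rng.uniform(-mag_px, mag_px, size=(2, cells + 1, cells + 1))
    H, W = shape
    zoom = (H / (cells + 1), W / (cells + 1))
    dy = ndi.zoom(coarse[0], zoom, order=3, mode="nearest")[:H, :W]
    dx = ndi.zoom(coarse[1], zoom, order=3, mode="nearest")[:H, :W]
    return dy, dx


def _warp_pair(
    image: np.ndarray, mask: np.ndarray, dy: np.ndarray, dx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    H, W = mask.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    coords = np.array([yy + dy, xx + dx])
    if image.ndim == 3:
        warped = np.stack(
            [
                ndi.map_coordinates(image[..., c].astype(np.float64), coords,
                                    order=1, mode="reflect")
                for c in range(image.shape[2])
            ],
            axis=-1,
        )
    else:
        warped = ndi.map_coordinates(image.astype(np.float64), coords,
                                     order=1, mode="reflect")
    warped_mask = ndi.map_coordinates(mask.astype(np.float64), coords,
                                      order=0, mode="reflect")
    if image.dtype == np.uint8:
        warped = np.clip(warped, 0, 255).astype(np.uint8)
    return warped, warped_mask.astype(mask.dtype)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    policy: AugmentPolicy,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a seeded random subset of the augmentation suite.

    Returns the transformed (image, mask) pair. Mask label values are
    never altered — geometric ops resample it with nearest-neighbor.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask shapes must match")
    rng = substream(seed, "augment")
    img, msk = image.copy(), mask.copy()

    if rng.random() < policy.p_flip:
        axis = int(rng.integers(0, 2))
        img = np.flip(img, axis=axis)
        msk = np.flip(msk, axis=axis)
    if rng.random() < policy.p_rotate:
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k, axes=(0, 1))
        msk = np.rot90(msk, k, axes=(0, 1))
    if rng.random() < policy.p_grid_distortion:
        mag = policy.grid_distortion_mag * min(msk.shape[:2])
        dy, dx = _smooth_displacement(msk.shape[:2], policy.grid_distortion_cells, mag, rng)
        img, msk = _warp_pair(img, msk, dy, dx)
    if rng.random() < policy.p_optical_distortion:
        H, W = msk.shape[:2]
        k = rng.uniform(-policy.optical_distortion_k, policy.optical_distortion_k)
        yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
        cy, cx = (H - 1) / 2, (W - 1) / 2
        ry, rx = (yy - cy) / max(cy, 1), (xx - cx) / max(cx, 1)
        r2 = ry * ry + rx * rx
        dy = ry * k * r2 * cy
        dx = rx * k * r2 * cx
        img, msk = _warp_pair(img, msk, dy, dx)
    if rng.random() < policy.p_gaussian_blur:
        sigma = rng.uniform(0.3, policy.blur_sigma_max)
        blurred = ndi.gaussian_filter(img.astype(np.float64), sigma=(sigma, sigma, 0)[: img.ndim])
        img = np.clip(blurred, 0, 255).astype(np.uint8) if image.dtype == np.uint8 else blurred
    if rng.random() < policy.p_gaussian_noise:
        std = rng.uniform(1.0, policy.noise_std_max)
        scale = std if image.dtype == np.uint8 else std / 255.0
        noisy = img.astype(np.float64) + rng.normal(0, scale, size=img.shape)
        img = np.clip(noisy, 0, 255).astype(np.uint8) if image.dtype == np.uint8 else noisy
    return img, msk


# ---------------------------------------------------------------------------
# Test-time augmentation: the dihedral-4 group
# ---------------------------------------------------------------------------

#: Transform id -> (apply, inverse-id). All act on the first two axes.
D4_TRANSFORMS = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "flip_h",
    "flip_v",
    "transpose",
    "anti_transpose",
)

_D4_INVERSE = {
    "identity": "identity",
    "rot90": "rot270",
    "rot180": "rot180",
    "rot270": "rot90",
    "flip_h": "flip_h",
    "flip_v": "flip_v",
    "transpose": "transpose",
    "anti_transpose": "anti_transpose",
}


def apply_d4(transform_id: str, arr: np.ndarray) -> np.ndarray:
    """Apply one of the 8 square symmetries to the first two axes."""
    a = np.asarray(arr)
    if transform_id == "identity":
        return a.copy()
    if transform_id == "rot90":
        return np.rot90(a, 1, axes=(0, 1)).copy()
    if transform_id == "rot180":
        return np.rot90(a, 2, axes=(0, 1)).copy()
    if transform_id == "rot270":
        return np.rot90(a, 3, axes=(0, 1)).copy()
    if transform_id == "flip_h":
        return np.flip(a, axis=1).copy()
    if transform_id == "flip_v":
        return np.flip(a, axis=0).copy()
    if transform_id == "transpose":
        return np.swapaxes(a, 0, 1).copy()
    if transform_id == "anti_transpose":
        return np.rot90(np.swapaxes(a, 0, 1), 2, axes=(0, 1)).copy()
    raise ValueError(f"unknown D4 transform {transform_id!r}")


def invert_d4(transform_id: str, arr: np.ndarray) -> np.ndarray:
    """Exactly undo :func:`apply_d4` for the given transform id."""
    return apply_d4(_D4_INVERSE[transform_id], arr)


@dataclass(frozen=True)
class TTARecord:
    """Bookkeeping for one TTA branch: which transform was applied."""

    transform_id: str

    def __post_init__(self) -> None:
        if self.transform_id not in D4_TRANSFORMS:
            raise ValueError(f"unknown D4 transform {self.transform_id!r}")


def tta_forward(
    image: np.ndarray, policy: tuple[str, ...] = D4_TRANSFORMS
) -> list[tuple[np.ndarray, TTARecord]]:
    """Transformed copies of ``image`` with the records needed to invert."""
    return [(apply_d4(t, image), TTARecord(t)) for t in policy]


def tta_inverse_average(
    prob_maps: list[np.ndarray], records: list[TTARecord]
) -> np.ndarray:
    """Invert each prediction per its record, then average per pixel."""
    if len(prob_maps) != len(records):
        raise ValueError("one record per probability map required")
    if not prob_maps:
        raise ValueError("need at least one probability map")
    inverted = [invert_d4(r.transform_id, p) for p, r in zip(prob_maps, records)]
    shape = inverted[0].shape
    if any(inv.shape != shape for inv in inverted):
        raise ValueError("inverted maps must share a common shape")
    return np.mean(np.stack(inverted, axis=0), axis=0)
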