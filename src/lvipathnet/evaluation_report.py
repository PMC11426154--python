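"""Metrics, overlay rendering, and the end-to-end pipeline orchestrator.

Segmentation quality is reported pixel-level (IoU, FBeta, recall,
AUC-ROC); classification quality per tile or per vessel (F1, precision,
sensitivity, specificity, AUC-ROC). ``run_pipeline`` wires every stage
together on synthetic slides: generate -> tile -> train segmenter ->
infer -> extract instances -> train classifier ensemble -> flag ->
evaluate -> render, writing masks, GeoJSON predictions, overlays and
metrics to a run directory.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from ._rng import substream
from .geometry_tiling import bbox_tile
from .stain_augment import (
    apply_d4,
    fit_stain_stats,
    randstain_normalize,
    stain_normalize,
)
from .invasion_classifier import (
    TileVerdict,
    VesselInstance,
    default_ensemble_specs,
    default_min_area_px,
    extract_instances,
    flag_invasion,
    make_classifier_inputs,
    train_classifier_member,
)
from .seg_engine import (
    SegModelSpec,
    TrainConfig,
    predict_slide,
    train_segmenter,
)
from .synthetic_slide import (
    SceneConfig,
    SyntheticSlide,
    export_annotations,
    generate_scene,
)
from .types import AnnotationPolygon, SlidePlane, TileSpec

__all__ = [
    "SegMetrics",
    "ClsMetrics",
    "seg_metrics",
    "cls_metrics",
    "render_overlay",
    "classify_instances",
    "oracle_tile_prob",
    "run_pipeline",
    "default_pipeline_config",
]

log = logging.getLogger(__name__)


@dataclass
class SegMetrics:
    """Pixel-level segmentation scores, all in [0, 1] (AUC NaN-able)."""

    iou: float
    fbeta: float
    recall: float
    auc_roc: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClsMetrics:
    """Binary classification scores at a threshold plus threshold-free AUC."""

    f1: float
    precision: float
    sensitivity: float
    specificity: float
    auc_roc: float

    def to_dict(self) -> dict:
        return asdict(self)


def _confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    pred = np.asarray(pred).astype(bool).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return tp, fp, fn, tn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC-ROC undefined: only one class present")
        return float("nan")
    return float(roc_auc_score(labels, scores))


def seg_metrics(
    prob_plane: np.ndarray,
    binary_pred: np.ndarray,
    truth_mask: np.ndarray,
    beta: float = 1.0,
    max_auc_pixels: int = 1_000_000,
    seed: int = 0,
) -> SegMetrics:
    """IoU, FBeta, recall from the binary mask; AUC-ROC from probabilities.

    AUC is a rank (Mann-Whitney) statistic over pixels, subsampled to at
    most ``max_auc_pixels`` with a seeded draw for tractability. If the
    truth is single-class, AUC is NaN with a warning.
    """
    prob = np.asarray(prob_plane, dtype=np.float64)
    if prob.shape != np.asarray(truth_mask).shape or prob.shape != np.asarray(binary_pred).shape:
        raise ValueError("prob_plane, binary_pred and truth_mask shapes must match")
    tp, fp, fn, _tn = _confusion(binary_pred, truth_mask)
    iou = _safe_div(tp, tp + fp + fn)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    fbeta = _safe_div((1 + beta**2) * precision * recall,
                      beta**2 * precision + recall)
    flat_p = prob.ravel()
    flat_y = np.asarray(truth_mask).astype(bool).ravel()
    if flat_p.size > max_auc_pixels:
        idx = substream(seed, "auc-subsample").choice(flat_p.size, max_auc_pixels,
                                                      replace=False)
        flat_p, flat_y = flat_p[idx], flat_y[idx]
    return SegMetrics(iou=float(iou), fbeta=float(fbeta), recall=float(recall),
                      auc_roc=_rank_auc(flat_p, flat_y))


def cls_metrics(probs: Sequence[float], labels: Sequence[int],
                threshold: float = 0.5) -> ClsMetrics:
    """Confusion-matrix scores at ``threshold``; AUC is threshold-free."""
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    pred = p >= threshold
    tp, fp, fn, tn = _confusion(pred, y)
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity)
    return ClsMetrics(f1=float(f1), precision=float(precision),
                      sensitivity=float(sensitivity), specificity=float(specificity),
                      auc_roc=_rank_auc(p, y))


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

_CLEAN_RGB = np.array([40, 190, 70], dtype=np.float64)
_INVASIVE_RGB = np.array([220, 40, 40], dtype=np.float64)
_BOX_RGB = np.array([140, 0, 0], dtype=np.float64)


def render_overlay(
    plane: SlidePlane,
    instances: Sequence[VesselInstance],
    verdicts: Sequence[TileVerdict] = (),
    opacity: float = 0.4,
) -> np.ndarray:
    """RGBA overlay: green fill on clean vessels, red on invasive.

    Tiles judged invasive get a dark-red rectangle outline. With opacity
    0 (or no instances) the RGB channels equal the input exactly.
    """
    H, W = plane.shape
    out = np.empty((H, W, 4), dtype=np.uint8)
    rgb = plane.pixels.astype(np.float64)
    for inst in instances:
        x, y, w, h = inst.bbox
        if x < 0 or y < 0 or x + w > W or y + h > H:
            raise ValueError(f"instance {inst.id} exceeds the plane")
        color = _INVASIVE_RGB if inst.verdict == "invasive" else _CLEAN_RGB
        region = rgb[y : y + h, x : x + w]
        m = inst.mask
        region[m] = (1 - opacity) * region[m] + opacity * color
    for v in verdicts:
        if v.label != "invasive_or_displacement" or opacity == 0:
            continue
        s = v.spec
        x0, y0 = max(s.x, 0), max(s.y, 0)
        x1, y1 = min(s.x + s.w, W), min(s.y + s.h, H)
        rgb[y0, x0:x1] = _BOX_RGB
        rgb[y1 - 1, x0:x1] = _BOX_RGB
        rgb[y0:y1, x0] = _BOX_RGB
        rgb[y0:y1, x1 - 1] = _BOX_RGB
    out[..., :3] = np.clip(rgb + 0.5, 0, 255).astype(np.uint8)
    out[..., 3] = 255
    return out


# ---------------------------------------------------------------------------
# Instance classification helpers
# ---------------------------------------------------------------------------


def oracle_tile_prob(slide: SyntheticSlide, spec: TileSpec,
                     instance: VesselInstance | None = None) -> float:
    """Ground-truth stub: 1.0 iff the tile contains a planted tumor pixel.

    With ``instance`` given, only tumor pixels that fall on the
    instance's own pixel set count — a tile of a clean vessel that
    happens to overlap a neighboring invaded vessel stays clean.
    """
    for vessel in slide.vessels:
        if vessel.state == "clean" or len(vessel.tumor_mask_global) == 0:
            continue
        ys, xs = vessel.tumor_mask_global[:, 0], vessel.tumor_mask_global[:, 1]
        inside = ((ys >= spec.y) & (ys < spec.y + spec.h)
                  & (xs >= spec.x) & (xs < spec.x + spec.w))
        if inside.any() and instance is not None:
            bx, by, bw, bh = instance.bbox
            on_inst = np.zeros_like(inside)
            in_bbox = ((ys >= by) & (ys < by + bh) & (xs >= bx) & (xs < bx + bw))
            sel = inside & in_bbox
            if sel.any():
                on_inst[sel] = instance.mask[ys[sel] - by, xs[sel] - bx]
            inside = on_inst
        if inside.any():
            return 1.0
    return 0.0


def classify_instances(
    instances: Sequence[VesselInstance],
    plane: SlidePlane,
    members: Sequence | None = None,
    oracle_slide: SyntheticSlide | None = None,
    tile_um: float = 128.0,
    out_px: int = 224,
    min_mask_fraction: float = 0.05,
    threshold: float = 0.5,
) -> list[TileVerdict]:
    """Score every classifier tile of every instance.

    Either a member list (real ensemble) or ``oracle_slide`` (ground-
    truth-reading stub, used to validate the plumbing end-to-end) must be
    given.
    """
    if members is None and oracle_slide is None:
        raise ValueError("provide ensemble members or an oracle slide")
    verdicts: list[TileVerdict] = []
    for inst in instances:
        for spec, img in make_classifier_inputs(inst, plane, tile_um, out_px,
                                                min_mask_fraction):
            if oracle_slide is not None:
                p = oracle_tile_prob(oracle_slide, spec, inst)
                member_probs = (p,)
            else:
                member_probs = tuple(
                    float((m.predict_proba if hasattr(m, "predict_proba") else m)(img))
                    for m in members)
                p = float(np.mean(member_probs))
            verdicts.append(TileVerdict(inst.id, spec, member_probs, p,
                                        threshold=threshold))
    return verdicts


def per_vessel_scores(
    instances: Sequence[VesselInstance], slide: SyntheticSlide
) -> tuple[list[float], list[int]]:
    """Score each ground-truth vessel by its overlapping predictions.

    A truth vessel's score is the maximum invasive probability over all
    predicted instances touching its polygon (0 when the segmenter
    missed it entirely); its label is whether it was planted invaded.
    This is vessel-level evaluation against real vessels, immune to
    fragment double-counting in the predicted mask.
    """
    H, W = slide.plane.shape
    scores, labels = [], []
    for vessel in slide.vessels:
        vm = vessel.polygon.rasterize((H, W))
        mx = 0.0
        for inst in instances:
            x, y, w, h = inst.bbox
            if (vm[y : y + h, x : x + w] & inst.mask).any():
                mx = max(mx, inst.max_invasive_prob or 0.0)
        scores.append(mx)
        labels.append(int(vessel.state != "clean"))
    return scores, labels


def _instance_polygon(inst: VesselInstance) -> AnnotationPolygon | None:
    from skimage import measure

    padded = np.pad(inst.mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    ring = max(contours, key=len)
    x0, y0, _, _ = inst.bbox
    xy = np.column_stack([ring[:, 1] - 1 + x0, ring[:, 0] - 1 + y0])
    label = "luminal_invasion" if inst.verdict == "invasive" else "clean"
    return AnnotationPolygon(xy, label=label)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def default_pipeline_config() -> dict:
    """Desk-scale defaults: small planes, tiny models, CPU-minutes budget.

    The scene vocabulary leaves out the largest arteries so several
    vessels fit per small plane; mpp 2.0 keeps a 200-um vein around 100
    px. Segmentation trains on 64-px bbox crops; inference runs without
    TTA by default (the D4 symmetry machinery is exercised separately).
    """
    return {
        "seed": 0,
        "n_train_slides": 8,
        "n_val_slides": 3,
        "n_test_slides": 5,
        "scene": {
            "width_px": 288,
            "height_px": 288,
            "mpp": 2.0,
            "n_vessels_by_kind": {"vein": 2, "capillary": 3, "lymphatic": 2},
            "invasion_fraction": 0.4,
            "intramural_fraction": 0.25,
            "stain_jitter": 0.15,
        },
        "seg": {
            "tile_px": 64,
            "bg_tiles_per_slide": 2,
            "base_channels": 8,
            "use_aspp": True,
            "max_epochs": 35,
            "batch_size": 16,
            "learning_rate": 5e-3,
            "lr_decay_factor": 0.3,
            "lr_decay_epoch": 26,
            "early_stop_patience": 20,
            "augment_d4": ["identity", "rot90", "rot180", "rot270"],
        },
        "infer": {
            "tile_px": 96,
            "overlap": 0.5,
            "threshold": 0.5,
            "use_tta": False,
            "use_reflect_pad": True,
            "closing_px": 1,
        },
        "cls": {
            "tile_um": 128.0,
            "out_px": 224,
            "min_mask_fraction": 0.05,
            "epochs": 20,
            "threshold": 0.5,
            "use_oracle": False,
            "augment_d4": ["identity", "rot90", "rot180", "rot270"],
        },
    }


def _merge(base: dict, override: dict | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _make_slides(cfg: dict, n: int, stream: str) -> list[SyntheticSlide]:
    rng = substream(cfg["seed"], stream)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    scene = dict(cfg["scene"])
    return [generate_scene(SceneConfig(**scene, seed=int(s))) for s in seeds]


def _seg_training_tiles(slides: list[SyntheticSlide], tile_px: int,
                        bg_per_slide: int, seed: int,
                        augment_d4: Sequence[str] = ("identity",)):
    rng = substream(seed, "seg-tiles")
    base = []
    for slide in slides:
        H, W = slide.plane.shape
        for poly in slide.truth_polygons:
            spec = bbox_tile(poly, tile_px, slide.plane)
            base.append((spec.crop(slide.plane.pixels),
                         spec.crop(slide.truth_mask).astype(np.float64)))
        for _ in range(bg_per_slide):
            x = int(rng.integers(0, W - tile_px + 1))
            y = int(rng.integers(0, H - tile_px + 1))
            spec = TileSpec(x, y, tile_px, tile_px)
            base.append((spec.crop(slide.plane.pixels),
                         spec.crop(slide.truth_mask).astype(np.float64)))
    return [(apply_d4(t, img), apply_d4(t, msk))
            for img, msk in base for t in augment_d4]


def _cls_training_data(slides: list[SyntheticSlide], cls_cfg: dict):
    """Tiles cut from truth-mask instances, labeled by planted tumor pixels.

    D4 copies of each tile (per ``augment_d4``) expand the small tile
    set, mirroring the rotation/flip augmentation of the training
    protocol.
    """
    images, labels = [], []
    transforms = cls_cfg.get("augment_d4", ["identity"])
    for slide in slides:
        min_area = default_min_area_px(slide.plane.mpp)
        for inst in extract_instances(slide.truth_mask, min_area):
            for spec, img in make_classifier_inputs(
                    inst, slide.plane, cls_cfg["tile_um"], cls_cfg["out_px"],
                    cls_cfg["min_mask_fraction"]):
                label = int(oracle_tile_prob(slide, spec, inst) >= 0.5)
                for t in transforms:
                    images.append(apply_d4(t, img))
                    labels.append(label)
    return images, labels


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path = "run") -> dict:
    """Execute the full two-stage pipeline on synthetic slides.

    Returns the aggregate metrics dict (also written to
    ``out_dir/metrics.json``); per-slide rows go to ``metrics.csv``,
    per-slide masks/overlays/GeoJSON under ``out_dir/slides/``.
    Reproducible given the config (including its seed).
    """
    cfg = _merge(default_pipeline_config(), config)
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log_lines = [f"pipeline config: {json.dumps(cfg, sort_keys=True)}"]

    train_slides = _make_slides(cfg, cfg["n_train_slides"], "train-scenes")
    val_slides = _make_slides(cfg, cfg["n_val_slides"], "val-scenes")
    test_slides = _make_slides(cfg, cfg["n_test_slides"], "test-scenes")

    # stain normalization: random targets on training planes (augmentation),
    # deterministic mapping to the template mean at validation/inference
    template = fit_stain_stats([s.plane.pixels for s in train_slides])
    norm_rng = substream(cfg["seed"], "stain-targets")
    for slide in train_slides:
        slide.plane.pixels = randstain_normalize(
            slide.plane.pixels, template, seed=int(norm_rng.integers(2**31)))
    for slide in val_slides + test_slides:
        slide.plane.pixels = stain_normalize(slide.plane.pixels, template)

    seg_cfg = cfg["seg"]
    train_tiles = _seg_training_tiles(train_slides, seg_cfg["tile_px"],
                                      seg_cfg["bg_tiles_per_slide"], cfg["seed"],
                                      seg_cfg["augment_d4"])
    val_tiles = _seg_training_tiles(val_slides, seg_cfg["tile_px"], 1, cfg["seed"] + 1)
    model, history = train_segmenter(
        train_tiles, val_tiles,
        SegModelSpec(base_channels=seg_cfg["base_channels"],
                     use_aspp=seg_cfg["use_aspp"]),
        TrainConfig(learning_rate=seg_cfg["learning_rate"],
                    batch_size=seg_cfg["batch_size"],
                    max_epochs=seg_cfg["max_epochs"],
                    lr_decay_factor=seg_cfg["lr_decay_factor"],
                    lr_decay_epoch=seg_cfg["lr_decay_epoch"],
                    early_stop_patience=seg_cfg["early_stop_patience"],
                    seed=cfg["seed"]),
    )
    log_lines.append(f"segmenter trained: {len(history)} epochs, "
                     f"best val IoU {max(h['val_iou'] for h in history):.3f}")

    cls_cfg = cfg["cls"]
    members = []
    if not cls_cfg["use_oracle"]:
        images, labels = _cls_training_data(train_slides + val_slides, cls_cfg)
        for k, spec in enumerate(default_ensemble_specs()):
            members.append(train_classifier_member(
                images, labels, spec, epochs=cls_cfg["epochs"],
                seed=cfg["seed"] + k))
        log_lines.append(f"classifier ensemble trained on {len(images)} tiles "
                         f"({int(np.sum(labels))} positive)")

    inf = cfg["infer"]
    rows = []
    probs_all, truth_all, preds_all = [], [], []
    vessel_probs, vessel_labels = [], []
    planted_counts, detected_oracle_counts = [], []
    for si, slide in enumerate(test_slides):
        prob, binary = predict_slide(model, slide.plane, inf["tile_px"],
                                     inf["overlap"], inf["threshold"],
                                     use_tta=inf["use_tta"],
                                     use_reflect_pad=inf["use_reflect_pad"])
        if inf.get("closing_px"):
            from scipy import ndimage as ndi
            from skimage.morphology import disk

            binary = ndi.binary_closing(binary, structure=disk(inf["closing_px"]))
        min_area = default_min_area_px(slide.plane.mpp)
        instances = extract_instances(binary, min_area)
        if cls_cfg["use_oracle"]:
            verdicts = classify_instances(instances, slide.plane,
                                          oracle_slide=slide,
                                          tile_um=cls_cfg["tile_um"],
                                          out_px=cls_cfg["out_px"],
                                          min_mask_fraction=cls_cfg["min_mask_fraction"],
                                          threshold=cls_cfg["threshold"])
        else:
            verdicts = classify_instances(instances, slide.plane, members=members,
                                          tile_um=cls_cfg["tile_um"],
                                          out_px=cls_cfg["out_px"],
                                          min_mask_fraction=cls_cfg["min_mask_fraction"],
                                          threshold=cls_cfg["threshold"])
        instances, summary = flag_invasion(instances, verdicts, cls_cfg["threshold"])
        sm = seg_metrics(prob, binary, slide.truth_mask, seed=cfg["seed"])
        scores, labels = per_vessel_scores(instances, slide)
        vessel_probs.extend(scores)
        vessel_labels.extend(labels)
        probs_all.append(prob.ravel())
        truth_all.append(slide.truth_mask.ravel())
        preds_all.append(binary.ravel())
        planted = sum(v.state != "clean" for v in slide.vessels)
        planted_counts.append(planted)
        # oracle pass over truth-mask instances: validates count plumbing
        truth_instances = extract_instances(slide.truth_mask, min_area)
        oracle_verdicts = classify_instances(truth_instances, slide.plane,
                                             oracle_slide=slide,
                                             tile_um=cls_cfg["tile_um"],
                                             out_px=cls_cfg["out_px"],
                                             min_mask_fraction=1e-9)
        _, oracle_summary = flag_invasion(truth_instances, oracle_verdicts)
        detected_oracle_counts.append(oracle_summary["n_invasive"])

        name = slide.plane.name
        slide_dir = out / "slides"
        import imageio.v3 as iio

        iio.imwrite(slide_dir / f"{name}-prob.png",
                    (prob * 255).astype(np.uint8))
        iio.imwrite(slide_dir / f"{name}-mask.png",
                    (binary * 255).astype(np.uint8))
        overlay = render_overlay(slide.plane, instances, verdicts)
        iio.imwrite(slide_dir / f"{name}-overlay.png", overlay)
        pred_polys = [p for p in (_instance_polygon(i) for i in instances) if p]
        export_annotations(pred_polys, slide_dir / f"{name}-predictions.geojson")
        rows.append({
            "slide": name, "iou": sm.iou, "fbeta": sm.fbeta, "recall": sm.recall,
            "auc_roc": sm.auc_roc, "n_vessels": summary["n_vessels"],
            "n_invasive": summary["n_invasive"], "planted_invasive": planted,
        })
        log_lines.append(f"slide {si}: IoU {sm.iou:.3f}, "
                         f"{summary['n_invasive']}/{planted} invasive detected")

    pooled_prob = np.concatenate(probs_all)
    pooled_truth = np.concatenate(truth_all)
    pooled_pred = np.concatenate(preds_all)
    sm = seg_metrics(pooled_prob, pooled_pred, pooled_truth, seed=cfg["seed"])
    if len(set(vessel_labels)) == 2:
        cm = cls_metrics(vessel_probs, vessel_labels, cls_cfg["threshold"])
    else:
        cm = ClsMetrics(*([float("nan")] * 5))
    metrics = {
        "iou": sm.iou, "fbeta": sm.fbeta, "recall": sm.recall, "auc_roc": sm.auc_roc,
        "f1": cm.f1, "precision": cm.precision, "sensitivity": cm.sensitivity,
        "specificity": cm.specificity, "cls_auc_roc": cm.auc_roc,
        "planted_invasive_total": int(np.sum(planted_counts)),
        "oracle_detected_invasive_total": int(np.sum(detected_oracle_counts)),
        "n_test_vessels": len(vessel_labels),
        "seed": cfg["seed"],
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    with (out / "metrics.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return metrics
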