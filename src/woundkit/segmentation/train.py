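"""Training loop for the two-stage segmentation pipeline.

Stage 1 learns wound-bed segmentation from RGB; stage 2 learns slough /
necrosis labelling from RGB with out-of-wound pixels zeroed plus the
wound mask as a fourth input channel.  Training minimises pixel
cross-entropy plus (1 - mean soft dice), tracks loss / pixel accuracy /
dice / IoU per epoch on both splits, and stops early when validation
loss has not improved by more than min_delta for `patience` consecutive
epochs (default 10), restoring the best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from skimage.transform import resize as _sk_resize

from ._nn import F32, Adam, ce_dice_loss
from .maps import TissueMap
from .metrics import (mean_foreground_dice, mean_foreground_iou,
                      pixel_accuracy)
from .unet import SegConfig, UNet, build_unet


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    train_dice: List[float] = field(default_factory=list)
    train_iou: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    val_dice: List[float] = field(default_factory=list)
    val_iou: List[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, self.n_epochs + 1),
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "train_dice": self.train_dice, "train_iou": self.train_iou,
            "val_loss": self.val_loss, "val_accuracy": self.val_accuracy,
            "val_dice": self.val_dice, "val_iou": self.val_iou,
        })


def wound_roi_box(mask: np.ndarray, margin: float = 0.15):
    """Square crop box (r0, r1, c0, c1) around a wound mask with margin,
    clipped to the image; None for an empty mask."""
    rr, cc = np.nonzero(mask)
    if len(rr) == 0:
        return None
    h, w = mask.shape
    side = int(np.ceil(max(rr.max() - rr.min(), cc.max() - cc.min()) + 1))
    side = min(max(int(side * (1 + 2 * margin)), 16), max(h, w))
    rc, cctr = (rr.max() + rr.min()) // 2, (cc.max() + cc.min()) // 2
    r0 = int(np.clip(rc - side // 2, 0, max(0, h - side)))
    c0 = int(np.clip(cctr - side // 2, 0, max(0, w - side)))
    return r0, min(r0 + side, h), c0, min(c0 + side, w)


def _roi_resize_rgb(img: np.ndarray, size) -> np.ndarray:
    out = _sk_resize(img.astype(np.float32), size + (img.shape[2],),
                     order=1, preserve_range=True, anti_aliasing=False)
    return out.astype(np.uint8)


def _roi_resize_labels(lab: np.ndarray, size) -> np.ndarray:
    return _sk_resize(lab, size, order=0, preserve_range=True,
                      anti_aliasing=False).astype(lab.dtype)


def extract_roi(images: np.ndarray, masks: np.ndarray,
                tissue: np.ndarray, size) -> tuple:
    """Crop each sample to its wound box and resample to `size`.

    Samples with empty masks are dropped (stage 2 has nothing to label
    there).  Returns (images, masks, tissue, kept_indices)."""
    size = tuple(size)
    out_i, out_m, out_t, kept = [], [], [], []
    for i in range(len(images)):
        box = wound_roi_box(masks[i])
        if box is None:
            continue
        r0, r1, c0, c1 = box
        out_i.append(_roi_resize_rgb(images[i, r0:r1, c0:c1], size))
        out_m.append(_roi_resize_labels(masks[i, r0:r1, c0:c1], size))
        out_t.append(_roi_resize_labels(tissue[i, r0:r1, c0:c1], size))
        kept.append(i)
    if not kept:
        raise ValueError("no samples with a non-empty wound mask")
    return (np.stack(out_i), np.stack(out_m), np.stack(out_t),
            np.asarray(kept))


def stage_inputs(stage: int, images: np.ndarray,
                 wound_masks: Optional[np.ndarray] = None) -> np.ndarray:
    """Network inputs (N, C, H, W) float32 in [0, 1] for a stage.

    Stage 1: RGB.  Stage 2: RGB with out-of-wound pixels zeroed, plus
    the wound mask as a fourth channel.
    """
    x = np.ascontiguousarray(images.transpose(0, 3, 1, 2)).astype(F32) / 255.0
    if stage == 1:
        return x
    if wound_masks is None:
        raise ValueError("stage 2 inputs need wound masks")
    m = wound_masks[:, None].astype(F32)
    return np.concatenate([x * m, m], axis=1)


def stage_targets(stage: int, wound_masks: np.ndarray,
                  tissue: Optional[np.ndarray] = None) -> np.ndarray:
    if stage == 1:
        return wound_masks.astype(np.uint8)
    if tissue is None:
        raise ValueError("stage 2 targets need tissue labels")
    return tissue.astype(np.uint8)


def _eval_split(model: UNet, x: np.ndarray, y: np.ndarray,
                batch_size: int, loss_masks: Optional[np.ndarray] = None
                ) -> Tuple[float, float, float, float]:
    n_classes = len(model.config.classes)
    losses, accs, dices, ious = [], [], [], []
    for i in range(0, len(x), batch_size):
        sl = slice(i, i + batch_size)
        lm = None if loss_masks is None else loss_masks[sl]
        logits = model.forward(x[sl], train=False)
        loss, _, p = ce_dice_loss(logits, y[sl], pixel_mask=lm)
        pred = p.argmax(axis=1)
        if lm is not None:
            pred = np.where(lm, pred, 0)
        losses.append(loss * len(logits))
        for j in range(len(logits)):
            accs.append(pixel_accuracy(pred[j], y[i + j]))
            dices.append(mean_foreground_dice(pred[j], y[i + j], n_classes))
            ious.append(mean_foreground_iou(pred[j], y[i + j], n_classes))
    return (float(np.sum(losses) / len(x)), float(np.mean(accs)),
            float(np.mean(dices)), float(np.mean(ious)))


def train(model: UNet, dataset, config: Optional[SegConfig] = None,
          stage: int = 1, verbose: bool = False) -> Tuple[UNet, TrainHistory]:
    """Train a stage network on a synthetic photo dataset.

    `dataset` is a :class:`woundkit.phantom.Dataset` (or anything with
    the same ``subset(split)`` -> (images, wound_masks, tissue) surface).
    Deterministic for a fixed config seed.  Returns the model with the
    best-validation weights restored, plus the epoch history.
    """
    config = config or model.config
    imgs_tr, masks_tr, tissue_tr = dataset.subset("train")
    imgs_va, masks_va, tissue_va = dataset.subset("val")
    if len(imgs_tr) == 0 or len(imgs_va) == 0:
        raise ValueError("training requires non-empty train and val splits")
    if stage == 2:
        imgs_tr, masks_tr, tissue_tr, _ = extract_roi(
            imgs_tr, masks_tr, tissue_tr, config.input_size)
        imgs_va, masks_va, tissue_va, _ = extract_roi(
            imgs_va, masks_va, tissue_va, config.input_size)
    x_tr = stage_inputs(stage, imgs_tr, masks_tr)
    y_tr = stage_targets(stage, masks_tr, tissue_tr)
    x_va = stage_inputs(stage, imgs_va, masks_va)
    y_va = stage_targets(stage, masks_va, tissue_va)
    # stage 2 scores pixels inside the wound mask only: its output is
    # masked at inference, so out-of-wound pixels carry no training signal
    lm_tr = masks_tr.astype(bool) if stage == 2 else None
    lm_va = masks_va.astype(bool) if stage == 2 else None

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.learning_rate)
    hist = TrainHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    stale = 0
    bs = config.batch_size
    n_classes = len(config.classes)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_acc, ep_dice, ep_iou, seen = 0.0, [], [], [], 0
        for i in range(0, len(order), bs):
            idx = order[i:i + bs]
            logits = model.forward(x_tr[idx], train=True)
            lm = None if lm_tr is None else lm_tr[idx]
            loss, dlogits, p = ce_dice_loss(logits, y_tr[idx], pixel_mask=lm)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
            seen += len(idx)
            pred = p.argmax(axis=1)
            if lm is not None:
                pred = np.where(lm, pred, 0)
            for j, k in enumerate(idx):
                ep_acc.append(pixel_accuracy(pred[j], y_tr[k]))
                ep_dice.append(mean_foreground_dice(pred[j], y_tr[k], n_classes))
                ep_iou.append(mean_foreground_iou(pred[j], y_tr[k], n_classes))
        hist.train_loss.append(ep_loss / seen)
        hist.train_accuracy.append(float(np.mean(ep_acc)))
        hist.train_dice.append(float(np.mean(ep_dice)))
        hist.train_iou.append(float(np.mean(ep_iou)))
        vl, va, vd, vi = _eval_split(model, x_va, y_va, bs, lm_va)
        hist.val_loss.append(vl)
        hist.val_accuracy.append(va)
        hist.val_dice.append(vd)
        hist.val_iou.append(vi)
        if verbose:
            print(f"epoch {epoch}: train loss {hist.train_loss[-1]:.4f} "
                  f"val loss {vl:.4f} val dice {vd:.4f}")
        if best_loss - vl > config.early_stop_min_delta:
            best_loss = vl
            best_weights = model.get_weights()
            hist.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, hist


def segment_wound(model1: UNet, rgb: np.ndarray,
                  largest_component: bool = False,
                  min_area_px: int = 16) -> np.ndarray:
    """Stage-1 inference: binary wound mask from an RGB image.

    Connected components smaller than min_area_px are discarded as
    speckle; largest_component additionally keeps only the biggest blob.
    """
    from scipy import ndimage as _ndi
    single = rgb.ndim == 3
    imgs = rgb[None] if single else rgb
    x = stage_inputs(1, imgs)
    p = model1.predict(x)
    masks = p.argmax(axis=1).astype(bool)
    out = []
    for m in masks:
        lab, n = _ndi.label(m)
        if n:
            sizes = _ndi.sum_labels(m, lab, index=np.arange(1, n + 1))
            if largest_component:
                keep = sizes >= max(min_area_px, sizes.max())
            else:
                keep = sizes >= min_area_px
            m = np.isin(lab, 1 + np.flatnonzero(keep))
        out.append(m)
    masks = np.stack(out)
    return masks[0] if single else masks


def segment_tissue(model2: UNet, rgb: np.ndarray,
                   wound_mask: np.ndarray) -> TissueMap:
    """Stage-2 inference: slough/necrosis labels inside the wound mask.

    Pixels outside the mask are forced to "other"; an empty mask yields
    an empty (all-other) TissueMap.
    """
    wound_mask = np.asarray(wound_mask, dtype=bool)
    if not wound_mask.any():
        return TissueMap(labels=np.zeros(wound_mask.shape, np.uint8),
                         wound_mask=wound_mask)
    r0, r1, c0, c1 = wound_roi_box(wound_mask)
    size = tuple(model2.config.input_size)
    roi_rgb = _roi_resize_rgb(rgb[r0:r1, c0:c1], size)
    roi_mask = _roi_resize_labels(wound_mask[r0:r1, c0:c1], size)
    x = stage_inputs(2, roi_rgb[None], roi_mask[None])
    roi_labels = model2.predict(x).argmax(axis=1)[0].astype(np.uint8)
    labels = np.zeros(wound_mask.shape, np.uint8)
    labels[r0:r1, c0:c1] = _roi_resize_labels(roi_labels,
                                              (r1 - r0, c1 - c0))
    labels[~wound_mask] = 0
    return TissueMap(labels=labels, wound_mask=wound_mask)


def train_two_stage(dataset, seed: int = 0, base_filters: int = 8,
                    stage1_epochs: int = 15, stage2_epochs: int = 12,
                    verbose: bool = False):
    """Train both pipeline stages on one dataset with a shared seed.

    Epoch budgets default to what the synthetic corpus needs on a single
    CPU core: both stages must clear their majority-class plateau, whose
    length varies a few epochs with the initialisation seed.

    Returns (model1, history1, model2, history2).
    """
    m1 = build_unet(SegConfig(base_filters=base_filters,
                              max_epochs=stage1_epochs, seed=seed))
    m1, h1 = train(m1, dataset, stage=1, verbose=verbose)
    from .unet import stage2_config
    m2 = build_unet(stage2_config(base_filters=base_filters,
                                  max_epochs=stage2_epochs, seed=seed))
    m2, h2 = train(m2, dataset, stage=2, verbose=verbose)
    return m1, h1, m2, h2
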