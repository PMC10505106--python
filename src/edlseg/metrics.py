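"""Segmentation and uncertainty evaluation: Dice, brain-masked ECE, sUEO, BraS.

* Dice — spatial overlap ``2|X∩Y| / (|X|+|Y|)``.
* ECE — voxel-count-weighted mean absolute gap between binned confidence
  (``1 - u``) and binned accuracy, restricted to the brain mask so the
  huge, trivially-confident extracranial background does not mask
  miscalibration inside the head.
* sUEO — soft Dice overlap between the continuous uncertainty map and the
  binary segmentation-error map; high when the model places its
  uncertainty exactly where it errs, with no threshold to tune.
* BraS — mean of the area under the confidence-filtered Dice curve and the
  complements of the filtered-true-positive / filtered-true-negative ratio
  curves; rewards uncertainty that is low on correct voxels and high on
  wrong ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evidential import hard_labels, normalized_predictive_entropy
from .fields import LabelField, UncertaintyMap

__all__ = [
    "CalibrationTable",
    "ConfidenceCurves",
    "dice_score",
    "error_map",
    "ece",
    "sueo",
    "confidence_filtered_curves",
    "brats_score",
    "evaluate_case",
]


def _as_binary(arr, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(bool)


def _as_uncertainty(u) -> np.ndarray:
    if isinstance(u, UncertaintyMap):
        return u.values
    u = np.asarray(u, dtype=np.float64)
    if (u < 0).any() or (u > 1).any():
        raise ValueError("uncertainty values must lie in [0, 1]")
    return u


@dataclass(frozen=True)
class CalibrationTable:
    """Per-bin confidence/accuracy/count record behind an ECE value."""

    bin_edges: np.ndarray
    confidence: np.ndarray  # mean member confidence per bin (nan if empty)
    accuracy: np.ndarray
    counts: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ConfidenceCurves:
    """Dice / FTP / FTN versus confidence threshold, with trapezoidal AUCs."""

    thresholds: np.ndarray
    dice_at_tau: np.ndarray
    ftp_at_tau: np.ndarray
    ftn_at_tau: np.ndarray
    auc_dice: float
    auc_ftp: float
    auc_ftn: float
    degenerate_tp: bool = False  # no true positives at tau = 0
    degenerate_tn: bool = False


def dice_score(x, y) -> float:
    """Dice overlap of two binary masks; two empty masks score 1.0."""
    x = _as_binary(x, "mask x")
    y = _as_binary(y, "mask y")
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / total


def error_map(pred, gt) -> np.ndarray:
    """Voxelwise XOR of prediction and ground truth (1 where they disagree)."""
    pred = _as_binary(pred, "prediction")
    gt = _as_binary(gt, "ground truth")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return (pred ^ gt).astype(np.uint8)


def ece(u, pred, gt, brain, n_bins: int = 10):
    """Expected calibration error over brain voxels, with its table.

    Confidence is ``1 - u``; bins are equal-width, half-open ``[lo, hi)``
    with the top bin closed; per-bin confidence is the mean member
    confidence (not the bin midpoint); per-bin accuracy is the fraction of
    voxels where prediction matches ground truth.
    """
    u = _as_uncertainty(u)
    pred = _as_binary(pred, "prediction")
    gt = _as_binary(gt, "ground truth")
    brain = _as_binary(brain, "brain mask")
    if not (u.shape == pred.shape == gt.shape == brain.shape):
        raise ValueError("all inputs must share one shape")
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if not brain.any():
        raise ValueError("empty brain mask")
    conf = 1.0 - u[brain]
    correct = (pred == gt)[brain]
    idx = np.minimum((conf * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    conf_sum = np.bincount(idx, weights=conf, minlength=n_bins)
    acc_sum = np.bincount(idx, weights=correct.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        c_m = conf_sum / counts
        a_m = acc_sum / counts
    n = counts.sum()
    occupied = counts > 0
    value = float(np.sum(counts[occupied] / n * np.abs(c_m - a_m)[occupied]))
    table = CalibrationTable(
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        confidence=c_m,
        accuracy=a_m,
        counts=counts,
    )
    return value, table


def sueo(u, err) -> float:
    """Soft uncertainty-error overlap ``2 Σ e·u / Σ (e² + u²)``.

    Returns 0.0 for the degenerate no-error, no-uncertainty case, which the
    ratio cannot express (a perfect outcome; callers may flag it).
    """
    u = _as_uncertainty(u)
    err = _as_binary(err, "error map").astype(np.float64)
    if u.shape != err.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {err.shape}")
    den = float((err**2).sum() + (u**2).sum())
    if den == 0.0:
        return 0.0
    return float(2.0 * (err * u).sum() / den)


def confidence_filtered_curves(u, pred, gt, tau_grid=None, brain=None) -> ConfidenceCurves:
    """Dice, FTP-ratio and FTN-ratio curves over confidence thresholds.

    At each threshold tau, only voxels with confidence ``1 - u >= tau`` are
    retained.  Dice is computed among retained voxels (carried forward from
    the last non-empty threshold if nothing remains); FTP(tau) and FTN(tau)
    are the fractions of the tau=0 true positives / true negatives that the
    filtering removed.  If a brain mask is given, all counts are restricted
    to it.  AUCs are trapezoidal over the threshold grid.
    """
    u = _as_uncertainty(u)
    pred = _as_binary(pred, "prediction")
    gt = _as_binary(gt, "ground truth")
    if tau_grid is None:
        tau_grid = np.linspace(0.0, 1.0, 101)
    tau_grid = np.asarray(tau_grid, dtype=np.float64)
    if tau_grid.ndim != 1 or (np.diff(tau_grid) <= 0).any():
        raise ValueError("tau grid must be 1-D strictly ascending")
    if tau_grid[0] != 0.0 or tau_grid[-1] > 1.0:
        raise ValueError("tau grid must start at 0 and stay within [0, 1]")
    if brain is not None:
        keep = _as_binary(brain, "brain mask")
        u, pred, gt = u[keep], pred[keep], gt[keep]
    conf = 1.0 - u.ravel()
    pred = pred.ravel()
    gt = gt.ravel()

    tp0 = int((pred & gt).sum())
    tn0 = int((~pred & ~gt).sum())
    degenerate_tp = tp0 == 0
    degenerate_tn = tn0 == 0

    dice_t = np.empty_like(tau_grid)
    ftp_t = np.zeros_like(tau_grid)
    ftn_t = np.zeros_like(tau_grid)
    last_dice = 1.0
    for k, tau in enumerate(tau_grid):
        retain = conf >= tau
        if retain.any():
            last_dice = dice_score(pred[retain], gt[retain])
            tp = int((pred[retain] & gt[retain]).sum())
            tn = int((~pred[retain] & ~gt[retain]).sum())
        else:
            tp = 0
            tn = 0
        dice_t[k] = last_dice
        if not degenerate_tp:
            ftp_t[k] = (tp0 - tp) / tp0
        if not degenerate_tn:
            ftn_t[k] = (tn0 - tn) / tn0

    if tau_grid.size == 1:
        aucs = (float(dice_t[0]), float(ftp_t[0]), float(ftn_t[0]))
    else:
        span = tau_grid[-1] - tau_grid[0]
        aucs = tuple(
            float(np.trapezoid(c, tau_grid) / span) for c in (dice_t, ftp_t, ftn_t)
        )
    return ConfidenceCurves(
        thresholds=tau_grid,
        dice_at_tau=dice_t,
        ftp_at_tau=ftp_t,
        ftn_at_tau=ftn_t,
        auc_dice=aucs[0],
        auc_ftp=aucs[1],
        auc_ftn=aucs[2],
        degenerate_tp=degenerate_tp,
        degenerate_tn=degenerate_tn,
    )


def brats_score(curves: ConfidenceCurves) -> float:
    """``(AUC_Dice + (1 - AUC_FTP) + (1 - AUC_FTN)) / 3``, in [0, 1]."""
    return (curves.auc_dice + (1.0 - curves.auc_ftp) + (1.0 - curves.auc_ftn)) / 3.0


def evaluate_case(
    p,
    gt: LabelField,
    brain=None,
    n_bins: int = 10,
    tau_steps: int = 101,
) -> dict:
    """Bundle Dice / ECE / sUEO / BraS per foreground class, plus the mean.

    ``p`` is an exclusive per-voxel probability tensor (channel-first); the
    uncertainty map is its normalized predictive entropy and the predicted
    mask per class comes from the argmax.  When no brain mask is given, all
    voxels are used.  Background (class 0) is excluded from the per-class
    metrics when K > 2 by convention of foreground-region evaluation; for
    K = 2 the single foreground class is evaluated.
    """
    if not isinstance(gt, LabelField):
        gt = LabelField(onehot=gt)
    p = np.asarray(p, dtype=np.float64)
    if p.shape != gt.onehot.shape:
        raise ValueError("probability and label shapes differ")
    k = p.shape[0]
    u = normalized_predictive_entropy(p).values
    pred_idx = hard_labels(p)
    if brain is None:
        brain_mask = np.ones(p.shape[1:], dtype=bool)
    else:
        brain_mask = _as_binary(brain, "brain mask")
    tau_grid = np.linspace(0.0, 1.0, tau_steps)
    classes = list(range(1, k))
    per_class = {}
    for j in classes:
        pred_j = (pred_idx == j).astype(np.uint8)
        gt_j = gt.onehot[j].astype(np.uint8)
        err = error_map(pred_j, gt_j)
        ece_val, _ = ece(u, pred_j, gt_j, brain_mask, n_bins=n_bins)
        curves = confidence_filtered_curves(u, pred_j, gt_j, tau_grid, brain_mask)
        per_class[j] = {
            "dice": dice_score(pred_j, gt_j),
            "ece": ece_val,
            "sueo": sueo(u, err),
            "bras": brats_score(curves),
            "sueo_degenerate": bool(err.sum() == 0 and (u**2).sum() == 0),
        }
    mean = {
        key: float(np.mean([per_class[j][key] for j in classes]))
        for key in ("dice", "ece", "sueo", "bras")
    }
    return {"per_class": per_class, "mean": mean}
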