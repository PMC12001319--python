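"""Geometric evaluation metrics and differentiable training losses.

Evaluation uses the Dice similarity coefficient (DSC) and the (maximum,
symmetric) Hausdorff distance in millimetres.  Training combines a soft
Dice loss with a distance-transform-weighted squared-error surrogate of the
Hausdorff distance; an epoch-varying weight keeps the Dice term dominant
early in training and brings the boundary term up to a comparable magnitude
once the running DSC clears a gate (default 0.70).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import autograd as ag
from .grids import Mask, require_same_grid

ArrayLike = Union[np.ndarray, Mask]


def _grid(a: ArrayLike) -> np.ndarray:
    return a.grid if isinstance(a, Mask) else np.asarray(a, dtype=bool)


def dsc(a: ArrayLike, b: ArrayLike) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks agree perfectly and score 1 (styles may legitimately
    empty a mask on some subjects).
    """
    ga, gb = _grid(a), _grid(b)
    if ga.shape != gb.shape:
        raise ValueError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    denom = int(ga.sum()) + int(gb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ga & gb).sum()) / denom


def _boundary_points_mm(mask: Mask) -> np.ndarray:
    """Coordinates (mm) of boundary voxels (mask minus its erosion)."""
    g = mask.grid
    interior = ndimage.binary_erosion(g)
    boundary = g & ~interior
    coords = np.argwhere(boundary).astype(np.float64)
    return coords * np.asarray(mask.spacing)


def hausdorff(a: Mask, b: Mask) -> float:
    """Symmetric maximum Hausdorff distance between mask boundaries, in mm."""
    require_same_grid(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("Hausdorff distance is undefined for empty masks")
    pa = _boundary_points_mm(a)
    pb = _boundary_points_mm(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


# ---------------------------------------------------------------------------
# differentiable losses (operate on autograd Tensors)
# ---------------------------------------------------------------------------

def _pred_tensor(pred) -> ag.Tensor:
    t = pred if isinstance(pred, ag.Tensor) else ag.Tensor(pred)
    if t.data.min() < 0.0 or t.data.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return t


def soft_dsc_loss(pred, target: ArrayLike, eps: float = 1.0) -> ag.Tensor:
    """1 − (2Σ p·t + ε) / (Σ p + Σ t + ε) with ε = 1."""
    p = _pred_tensor(pred)
    t = _grid(target).astype(np.float32)
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {t.shape}")
    inter = ag.tsum(ag.mul(p, ag.Tensor(t)))
    total = ag.tsum(p)
    tsum_const = float(t.sum())
    # loss = 1 - (2*inter + eps) / (total + tsum + eps); form the ratio with
    # a custom node so the quotient rule is applied exactly once.
    num = ag.add(ag.mul_scalar(inter, 2.0), ag.Tensor(eps))
    den = ag.add(total, ag.Tensor(tsum_const + eps))
    out = ag.Tensor(1.0 - num.data / den.data, _parents=(num, den))

    def bwd(g):
        ag._accumulate(num, -g / den.data)
        ag._accumulate(den, g * num.data / (den.data * den.data))

    out._bwd = bwd
    return out


def hd_loss(pred, target: ArrayLike, spacing=(1.0, 1.0, 1.0),
            threshold: float = 0.5) -> ag.Tensor:
    """Distance-transform-weighted squared-error Hausdorff surrogate.

    Weighted mean over voxels of (p − t)² with weights
    dt(target)² + dt(pred > threshold)², distances in mm:

        Σ (p − t)²·w / (Σ w + ε)

    The normalization by the total weight keeps the loss in O(1)
    regardless of grid size and voxel spacing (an unnormalized sum is
    unbounded in mm² and destabilizes batch-1 training).  The distance
    maps are treated as constants, so the loss is differentiable in
    ``pred`` everywhere and exactly zero when the prediction equals the
    binary target.
    """
    p = _pred_tensor(pred)
    t = _grid(target)
    if isinstance(target, Mask):
        spacing = target.spacing
    if p.data.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.data.shape} vs {t.shape}")
    pb = p.data > threshold
    # leading singleton (batch/channel) axes get unit sampling
    full_spacing = (1.0,) * (t.ndim - 3) + tuple(spacing)
    diag_mm = float(np.sqrt(sum((n * s) ** 2 for n, s in zip(t.shape, full_spacing))))

    def _dist_to(mask_set: np.ndarray) -> np.ndarray:
        # distance from every voxel to the given set; an empty set is
        # "infinitely" far — use the grid diagonal as a finite stand-in
        if not mask_set.any():
            return np.full(mask_set.shape, diag_mm)
        return ndimage.distance_transform_edt(~mask_set, sampling=full_spacing)

    dt_t = _dist_to(t)
    dt_p = _dist_to(pb)
    w = (dt_t * dt_t + dt_p * dt_p).astype(np.float32)
    diff = ag.add(p, ag.Tensor(-t.astype(np.float32)))
    num = ag.tsum(ag.mul(ag.square(diff), ag.Tensor(w)))
    return ag.mul_scalar(num, 1.0 / (float(w.sum()) + 1.0))


@dataclass(frozen=True)
class LossSchedule:
    """Epoch-varying weight on the Hausdorff surrogate.

    The weight stays at ``hd_weight_floor`` while the running (EMA) batch
    DSC is below ``dsc_gate``; once above the gate it ramps linearly with
    epoch over ``ramp_epochs`` up to ``hd_weight_ceiling``.  The default
    ceiling puts the weighted-mean Hausdorff surrogate (typically
    1e-3…5e-3 in the gated regime) on the same order of magnitude as the
    Dice loss (~0.1), so both terms shape late training.
    """

    hd_weight_floor: float = 0.1
    hd_weight_ceiling: float = 100.0
    dsc_gate: float = 0.70
    ramp_epochs: int = 10

    def __post_init__(self):
        if not (0.0 <= self.hd_weight_floor <= self.hd_weight_ceiling):
            raise ValueError("require 0 <= floor <= ceiling")
        if not (0.0 < self.dsc_gate < 1.0):
            raise ValueError("dsc_gate must be in (0, 1)")

    def weight(self, epoch: int, running_dsc: float) -> float:
        if running_dsc < self.dsc_gate:
            return self.hd_weight_floor
        frac = min(1.0, max(0.0, epoch / max(1, self.ramp_epochs)))
        return self.hd_weight_floor + frac * (self.hd_weight_ceiling - self.hd_weight_floor)


def combined_loss(pred, target: ArrayLike, epoch: int, running_dsc: float,
                  schedule: LossSchedule, spacing=(1.0, 1.0, 1.0)) -> ag.Tensor:
    """soft_dsc_loss + w(epoch, running_dsc) · hd_loss."""
    if not (0.0 <= running_dsc <= 1.0):
        raise ValueError(f"running_dsc must be in [0, 1], got {running_dsc}")
    w = schedule.weight(epoch, running_dsc)
    loss = soft_dsc_loss(pred, target)
    if w > 0.0:
        loss = ag.add(loss, ag.mul_scalar(hd_loss(pred, target, spacing=spacing), w))
    return loss
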