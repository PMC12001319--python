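"""Metric closed forms, brute-force Hausdorff equivalence, loss properties."""

import numpy as np
import pytest

from ddlseg import autograd as ag
from ddlseg.grids import Mask
from ddlseg.metrics import (
    LossSchedule,
    combined_loss,
    dsc,
    hausdorff,
    hd_loss,
    soft_dsc_loss,
)

import oracles

UNIT = (1.0, 1.0, 1.0)


def _mask(grid, spacing=UNIT):
    return Mask(np.asarray(grid, dtype=bool), spacing)


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------

def test_dsc_closed_forms():
    g = np.zeros((6, 6, 6), dtype=bool)
    g[2:4, 2:4, 2:4] = True
    assert dsc(_mask(g), _mask(g)) == 1.0
    other = np.zeros((6, 6, 6), dtype=bool)
    other[0, 0, 0] = True
    assert dsc(_mask(g), _mask(other)) == 0.0
    a = np.zeros((6, 6, 6), dtype=bool)
    a[0, 0, :6] = True  # |A| = 6
    b = np.zeros((6, 6, 6), dtype=bool)
    b[0, 0, :2] = True  # |B| = 2, overlap 2
    assert dsc(_mask(a), _mask(b)) == pytest.approx(0.5)  # 2*2/8


def test_dsc_symmetry_and_empty_convention():
    rng = np.random.default_rng(0)
    a = _mask(rng.random((8, 8, 8)) < 0.3)
    b = _mask(rng.random((8, 8, 8)) < 0.3)
    assert dsc(a, b) == dsc(b, a)
    empty = _mask(np.zeros((8, 8, 8), bool))
    assert dsc(empty, empty) == 1.0
    assert dsc(a, empty) == 0.0
    with pytest.raises(ValueError):
        dsc(a, _mask(np.zeros((4, 4, 4), bool)))


# ---------------------------------------------------------------------------
# Hausdorff
# ---------------------------------------------------------------------------

def test_hausdorff_closed_forms():
    g = np.zeros((8, 8, 8), dtype=bool)
    g[2:5, 2:5, 2:5] = True
    assert hausdorff(_mask(g), _mask(g)) == 0.0
    a = np.zeros((8, 4, 4), dtype=bool)
    a[1, 1, 1] = True
    b = np.zeros((8, 4, 4), dtype=bool)
    b[5, 1, 1] = True  # 4 slices apart
    assert hausdorff(_mask(a), _mask(b)) == pytest.approx(4.0)
    assert hausdorff(
        Mask(a, (2.0, 1.0, 1.0)), Mask(b, (2.0, 1.0, 1.0))
    ) == pytest.approx(8.0)  # spacing scales the same gap


def test_hausdorff_empty_is_error():
    g = np.zeros((6, 6, 6), dtype=bool)
    g[1, 1, 1] = True
    with pytest.raises(ValueError):
        hausdorff(_mask(g), _mask(np.zeros((6, 6, 6), bool)))


@pytest.mark.parametrize("seed", range(10))
def test_hausdorff_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(4, 13, size=3))
    spacing = tuple(rng.uniform(0.5, 2.5, size=3))
    a = rng.random(shape) < 0.25
    b = rng.random(shape) < 0.25
    if not a.any() or not b.any():
        return
    got = hausdorff(Mask(a, spacing), Mask(b, spacing))
    exp = oracles.hausdorff_bf(a, b, spacing)
    assert got == pytest.approx(exp, abs=1e-9)
    assert got == pytest.approx(hausdorff(Mask(b, spacing), Mask(a, spacing)))


# ---------------------------------------------------------------------------
# soft Dice loss
# ---------------------------------------------------------------------------

def test_soft_dsc_loss_limits():
    t = np.zeros((6, 6, 6), dtype=bool)
    t[2:4, 2:4, 2:4] = True
    perfect = soft_dsc_loss(t.astype(np.float32), t).item()
    assert 0.0 <= perfect <= 1.0 / (2 * t.sum() + 1)  # epsilon-bounded
    zero_pred = soft_dsc_loss(np.zeros(t.shape, np.float32), t).item()
    assert zero_pred == pytest.approx(1.0 - 1.0 / (t.sum() + 1))
    with pytest.raises(ValueError):
        soft_dsc_loss(np.full(t.shape, 1.5, np.float32), t)


def test_soft_dsc_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    t = rng.random((4, 4, 4)) < 0.4
    p0 = rng.uniform(0.05, 0.95, size=(4, 4, 4)).astype(np.float32)
    pred = ag.Tensor(p0, requires_grad=True)
    soft_dsc_loss(pred, t).backward()
    eps = 1e-2
    for _ in range(10):
        idx = tuple(rng.integers(0, 4, size=3))
        hi = p0.copy()
        hi[idx] += eps
        lo = p0.copy()
        lo[idx] -= eps
        fd = (soft_dsc_loss(hi, t).item() - soft_dsc_loss(lo, t).item()) / (2 * eps)
        assert pred.grad[idx] == pytest.approx(fd, abs=1e-4)


# ---------------------------------------------------------------------------
# Hausdorff surrogate loss
# ---------------------------------------------------------------------------

def test_hd_loss_zero_at_equality_and_nonnegative():
    rng = np.random.default_rng(2)
    t = rng.random((6, 6, 6)) < 0.3
    assert hd_loss(t.astype(np.float32), t).item() == 0.0
    for _ in range(5):
        p = rng.uniform(0, 1, size=(6, 6, 6)).astype(np.float32)
        assert hd_loss(p, t).item() >= 0.0


def test_hd_loss_increases_with_error_distance():
    t = np.zeros((12, 5, 5), dtype=bool)
    t[0:2] = True
    base = t.astype(np.float32)
    near = base.copy()
    near[4, 2, 2] = 1.0  # false positive 3 slices from the target
    far = base.copy()
    far[10, 2, 2] = 1.0  # same-size error, farther away (in mm)
    l_near = hd_loss(near, t, spacing=UNIT).item()
    l_far = hd_loss(far, t, spacing=UNIT).item()
    assert 0.0 < l_near < l_far


def test_hd_loss_differentiable_in_pred():
    rng = np.random.default_rng(3)
    t = rng.random((5, 5, 5)) < 0.3
    p0 = rng.uniform(0.05, 0.95, size=(5, 5, 5)).astype(np.float32)
    pred = ag.Tensor(p0, requires_grad=True)
    hd_loss(pred, t).backward()
    assert np.isfinite(pred.grad).all()


# ---------------------------------------------------------------------------
# loss schedule / combined loss
# ---------------------------------------------------------------------------

def test_schedule_floor_below_gate():
    s = LossSchedule()
    assert s.weight(epoch=0, running_dsc=0.0) == s.hd_weight_floor
    assert s.weight(epoch=50, running_dsc=0.69) == s.hd_weight_floor


def test_schedule_ceiling_after_ramp():
    s = LossSchedule(ramp_epochs=10)
    assert s.weight(epoch=10, running_dsc=0.9) == s.hd_weight_ceiling
    assert s.weight(epoch=99, running_dsc=0.71) == s.hd_weight_ceiling


def test_schedule_nondecreasing_in_epoch_above_gate():
    s = LossSchedule(ramp_epochs=8)
    weights = [s.weight(e, 0.8) for e in range(0, 20)]
    assert all(b >= a for a, b in zip(weights, weights[1:]))
    assert weights[0] == s.hd_weight_floor
    assert weights[-1] == s.hd_weight_ceiling


def test_schedule_validation():
    with pytest.raises(ValueError):
        LossSchedule(hd_weight_floor=2.0, hd_weight_ceiling=1.0)
    with pytest.raises(ValueError):
        LossSchedule(dsc_gate=1.5)


def test_combined_loss_components():
    rng = np.random.default_rng(4)
    t = rng.random((6, 6, 6)) < 0.3
    p = rng.uniform(0, 1, size=(6, 6, 6)).astype(np.float32)
    s = LossSchedule()
    below = combined_loss(p, t, epoch=3, running_dsc=0.1, schedule=s).item()
    above = combined_loss(p, t, epoch=30, running_dsc=0.9, schedule=s).item()
    dice_only = soft_dsc_loss(p, t).item()
    hd_only = hd_loss(p, t).item()
    assert below == pytest.approx(dice_only + s.hd_weight_floor * hd_only, rel=1e-5)
    assert above == pytest.approx(dice_only + s.hd_weight_ceiling * hd_only, rel=1e-5)
    with pytest.raises(ValueError):
        combined_loss(p, t, 0, running_dsc=1.5, schedule=s)
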