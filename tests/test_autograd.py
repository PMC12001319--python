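"""Gradient checks for the reverse-mode engine against finite differences
and scipy-based forward references.

Finite differences are computed in float32, so the step is chosen large
enough (5e-2) that roundoff does not dominate; tolerances reflect that.
"""

import numpy as np
import pytest
from scipy.ndimage import correlate

from ddlseg import autograd as ag

import oracles

RNG = np.random.default_rng(42)


def fd_gradcheck(build, arrays, eps=5e-2, rtol=5e-3, n_probe=6, rng=None):
    """Compare analytic grads of a scalar-valued builder to central FD."""
    rng = rng or np.random.default_rng(0)
    tensors = [ag.Tensor(a.copy(), requires_grad=True) for a in arrays]
    build(*tensors).backward()
    for ti, a in enumerate(arrays):
        for _ in range(n_probe):
            idx = tuple(rng.integers(0, s) for s in a.shape)
            hi = [x.copy() for x in arrays]
            hi[ti][idx] += eps
            lo = [x.copy() for x in arrays]
            lo[ti][idx] -= eps
            fd = (
                build(*[ag.Tensor(x) for x in hi]).item()
                - build(*[ag.Tensor(x) for x in lo]).item()
            ) / (2 * eps)
            assert tensors[ti].grad[idx] == pytest.approx(
                fd, rel=rtol, abs=5e-3
            ), f"input {ti} at {idx}"


def _x(shape):
    return RNG.standard_normal(shape).astype(np.float32)


# ---------------------------------------------------------------------------
# elementwise, reductions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name,build",
    [
        ("relu", lambda a: ag.tsum(ag.square(ag.relu(a)))),
        ("tanh", lambda a: ag.tsum(ag.square(ag.tanh(a)))),
        ("sigmoid", lambda a: ag.tsum(ag.square(ag.sigmoid(a)))),
        ("mean", lambda a: ag.tmean(ag.square(a))),
        ("mean_over_batch", lambda a: ag.tsum(ag.square(ag.mean_over_batch(a)))),
    ],
)
def test_elementwise_gradients(name, build):
    fd_gradcheck(build, [_x((3, 2, 4, 4, 4))])


def test_mul_add_gradients():
    a, b = _x((2, 3, 4, 4, 4)), _x((2, 3, 4, 4, 4))
    fd_gradcheck(lambda x, y: ag.tsum(ag.mul(x, y)), [a, b])
    fd_gradcheck(lambda x, y: ag.tsum(ag.square(ag.add(x, y))), [a, b])


def test_concat_gradient_and_split():
    a, b = _x((3, 2, 4, 4, 4)), _x((2, 2, 4, 4, 4))
    fd_gradcheck(lambda x, y: ag.tsum(ag.square(ag.concat_channels([x, y]))), [a, b])
    out = ag.concat_channels([ag.Tensor(a), ag.Tensor(b)])
    assert out.data.shape == (5, 2, 4, 4, 4)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("dilation", [1, 2, 3])
def test_conv3d_forward_matches_direct_computation(dilation):
    x = _x((3, 2, 6, 5, 7))
    w = _x((4, 3, 3, 3, 3)) * 0.3
    b = _x(4) * 0.1
    got = ag.conv3d(ag.Tensor(x), ag.Tensor(w), ag.Tensor(b), dilation=dilation).data
    exp = oracles.conv3d_bf(
        x.astype(np.float64), w.astype(np.float64), b.astype(np.float64), dilation
    )
    np.testing.assert_allclose(got, exp, atol=1e-4)


def test_conv3d_dilation1_matches_scipy():
    x = _x((2, 1, 8, 8, 8))
    w = _x((3, 2, 3, 3, 3)) * 0.3
    b = np.zeros(3, np.float32)
    got = ag.conv3d(ag.Tensor(x), ag.Tensor(w), ag.Tensor(b)).data
    for o in range(3):
        ref = sum(
            correlate(x[c, 0].astype(np.float64), w[o, c].astype(np.float64), mode="constant")
            for c in range(2)
        )
        np.testing.assert_allclose(got[o, 0], ref, atol=1e-4)


@pytest.mark.parametrize("dilation", [1, 2, 6])
def test_conv3d_gradients(dilation):
    x = _x((3, 2, 4, 4, 4))
    w = _x((4, 3, 3, 3, 3)) * 0.3
    b = _x(4) * 0.1
    fd_gradcheck(
        lambda X, W, B: ag.tsum(ag.square(ag.conv3d(X, W, B, dilation=dilation))),
        [x, w, b],
    )


def test_conv3d_rejects_wrong_kernel():
    with pytest.raises(ValueError):
        ag.conv3d(ag.Tensor(_x((3, 1, 4, 4, 4))), ag.Tensor(_x((4, 2, 3, 3, 3))),
                  ag.Tensor(np.zeros(4, np.float32)))


# ---------------------------------------------------------------------------
# group norm, pooling, upsampling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("groups", [1, 2, 3])
def test_group_norm_gradients(groups):
    x = _x((6, 2, 3, 3, 3))
    gamma = np.ones(6, np.float32) + 0.1 * _x(6)
    beta = 0.1 * _x(6)
    fd_gradcheck(
        lambda X, G, B: ag.tsum(ag.square(ag.group_norm(X, G, B, groups=groups))),
        [x, gamma, beta],
    )


def test_group_norm_normalizes_per_sample_group():
    x = _x((4, 3, 4, 4, 4)) * 5 + 2
    out = ag.group_norm(
        ag.Tensor(x), ag.Tensor(np.ones(4, np.float32)),
        ag.Tensor(np.zeros(4, np.float32)), groups=2,
    ).data
    per = out.reshape(2, 2, 3, -1)
    np.testing.assert_allclose(per.mean(axis=(1, 3)), 0.0, atol=1e-5)
    np.testing.assert_allclose(per.std(axis=(1, 3)), 1.0, atol=1e-3)


def test_max_pool2_values_and_gradient():
    x = _x((2, 3, 4, 4, 4))
    out = ag.max_pool2(ag.Tensor(x)).data
    assert out.shape == (2, 3, 2, 2, 2)
    for c in range(2):
        for b in range(3):
            assert out[c, b, 0, 0, 0] == x[c, b, :2, :2, :2].max()
    fd_gradcheck(lambda X: ag.tsum(ag.square(ag.max_pool2(X))), [x])
    with pytest.raises(ValueError):
        ag.max_pool2(ag.Tensor(_x((1, 1, 3, 4, 4))))


def test_upsample2_constant_preserved_and_gradient():
    const = np.full((1, 1, 3, 3, 3), 2.5, np.float32)
    out = ag.upsample2(ag.Tensor(const)).data
    assert out.shape == (1, 1, 6, 6, 6)
    np.testing.assert_allclose(out, 2.5, atol=1e-6)
    fd_gradcheck(lambda X: ag.tsum(ag.square(ag.upsample2(X))), [_x((2, 1, 3, 4, 3))])


def test_upsample2_linear_ramp():
    # interior samples of a linear ramp stay on the ramp (align_corners=False)
    x = np.arange(8, dtype=np.float32).reshape(1, 1, 1, 1, 8)
    x = np.broadcast_to(x, (1, 1, 2, 2, 8)).copy()
    out = ag.upsample2(ag.Tensor(x)).data
    inner = out[0, 0, 1, 1, 2:-2]
    steps = np.diff(inner)
    np.testing.assert_allclose(steps, 0.5, atol=1e-6)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def test_adam_descends_quadratic():
    params = {"w": np.array([5.0, -3.0], dtype=np.float32)}
    opt = ag.Adam(params, lr=0.1)
    for _ in range(200):
        opt.step({"w": 2 * params["w"]})
    np.testing.assert_allclose(params["w"], 0.0, atol=1e-2)
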