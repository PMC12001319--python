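"""Shared encoder, difference block and decoder of the style-adaptation net.

The network takes an (image, mask) pair as a 2-channel 3D input.  The
encoder applies, per resolution level: a 3x3x3 convolution, ReLU, group
normalization (32 features per group), and three parallel atrous
convolutions (dilation rates 6, 12, 24) whose outputs are summed, followed
by 2x max pooling; the level-and-pool step runs twice, doubling the channel
count each time, so with ``base_features`` F the pyramid carries F, 2F and
4F channels.

The deep-difference (DDL) block summarizes a contouring style from support
patients entirely in feature space:

    DDL({P_i}, {M_i}) = (1/n) Σ_i tanh(Conv3D_θ( f(P_i) − f(M_i) ))

computed at the deepest level.  The decoder concatenates this style signal
with the query's deepest features and upsamples back to input resolution
(trilinear interpolation + convolution), merging the query's skip features,
ending in a 1-channel sigmoid.  Inference never mutates parameters: with an
empty support set the style signal is a zero grid (the "no adaptation"
baseline).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import autograd as ag
from .grids import Mask, Volume

Params = Dict[str, np.ndarray]


@dataclass(frozen=True)
class ArchSpec:
    """Architecture hyperparameters (scalable; defaults are full scale)."""

    base_features: int = 32
    pool_steps: int = 2
    atrous_rates: Tuple[int, int, int] = (6, 12, 24)
    groupnorm_features_per_group: int = 32
    in_channels: int = 2

    def __post_init__(self):
        if self.pool_steps < 1:
            raise ValueError("pool_steps must be >= 1")
        if any(r < 1 for r in self.atrous_rates):
            raise ValueError("atrous rates must be >= 1")
        object.__setattr__(self, "atrous_rates", tuple(int(r) for r in self.atrous_rates))

    @property
    def level_channels(self) -> Tuple[int, ...]:
        return tuple(self.base_features * 2**l for l in range(self.pool_steps + 1))

    def groups(self, channels: int) -> int:
        return max(1, channels // self.groupnorm_features_per_group)

    def to_json(self) -> str:
        return json.dumps(
            {
                "base_features": self.base_features,
                "pool_steps": self.pool_steps,
                "atrous_rates": list(self.atrous_rates),
                "groupnorm_features_per_group": self.groupnorm_features_per_group,
                "in_channels": self.in_channels,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ArchSpec":
        d = json.loads(s)
        d["atrous_rates"] = tuple(d["atrous_rates"])
        return cls(**d)


@dataclass
class FeaturePyramid:
    """Per-level encoder features; ``levels[-1]`` is the deepest grid."""

    levels: List[ag.Tensor]

    @property
    def deepest(self) -> ag.Tensor:
        return self.levels[-1]


class ModelState:
    """Architecture + all learnable parameters + a content digest.

    The digest is recomputed from the parameter bytes on every call, so it
    changes iff any parameter changes; frozen-inference contracts assert
    digest equality around forward passes.
    """

    def __init__(self, arch: ArchSpec, params: Params):
        self.arch = arch
        self.params = params

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.arch.to_json().encode())
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name], dtype=np.float32).tobytes())
        return h.hexdigest()

    def copy(self) -> "ModelState":
        return ModelState(self.arch, {k: v.copy() for k, v in self.params.items()})

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def init_state(arch: ArchSpec, seed: int = 0) -> ModelState:
    """Seeded fan-in initialization; all biases (incl. the DDL conv bias)
    start at zero so identical support pairs yield a zero style signal."""
    rng = np.random.default_rng(seed)
    p: Params = {}

    def conv(name: str, c_in: int, c_out: int) -> None:
        p[f"{name}_w"] = _he(rng, (c_out, c_in, 3, 3, 3), c_in * 27)
        p[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

    def gn(name: str, c: int) -> None:
        p[f"{name}_gamma"] = np.ones(c, dtype=np.float32)
        p[f"{name}_beta"] = np.zeros(c, dtype=np.float32)

    chans = arch.level_channels
    c_prev = arch.in_channels
    for l, c in enumerate(chans):
        conv(f"enc{l}_conv", c_prev, c)
        gn(f"enc{l}_gn", c)
        for r in arch.atrous_rates:
            conv(f"enc{l}_atrous{r}", c, c)
        c_prev = c

    deep = chans[-1]
    conv("ddl_conv", deep, deep)

    conv(f"dec{len(chans) - 1}_conv", 2 * deep, deep)  # style ++ query deepest
    gn(f"dec{len(chans) - 1}_gn", deep)
    for l in range(len(chans) - 2, -1, -1):
        conv(f"dec{l}_conv", chans[l + 1] + chans[l], chans[l])
        gn(f"dec{l}_gn", chans[l])
    conv("out_conv", chans[0], 1)
    return ModelState(arch, p)


class _Net:
    """Wraps a ModelState's arrays as autograd tensors for one pass."""

    def __init__(self, state: ModelState, trainable: bool):
        self.arch = state.arch
        self.t = {
            k: ag.Tensor(v, requires_grad=trainable) for k, v in state.params.items()
        }

    def grads(self) -> Dict[str, Optional[np.ndarray]]:
        return {k: t.grad for k, t in self.t.items()}

    # -- encoder -----------------------------------------------------------
    def encode_batch(self, x: ag.Tensor) -> List[ag.Tensor]:
        arch = self.arch
        _check_divisible(x.data.shape[2:], arch.pool_steps)
        levels: List[ag.Tensor] = []
        h = x
        for l, c in enumerate(arch.level_channels):
            h = ag.conv3d(h, self.t[f"enc{l}_conv_w"], self.t[f"enc{l}_conv_b"])
            h = ag.relu(h)
            h = ag.group_norm(
                h, self.t[f"enc{l}_gn_gamma"], self.t[f"enc{l}_gn_beta"], arch.groups(c)
            )
            branches = [
                ag.conv3d(h, self.t[f"enc{l}_atrous{r}_w"], self.t[f"enc{l}_atrous{r}_b"], dilation=r)
                for r in arch.atrous_rates
            ]
            h = branches[0]
            for br in branches[1:]:
                h = ag.add(h, br)
            levels.append(h)
            if l < arch.pool_steps:
                h = ag.max_pool2(h)
        return levels

    # -- DDL block ---------------------------------------------------------
    def ddl(self, p_deep: ag.Tensor, m_deep: ag.Tensor) -> ag.Tensor:
        """(4F, k, z, y, x) support features -> (4F, 1, z, y, x) style grid."""
        diff = ag.add(p_deep, ag.mul_scalar(m_deep, -1.0))
        conv = ag.conv3d(diff, self.t["ddl_conv_w"], self.t["ddl_conv_b"])
        return ag.mean_over_batch(ag.tanh(conv))

    # -- decoder -----------------------------------------------------------
    def decode(self, query_levels: Sequence[ag.Tensor], style: ag.Tensor) -> ag.Tensor:
        arch = self.arch
        chans = arch.level_channels
        deep = query_levels[-1]
        if style.data.shape != deep.data.shape:
            raise ValueError(
                f"style grid shape {style.data.shape} does not match deepest "
                f"query features {deep.data.shape}"
            )
        lmax = len(chans) - 1
        h = ag.concat_channels([style, deep])
        h = ag.conv3d(h, self.t[f"dec{lmax}_conv_w"], self.t[f"dec{lmax}_conv_b"])
        h = ag.relu(h)
        h = ag.group_norm(
            h, self.t[f"dec{lmax}_gn_gamma"], self.t[f"dec{lmax}_gn_beta"], arch.groups(chans[lmax])
        )
        for l in range(lmax - 1, -1, -1):
            h = ag.upsample2(h)
            h = ag.concat_channels([h, query_levels[l]])
            h = ag.conv3d(h, self.t[f"dec{l}_conv_w"], self.t[f"dec{l}_conv_b"])
            h = ag.relu(h)
            h = ag.group_norm(
                h, self.t[f"dec{l}_gn_gamma"], self.t[f"dec{l}_gn_beta"], arch.groups(chans[l])
            )
        out = ag.conv3d(h, self.t["out_conv_w"], self.t["out_conv_b"])
        return ag.sigmoid(out)


def _check_divisible(spatial, pool_steps: int) -> None:
    f = 2**pool_steps
    if any(s % f for s in spatial):
        raise ValueError(
            f"spatial dims {tuple(spatial)} must be divisible by {f} "
            f"(pad the volume upstream)"
        )


def _pair_channels(volume: Volume, mask: Mask) -> np.ndarray:
    """Stack (image, mask) as a 2-channel network input; intensities are
    standardized per volume so the network is insensitive to intensity scale.

    Returns (2, Z, Y, X); batches are assembled channel-major as
    (2, B, Z, Y, X).
    """
    img = volume.grid.astype(np.float32)
    sd = img.std()
    img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    return np.stack([img, mask.grid.astype(np.float32)], axis=0)


# ---------------------------------------------------------------------------
# public forward-computation contracts
# ---------------------------------------------------------------------------

def encode(state: ModelState, image: Volume, mask: Mask) -> FeaturePyramid:
    """Encode one (image, mask) pair into the per-level feature pyramid."""
    if image.grid.shape != mask.grid.shape:
        raise ValueError("image and mask are not aligned")
    net = _Net(state, trainable=False)
    x = ag.Tensor(_pair_channels(image, mask)[:, None])  # (2, 1, Z, Y, X)
    return FeaturePyramid(net.encode_batch(x))


def ddl_block(
    state: ModelState,
    support_p_feats: Sequence[FeaturePyramid],
    support_m_feats: Sequence[FeaturePyramid],
) -> ag.Tensor:
    """Average tanh(Conv3D(f(P_i) − f(M_i))) over supports (deepest level)."""
    if len(support_p_feats) == 0 or len(support_p_feats) != len(support_m_feats):
        raise ValueError("support feature lists must be non-empty and equal length")
    net = _Net(state, trainable=False)
    p_deep = ag.Tensor(np.concatenate([f.deepest.data for f in support_p_feats], axis=1))
    m_deep = ag.Tensor(np.concatenate([f.deepest.data for f in support_m_feats], axis=1))
    return net.ddl(p_deep, m_deep)


def decode(state: ModelState, query_feats: FeaturePyramid, style: ag.Tensor) -> np.ndarray:
    """Decode query features + style grid to a probability volume."""
    net = _Net(state, trainable=False)
    if not isinstance(style, ag.Tensor):
        style = ag.Tensor(style)
    out = net.decode(query_feats.levels, style)
    return out.data[0, 0]


def zero_style(state: ModelState, spatial_shape: Tuple[int, int, int]) -> ag.Tensor:
    deep = state.arch.level_channels[-1]
    f = 2**state.arch.pool_steps
    shp = tuple(s // f for s in spatial_shape)
    return ag.Tensor(np.zeros((deep, 1) + shp, dtype=np.float32))


def forward_graph(
    net: _Net,
    query: Tuple[Volume, Mask],
    supports: Sequence[Tuple[Volume, Mask, Mask]],
) -> ag.Tensor:
    """Build the full forward computation graph (shared by train/infer).

    ``supports`` holds (volume, general mask M_i, styled truth P_i) triples;
    query + all support pairs are encoded as one batch for speed.
    """
    q_vol, q_mask = query
    inputs = [_pair_channels(q_vol, q_mask)]
    for vol, m_gen, p_styled in supports:
        if vol.grid.shape != q_vol.grid.shape:
            raise ValueError("support and query grids are not congruent")
        inputs.append(_pair_channels(vol, p_styled))  # f(P_i)
        inputs.append(_pair_channels(vol, m_gen))  # f(M_i)
    batch = ag.Tensor(np.stack(inputs, axis=1))  # (2, B, Z, Y, X)
    levels = net.encode_batch(batch)

    def batch_slice(t: ag.Tensor, sel) -> ag.Tensor:
        """View batch rows (axis 1) of a channel-major tensor; backward adds
        into the parent's gradient region in place."""
        out = ag.Tensor(t.data[:, sel], _parents=(t,))

        def bwd(g, t=t, sel=sel):
            if not t.requires_grad:
                return
            if t.grad is None:
                t.grad = np.zeros_like(t.data)
            t.grad[:, sel] += g

        out._bwd = bwd
        return out

    query_levels = [batch_slice(lv, slice(0, 1)) for lv in levels]
    k = len(supports)
    if k:
        deep = levels[-1]
        p_rows = batch_slice(deep, slice(1, 1 + 2 * k, 2))  # interleaved P, M
        m_rows = batch_slice(deep, slice(2, 2 + 2 * k, 2))
        style = net.ddl(p_rows, m_rows)
    else:
        ds = levels[-1].data.shape
        style = ag.Tensor(np.zeros((ds[0], 1) + ds[2:], dtype=np.float32))
    return net.decode(query_levels, style)


def forward(
    state: ModelState,
    query: Tuple[Volume, Mask],
    supports: Sequence[Tuple[Volume, Mask, Mask]] = (),
) -> np.ndarray:
    """Frozen-weight forward pass -> probability volume in [0, 1].

    With an empty support list the style grid is zero (the no-adaptation
    baseline).  The model state is never mutated.
    """
    net = _Net(state, trainable=False)
    return forward_graph(net, query, supports).data[0, 0]
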