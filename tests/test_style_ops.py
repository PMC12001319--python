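"""Style-operator correctness against brute-force voxel enumeration."""

import numpy as np
import pytest

from ddlseg.grids import Mask
from ddlseg.style_ops import (
    PRESET_STYLES,
    StyleStep,
    StyleTransform,
    apply_style,
    aspect_split,
    cap_extension_into,
    dilate,
    erode,
    exclude_structure,
    extend_into,
    get_style,
    keep_slices_with,
    keep_slices_without,
)

import oracles

UNIT = (1.0, 1.0, 1.0)


def _mask(grid, spacing=UNIT):
    return Mask(np.asarray(grid, dtype=bool), spacing)


def _random_mask(rng, shape=(10, 10, 10), p=0.25, spacing=UNIT):
    return _mask(rng.random(shape) < p, spacing)


# ---------------------------------------------------------------------------
# closed-form / enumerated examples
# ---------------------------------------------------------------------------

def test_dilate_single_voxel_radius2_gives_33_voxels():
    g = np.zeros((9, 9, 9), dtype=bool)
    g[4, 4, 4] = True
    out = dilate(_mask(g), 2)
    assert out.count() == 33  # lattice offsets with squared distance <= 4


def test_erode_cube_radius1_keeps_interior_27():
    g = np.zeros((9, 9, 9), dtype=bool)
    g[2:7, 2:7, 2:7] = True
    out = erode(_mask(g), 1)
    assert out.count() == 27


def test_dilate_erode_edge_cases():
    g = np.zeros((6, 6, 6), dtype=bool)
    g[3, 3, 3] = True
    m = _mask(g)
    assert dilate(m, 0).grid is g  # radius 0 is the identity
    assert erode(m, 1).is_empty()  # single voxel vanishes
    full = _mask(np.ones((6, 6, 6), dtype=bool))
    assert dilate(full, 2).grid.all()  # saturation
    with pytest.raises(ValueError):
        dilate(m, -1)
    with pytest.raises(ValueError):
        erode(m, -1)


def test_keep_slices_with_counts():
    g = np.zeros((10, 6, 6), dtype=bool)
    g[:, 2:4, 2:4] = True  # 4 voxels on each of 10 slices
    ref = np.zeros((10, 6, 6), dtype=bool)
    ref[3:6, 0, 0] = True  # slices 3-5
    out = keep_slices_with(_mask(g), _mask(ref))
    assert out.count() == 12
    assert set(np.flatnonzero(out.grid.any(axis=(1, 2)))) == {3, 4, 5}


def test_keep_slices_with_empty_and_full_ref():
    rng = np.random.default_rng(0)
    m = _random_mask(rng)
    assert keep_slices_with(m, _mask(np.zeros(m.shape, bool))).is_empty()
    assert (keep_slices_with(m, _mask(np.ones(m.shape, bool))).grid == m.grid).all()


def test_keep_slices_without_two_refs():
    g = np.ones((10, 4, 4), dtype=bool)
    r1 = np.zeros((10, 4, 4), dtype=bool)
    r1[0:5] = True
    r2 = np.zeros((10, 4, 4), dtype=bool)
    r2[3:8] = True
    out = keep_slices_without(_mask(g), [_mask(r1), _mask(r2)])
    assert set(np.flatnonzero(out.grid.any(axis=(1, 2)))) == {8, 9}


def test_keep_slices_partition():
    rng = np.random.default_rng(1)
    m = _random_mask(rng)
    r = _random_mask(rng, p=0.05)
    with_r = keep_slices_with(m, r)
    without_r = keep_slices_without(m, [r])
    assert ((with_r.grid | without_r.grid) == m.grid).all()
    assert not (with_r.grid & without_r.grid).any()


def test_keep_slices_errors():
    rng = np.random.default_rng(2)
    m = _random_mask(rng)
    with pytest.raises(ValueError):
        keep_slices_without(m, [])
    with pytest.raises(ValueError):
        keep_slices_with(m, _random_mask(rng, shape=(5, 5, 5)))


def test_extend_into_slab_depth2():
    target = np.zeros((10, 5, 5), dtype=bool)
    target[0:3] = True
    neighbor = np.zeros((10, 5, 5), dtype=bool)
    neighbor[3:10] = True
    out = extend_into(_mask(target), _mask(neighbor), 2.0)
    added = out.grid & ~target
    assert set(np.flatnonzero(added.any(axis=(1, 2)))) == {3, 4}
    assert added[3].all() and added[4].all()


def test_extend_into_trivial_cases():
    rng = np.random.default_rng(3)
    t = _random_mask(rng)
    n = _random_mask(rng)
    assert (extend_into(t, n, 0.0).grid == t.grid).all()
    far = np.zeros((10, 10, 10), dtype=bool)
    far[9, 9, 9] = True
    near = np.zeros((10, 10, 10), dtype=bool)
    near[0, 0, 0] = True
    assert (extend_into(_mask(near), _mask(far), 2.0).grid == near).all()
    with pytest.raises(ValueError):
        extend_into(t, Mask(n.grid, (2.0, 1.0, 1.0)), 1.0)


def test_cap_extension_slab():
    target = np.zeros((9, 5, 5), dtype=bool)
    target[:] = True
    neighbor = np.ones((9, 5, 5), dtype=bool)
    out = cap_extension_into(_mask(target), _mask(neighbor), 2.0)
    expected = oracles.cap_extension_into_bf(target, neighbor, 2.0, UNIT)
    assert (out.grid == expected).all()


def test_cap_extension_depth0_is_set_difference():
    rng = np.random.default_rng(4)
    t = _random_mask(rng)
    n = _random_mask(rng)
    out = cap_extension_into(t, n, 0.0)
    assert (out.grid == (t.grid & ~n.grid)).all()


def test_cap_extension_disjoint_identity():
    t = np.zeros((8, 8, 8), dtype=bool)
    t[0:2] = True
    n = np.zeros((8, 8, 8), dtype=bool)
    n[6:8] = True
    assert (cap_extension_into(_mask(t), _mask(n), 1.0).grid == t).all()


def test_exclude_structure_cases():
    rng = np.random.default_rng(5)
    t = _random_mask(rng, shape=(8, 8, 8))
    o = _random_mask(rng, shape=(8, 8, 8))
    assert (exclude_structure(t, o).grid == (t.grid & ~o.grid)).all()
    assert (exclude_structure(t, _mask(np.zeros((8, 8, 8), bool))).grid == t.grid).all()
    assert exclude_structure(t, _mask(np.ones((8, 8, 8), bool))).is_empty()


def test_aspect_split_cuboid():
    g = np.zeros((14, 6, 6), dtype=bool)
    g[2:12, 1:5, 1:5] = True  # 10-slice cuboid
    out = aspect_split(_mask(g), "superior", 0.5)
    assert set(np.flatnonzero(out.grid.any(axis=(1, 2)))) == set(range(2, 7))
    assert (aspect_split(_mask(g), "superior", 1.0).grid == g).all()
    comp = _mask(g & ~out.grid)
    assert ((out.grid | comp.grid) == g).all()


def test_aspect_split_posterior_and_errors():
    g = np.zeros((6, 12, 6), dtype=bool)
    g[1:5, 2:10, 1:5] = True
    out = aspect_split(_mask(g), "posterior", 0.25)
    assert set(np.flatnonzero(out.grid.any(axis=(0, 2)))) == {8, 9}
    with pytest.raises(ValueError):
        aspect_split(_mask(np.zeros((4, 4, 4), bool)), "superior", 0.5)
    with pytest.raises(ValueError):
        aspect_split(_mask(g), "superior", 0.0)
    with pytest.raises(ValueError):
        aspect_split(_mask(g), "lateral", 0.5)


# ---------------------------------------------------------------------------
# randomized oracle equivalence and invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_morphology_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(5, 13, size=3))
    m = _random_mask(rng, shape=shape, p=0.3)
    for r in (1, 2):
        assert (dilate(m, r).grid == oracles.dilate_bf(m.grid, r)).all()
        assert (erode(m, r).grid == oracles.erode_bf(m.grid, r)).all()


@pytest.mark.parametrize("seed", range(6))
def test_distance_operators_match_voxel_centre_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    spacing = (2.0, 1.0, 1.5)
    t = _random_mask(rng, shape=(8, 8, 8), p=0.2, spacing=spacing)
    n = _random_mask(rng, shape=(8, 8, 8), p=0.3, spacing=spacing)
    depth = float(rng.uniform(0.5, 4.0))
    got = extend_into(t, n, depth)
    exp = oracles.extend_into_bf(t.grid, n.grid, depth, spacing)
    assert (got.grid == exp).all()
    got = cap_extension_into(t, n, depth)
    exp = oracles.cap_extension_into_bf(t.grid, n.grid, depth, spacing)
    assert (got.grid == exp).all()


def test_dilate_erode_monotone_in_radius():
    rng = np.random.default_rng(7)
    m = _random_mask(rng, shape=(12, 12, 12), p=0.15)
    prev_d, prev_e = m, m
    for r in (1, 2, 3):
        d, e = dilate(m, r), erode(m, r)
        assert (d.grid | prev_d.grid).sum() == d.count()  # superset chain
        assert (e.grid & prev_e.grid).sum() == e.count()  # subset chain
        prev_d, prev_e = d, e


def test_closing_contains_original():
    rng = np.random.default_rng(8)
    for seed in range(5):
        m = _random_mask(np.random.default_rng(seed), shape=(12, 12, 12), p=0.1)
        closed = erode(dilate(m, 2), 2)
        assert (closed.grid & m.grid).sum() == m.count()


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def test_apply_style_empty_steps_is_identity(one_subject):
    s = StyleTransform(name="noop", steps=())
    out = apply_style(s, one_subject.structures)
    assert (out.grid == one_subject.structures.target.grid).all()


def test_apply_style_composite_equals_manual(one_subject):
    st = one_subject.structures
    composite = StyleTransform(
        name="combo",
        steps=(
            StyleStep("cap_extension_into", params=(("depth_mm", 10.0),), ref="neighbor_sup"),
            StyleStep("keep_slices_with", ref="ref_a"),
        ),
    )
    got = apply_style(composite, st)
    manual = keep_slices_with(cap_extension_into(st.target, st.neighbor_sup, 10.0), st.ref_a)
    assert (got.grid == manual.grid).all()


def test_apply_style_dilate_then_erode_contains_target(one_subject):
    s = StyleTransform(
        name="close",
        steps=(
            StyleStep("dilate", params=(("radius_px", 2),)),
            StyleStep("erode", params=(("radius_px", 2),)),
        ),
    )
    out = apply_style(s, one_subject.structures)
    t = one_subject.structures.target.grid
    assert (out.grid & t).sum() == t.sum()


def test_apply_style_deterministic_and_errors(one_subject):
    style = get_style("ctv_slices_with_sup_post")
    a = apply_style(style, one_subject.structures)
    b = apply_style(style, one_subject.structures)
    assert (a.grid == b.grid).all()
    bad = StyleTransform(name="bad", steps=(StyleStep("squash", params=()),))
    with pytest.raises(ValueError):
        apply_style(bad, one_subject.structures)
    bad_ref = StyleTransform(
        name="badref", steps=(StyleStep("keep_slices_with", ref="bladder"),)
    )
    with pytest.raises(KeyError):
        apply_style(bad_ref, one_subject.structures)


def test_preset_library_complete_and_valid(one_subject):
    # six target-volume, five parotid-like, five rectum-like, four held-out
    assert len(PRESET_STYLES) == 20
    for name, style in PRESET_STYLES.items():
        out = apply_style(style, one_subject.structures)
        assert out.shape == one_subject.structures.target.shape
        assert out.spacing == one_subject.structures.target.spacing
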