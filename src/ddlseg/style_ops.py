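"""Composable binary-mask operators that simulate contouring styles.

A contouring *style* is a systematic, protocol- or clinician-specific
deviation of a contour from its anatomical definition: dilating or eroding
the boundary, truncating to slices that contain (or lack) a landmark
structure, extending a fixed depth into a neighboring organ, capping such
an extension, excluding another structure, or keeping only the superior or
posterior aspect.  Styles are expressed as ordered step lists
(:class:`StyleTransform`) applied to a subject's anatomical target mask.

Conventions: "pixel"-radius morphology uses a Euclidean ball in voxel units
(spacing is ignored there), while depth-based operators measure millimetres
through spacing-aware Euclidean distance transforms.  Distance ties
(exactly equal to the threshold) are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import Mask, StructureSet, require_same_grid


# ---------------------------------------------------------------------------
# primitive operators
# ---------------------------------------------------------------------------

def ball_footprint(radius_px: int) -> np.ndarray:
    """Voxel offsets with squared Euclidean distance <= radius^2."""
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    r = int(radius_px)
    zz, yy, xx = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zz * zz + yy * yy + xx * xx) <= r * r


def dilate(mask: Mask, radius_px: int) -> Mask:
    """Morphological dilation with a Euclidean ball (voxel units)."""
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    if radius_px == 0:
        return mask
    out = ndimage.binary_dilation(mask.grid, structure=ball_footprint(radius_px))
    return mask.with_grid(out)


def erode(mask: Mask, radius_px: int) -> Mask:
    """Morphological erosion with a Euclidean ball.

    Outside the grid counts as foreground (the usual morphological
    convention for erosion): it keeps closing extensive —
    ``erode(dilate(A, r), r) ⊇ A`` — even for structures touching the
    border.
    """
    if radius_px < 0:
        raise ValueError(f"radius_px must be >= 0, got {radius_px}")
    if radius_px == 0:
        return mask
    out = ndimage.binary_erosion(
        mask.grid, structure=ball_footprint(radius_px), border_value=1
    )
    return mask.with_grid(out)


def keep_slices_with(mask: Mask, ref: Mask) -> Mask:
    """Keep the mask only on axial slices where ``ref`` has any voxel."""
    require_same_grid(mask, ref, spacing=False)
    keep = ref.grid.any(axis=(1, 2))
    return mask.with_grid(mask.grid & keep[:, None, None])


def keep_slices_without(mask: Mask, refs: Sequence[Mask]) -> Mask:
    """Keep the mask only on axial slices where *no* ref has any voxel."""
    if len(refs) == 0:
        raise ValueError("keep_slices_without requires at least one reference mask")
    for ref in refs:
        require_same_grid(mask, ref, spacing=False)
    occupied = np.zeros(mask.grid.shape[0], dtype=bool)
    for ref in refs:
        occupied |= ref.grid.any(axis=(1, 2))
    return mask.with_grid(mask.grid & ~occupied[:, None, None])


def extend_into(target: Mask, neighbor: Mask, depth_mm: float) -> Mask:
    """Add the part of ``neighbor`` lying within ``depth_mm`` (Euclidean,
    voxel centres, spacing-aware) of the target."""
    require_same_grid(target, neighbor)
    if depth_mm < 0:
        raise ValueError(f"depth_mm must be >= 0, got {depth_mm}")
    if depth_mm == 0 or target.is_empty() or neighbor.is_empty():
        return target
    dist = ndimage.distance_transform_edt(~target.grid, sampling=target.spacing)
    return target.with_grid(target.grid | (neighbor.grid & (dist <= depth_mm)))


def cap_extension_into(target: Mask, neighbor: Mask, depth_mm: float) -> Mask:
    """Trim the target inside ``neighbor`` to at most ``depth_mm`` from the
    neighbor's exterior; depth 0 removes the overlap entirely."""
    require_same_grid(target, neighbor)
    if depth_mm < 0:
        raise ValueError(f"depth_mm must be >= 0, got {depth_mm}")
    if neighbor.is_empty():
        return target
    # pad with background so off-grid counts as the neighbor's exterior
    # (otherwise a neighbor filling the grid would have no reference zeros)
    padded = np.pad(neighbor.grid, 1)
    inside = ndimage.distance_transform_edt(padded, sampling=neighbor.spacing)[
        1:-1, 1:-1, 1:-1
    ]
    remove = target.grid & neighbor.grid & (inside > depth_mm)
    return target.with_grid(target.grid & ~remove)


def exclude_structure(target: Mask, other: Mask) -> Mask:
    """Set difference ``target \\ other``."""
    require_same_grid(target, other, spacing=False)
    return target.with_grid(target.grid & ~other.grid)


def aspect_split(mask: Mask, axis: str, keep_fraction: float = 0.5) -> Mask:
    """Keep the superior (low axis-0 index) or posterior (high axis-1 index)
    fraction of the mask's own bounding box along that axis."""
    if mask.is_empty():
        raise ValueError("aspect_split requires a non-empty mask")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if axis not in ("superior", "posterior"):
        raise ValueError(f"axis must be 'superior' or 'posterior', got {axis!r}")
    ax = 0 if axis == "superior" else 1
    other_axes = tuple(i for i in range(3) if i != ax)
    occupied = np.flatnonzero(mask.grid.any(axis=other_axes))
    lo, hi = occupied[0], occupied[-1]
    extent = hi - lo + 1
    n_keep = int(np.floor(keep_fraction * extent))
    sel = np.zeros(mask.grid.shape[ax], dtype=bool)
    if axis == "superior":
        sel[lo : lo + n_keep] = True  # low indices = superior
    else:
        sel[hi + 1 - n_keep : hi + 1] = True  # high axis-1 indices = posterior
    shape = [1, 1, 1]
    shape[ax] = mask.grid.shape[ax]
    return mask.with_grid(mask.grid & sel.reshape(shape))


# ---------------------------------------------------------------------------
# style transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StyleStep:
    op: str
    params: Tuple[Tuple[str, object], ...] = ()
    ref: Optional[str] = None  # structure name, for operators that need one

    def kwargs(self) -> dict:
        return dict(self.params)


@dataclass(frozen=True)
class StyleTransform:
    """A named, ordered, deterministic composition of mask operators."""

    name: str
    steps: Tuple[StyleStep, ...]

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))


_REF_OPS = {"keep_slices_with", "extend_into", "cap_extension_into", "exclude_structure"}
_OPS = _REF_OPS | {"dilate", "erode", "keep_slices_without", "aspect_split"}


def apply_style(transform: StyleTransform, structures: StructureSet) -> Mask:
    """Fold the transform's steps, starting from ``structures.target``."""
    mask = structures.target
    for step in transform.steps:
        if step.op not in _OPS:
            raise ValueError(f"unknown style operator {step.op!r}")
        kw = step.kwargs()
        if step.op in _REF_OPS:
            ref = structures[step.ref]  # KeyError surfaces unknown names
            if step.op == "keep_slices_with":
                mask = keep_slices_with(mask, ref)
            elif step.op == "extend_into":
                mask = extend_into(mask, ref, **kw)
            elif step.op == "cap_extension_into":
                mask = cap_extension_into(mask, ref, **kw)
            else:
                mask = exclude_structure(mask, ref)
        elif step.op == "keep_slices_without":
            refs = [structures[name] for name in kw["refs"]]
            mask = keep_slices_without(mask, refs)
        elif step.op == "dilate":
            mask = dilate(mask, **kw)
        elif step.op == "erode":
            mask = erode(mask, **kw)
        elif step.op == "aspect_split":
            mask = aspect_split(mask, **kw)
    return mask


def _style(name: str, *steps: StyleStep) -> StyleTransform:
    return StyleTransform(name=name, steps=steps)


def _step(op: str, ref: Optional[str] = None, **params) -> StyleStep:
    return StyleStep(op=op, params=tuple(sorted(params.items())), ref=ref)


# Shipped preset library.  The three training families mirror the style
# augmentations used for target-volume, parotid-like and rectum-like
# structures (dilation/erosion by 2 px, slice conditioning on landmarks,
# fixed-depth extension into neighbors); the held-out presets define test
# styles never seen during meta-training.
PRESET_STYLES: Dict[str, StyleTransform] = {
    s.name: s
    for s in [
        # -- target-volume family (bladder-like neighbor_sup, rectum-like
        #    neighbor_post) --
        _style("ctv_dilate_2px", _step("dilate", radius_px=2)),
        _style("ctv_erode_2px", _step("erode", radius_px=2)),
        _style("ctv_exclude_sup", _step("cap_extension_into", ref="neighbor_sup", depth_mm=0.0)),
        _style("ctv_into_sup_30mm", _step("extend_into", ref="neighbor_sup", depth_mm=30.0)),
        _style("ctv_into_post_20mm", _step("extend_into", ref="neighbor_post", depth_mm=20.0)),
        _style(
            "ctv_slices_with_sup_post",
            _step("keep_slices_with", ref="neighbor_sup"),
            _step("keep_slices_with", ref="neighbor_post"),
        ),
        # -- parotid-like family (masseter-like ref_a, spinal-canal-like ref_b) --
        _style("parotid_dilate_2px", _step("dilate", radius_px=2)),
        _style("parotid_erode_2px", _step("erode", radius_px=2)),
        _style("parotid_slices_with_ref_a", _step("keep_slices_with", ref="ref_a")),
        _style("parotid_slices_with_ref_b", _step("keep_slices_with", ref="ref_b")),
        _style("parotid_slices_without_refs", _step("keep_slices_without", refs=("ref_a", "ref_b"))),
        # -- rectum-like family (bladder-like neighbor_sup, prostate-like ref_a) --
        _style("rectum_dilate_2px", _step("dilate", radius_px=2)),
        _style("rectum_erode_2px", _step("erode", radius_px=2)),
        _style("rectum_slices_with_sup", _step("keep_slices_with", ref="neighbor_sup")),
        _style("rectum_slices_with_ref_a", _step("keep_slices_with", ref="ref_a")),
        _style(
            "rectum_slices_without_sup_ref_a",
            _step("keep_slices_without", refs=("ref_a", "neighbor_sup")),
        ),
        # -- held-out test styles --
        _style("test_cap_sup_10mm", _step("cap_extension_into", ref="neighbor_sup", depth_mm=10.0)),
        _style("test_into_post_10mm", _step("extend_into", ref="neighbor_post", depth_mm=10.0)),
        _style("test_exclude_ref_b", _step("exclude_structure", ref="ref_b")),
        _style("test_superior_half", _step("aspect_split", axis="superior", keep_fraction=0.5)),
    ]
}

HELDOUT_STYLE_NAMES: Tuple[str, ...] = (
    "test_cap_sup_10mm",
    "test_into_post_10mm",
    "test_exclude_ref_b",
    "test_superior_half",
)

TRAIN_STYLE_NAMES: Tuple[str, ...] = tuple(
    n for n in PRESET_STYLES if n not in HELDOUT_STYLE_NAMES
)


def get_style(name: str) -> StyleTransform:
    if name not in PRESET_STYLES:
        raise KeyError(f"unknown style {name!r}; known: {sorted(PRESET_STYLES)}")
    return PRESET_STYLES[name]


def styles_from_config(entries: List[dict]) -> List[StyleTransform]:
    """Build style transforms from a structured config (e.g. parsed YAML).

    Each entry: ``{"name": ..., "steps": [{"op": ..., "ref": ...,
    <param>: <value>, ...}, ...]}``.
    """
    out = []
    for entry in entries:
        steps = []
        for raw in entry["steps"]:
            raw = dict(raw)
            op = raw.pop("op")
            ref = raw.pop("ref", None)
            steps.append(StyleStep(op=op, params=tuple(sorted(raw.items())), ref=ref))
        out.append(StyleTransform(name=entry["name"], steps=tuple(steps)))
    return out
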