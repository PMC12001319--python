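"""Voxel-grid containers shared by every other module.

Axis convention (fixed throughout the package):

* axis 0 — axial slices, increasing index = superior → **inferior**;
* axis 1 — anterior → **posterior**;
* axis 2 — left → right.

Spacing is always the per-axis voxel size in millimetres, ordered the same
way as the array axes ``(sz, sy, sx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Tuple

import numpy as np

Spacing = Tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive floats, got {spacing!r}")
    return spacing


@dataclass(frozen=True)
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    Parameters
    ----------
    grid
        ``(Z, Y, X)`` array of intensities; stored as float32.
    spacing
        Voxel size ``(sz, sy, sx)`` in mm.
    """

    grid: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float32)
        if grid.ndim != 3:
            raise ValueError(f"Volume grid must be 3D, got shape {grid.shape}")
        if not np.all(np.isfinite(grid)):
            raise ValueError("Volume grid contains non-finite values")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class Mask:
    """A 3D boolean structure mask aligned with a parent :class:`Volume`."""

    grid: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.dtype != bool:
            if not np.isin(grid, (0, 1)).all():
                raise ValueError("Mask grid must be boolean or 0/1 valued")
            grid = grid.astype(bool)
        if grid.ndim != 3:
            raise ValueError(f"Mask grid must be 3D, got shape {grid.shape}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.grid.shape

    def count(self) -> int:
        return int(self.grid.sum())

    def is_empty(self) -> bool:
        return not self.grid.any()

    def with_grid(self, grid: np.ndarray) -> "Mask":
        """Same spacing, new voxel content (shape must be preserved)."""
        if grid.shape != self.grid.shape:
            raise ValueError(f"shape changed: {grid.shape} vs {self.grid.shape}")
        return Mask(grid=grid, spacing=self.spacing)


def require_same_grid(a, b, *, spacing: bool = True) -> None:
    """Raise ValueError unless two grid objects share shape (and spacing)."""
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"shape mismatch: {a.grid.shape} vs {b.grid.shape}")
    if spacing and tuple(a.spacing) != tuple(b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


@dataclass(frozen=True)
class StructureSet:
    """Named structure masks of one phantom subject.

    ``target`` is the structure whose contouring style is adapted;
    ``neighbor_sup`` / ``neighbor_post`` abut or overlap it from the
    superior / posterior side (so "into neighbor" styles are non-trivial);
    ``ref_a`` / ``ref_b`` each occupy a proper subset of the axial slices
    and act as landmark structures for slice-conditioned styles.
    """

    target: Mask
    neighbor_sup: Mask
    neighbor_post: Mask
    ref_a: Mask
    ref_b: Mask

    NAMES = ("target", "neighbor_sup", "neighbor_post", "ref_a", "ref_b")

    def __iter__(self) -> Iterator[Tuple[str, Mask]]:
        for name in self.NAMES:
            yield name, getattr(self, name)

    def __getitem__(self, name: str) -> Mask:
        if name not in self.NAMES:
            raise KeyError(f"unknown structure {name!r}; known: {self.NAMES}")
        return getattr(self, name)

    def validate(self) -> None:
        """Check the geometric contract; raise ValueError on violation."""
        from scipy.ndimage import binary_dilation

        masks = dict(self)
        first = self.target
        for name, m in masks.items():
            require_same_grid(first, m)
        if self.target.is_empty():
            raise ValueError("target mask is empty")
        halo = binary_dilation(self.target.grid)
        for name in ("neighbor_sup", "neighbor_post"):
            if not (halo & masks[name].grid).any():
                raise ValueError(f"target does not abut or overlap {name}")
        nz = self.target.grid.shape[0]
        slices = {}
        for name in ("ref_a", "ref_b"):
            occupied = masks[name].grid.any(axis=(1, 2))
            if not occupied.any() or occupied.all():
                raise ValueError(f"{name} must occupy a proper non-empty subset of slices")
            slices[name] = tuple(np.flatnonzero(occupied))
        if slices["ref_a"] == slices["ref_b"]:
            raise ValueError("ref_a and ref_b occupy identical slice ranges")


@dataclass(frozen=True)
class PhantomSubject:
    """One synthetic patient: image, structures, and the simulated
    general-model segmentation of the target."""

    volume: Volume
    structures: StructureSet
    general_mask: Mask
    subject_id: str
    seed: int
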