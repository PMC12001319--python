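"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — explicit offset enumeration and
voxel-centre distance loops — so it cannot share a code path (or a bug)
with the package's scipy-based implementations.
"""

import numpy as np


def ball_offsets(radius):
    offs = []
    r = int(radius)
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dz * dz + dy * dy + dx * dx <= r * r:
                    offs.append((dz, dy, dx))
    return offs


def dilate_bf(grid, radius):
    """Voxel is set iff any ball offset lands on a set input voxel."""
    Z, Y, X = grid.shape
    out = np.zeros_like(grid)
    for z, y, x in zip(*np.nonzero(grid)):
        for dz, dy, dx in ball_offsets(radius):
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < Z and 0 <= yy < Y and 0 <= xx < X:
                out[zz, yy, xx] = True
    return out


def erode_bf(grid, radius):
    """Voxel survives iff every in-grid ball offset stays inside the mask
    (out-of-grid counts as foreground, matching the erosion convention)."""
    Z, Y, X = grid.shape
    out = np.zeros_like(grid)
    for z, y, x in zip(*np.nonzero(grid)):
        keep = True
        for dz, dy, dx in ball_offsets(radius):
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < Z and 0 <= yy < Y and 0 <= xx < X and not grid[zz, yy, xx]:
                keep = False
                break
        if keep:
            out[z, y, x] = True
    return out


def keep_slices_with_bf(grid, ref):
    out = np.zeros_like(grid)
    for z in range(grid.shape[0]):
        if ref[z].any():
            out[z] = grid[z]
    return out


def keep_slices_without_bf(grid, refs):
    out = np.zeros_like(grid)
    for z in range(grid.shape[0]):
        if not any(r[z].any() for r in refs):
            out[z] = grid[z]
    return out


def _coords_mm(grid, spacing):
    return np.argwhere(grid).astype(float) * np.asarray(spacing)


def extend_into_bf(target, neighbor, depth_mm, spacing):
    """Add neighbor voxels whose centre lies within depth of any target
    voxel centre (ties included)."""
    out = target.copy()
    if depth_mm <= 0 or not target.any():
        return out
    tpts = _coords_mm(target, spacing)
    for z, y, x in zip(*np.nonzero(neighbor)):
        p = np.array([z, y, x], dtype=float) * np.asarray(spacing)
        if np.sqrt(((tpts - p) ** 2).sum(axis=1)).min() <= depth_mm:
            out[z, y, x] = True
    return out


def cap_extension_into_bf(target, neighbor, depth_mm, spacing):
    """Remove target voxels inside the neighbor whose distance to the
    neighbor's exterior exceeds depth (exterior includes off-grid)."""
    out = target.copy()
    Z, Y, X = target.shape
    ext = ~neighbor
    epts = _coords_mm(ext, spacing) if ext.any() else np.empty((0, 3))
    sp = np.asarray(spacing)
    for z, y, x in zip(*np.nonzero(target & neighbor)):
        p = np.array([z, y, x], dtype=float) * sp
        dists = []
        if epts.size:
            dists.append(np.sqrt(((epts - p) ** 2).sum(axis=1)).min())
        # distance to the nearest point outside the grid along each axis
        dists.append((z + 1) * sp[0])
        dists.append((Z - z) * sp[0])
        dists.append((y + 1) * sp[1])
        dists.append((Y - y) * sp[1])
        dists.append((x + 1) * sp[2])
        dists.append((X - x) * sp[2])
        if min(dists) > depth_mm:
            out[z, y, x] = False
    return out


def aspect_split_bf(grid, axis_name, frac):
    occ_axes = {"superior": 0, "posterior": 1}[axis_name]
    other = tuple(i for i in range(3) if i != occ_axes)
    occupied = np.flatnonzero(grid.any(axis=other))
    lo, hi = occupied[0], occupied[-1]
    n_keep = int(np.floor(frac * (hi - lo + 1)))
    out = np.zeros_like(grid)
    if axis_name == "superior":
        idx = range(lo, lo + n_keep)
    else:
        idx = range(hi + 1 - n_keep, hi + 1)
    for i in idx:
        if axis_name == "superior":
            out[i] = grid[i]
        else:
            out[:, i] = grid[:, i]
    return out


def boundary_points_bf(grid, spacing):
    """Voxel centres (mm) of mask voxels with a 6-neighbour outside the
    mask (off-grid counts as outside)."""
    Z, Y, X = grid.shape
    pts = []
    for z, y, x in zip(*np.nonzero(grid)):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < Z and 0 <= yy < Y and 0 <= xx < X) or not grid[zz, yy, xx]:
                pts.append((z * spacing[0], y * spacing[1], x * spacing[2]))
                break
    return np.array(pts)


def hausdorff_bf(a, b, spacing):
    pa = boundary_points_bf(a, spacing)
    pb = boundary_points_bf(b, spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def conv3d_bf(x, w, bias, dilation=1):
    """Direct 6-loop dilated convolution with zero padding; float64."""
    C, B, D, H, W = x.shape
    O = w.shape[0]
    y = np.zeros((O, B, D, H, W))
    for o in range(O):
        y[o] = bias[o]
        for c in range(C):
            for kz in (-1, 0, 1):
                for ky in (-1, 0, 1):
                    for kx in (-1, 0, 1):
                        wv = w[o, c, kz + 1, ky + 1, kx + 1]
                        if wv == 0:
                            continue
                        shifted = np.zeros((B, D, H, W))
                        z0 = max(0, -kz * dilation)
                        z1 = D - max(0, kz * dilation)
                        y0 = max(0, -ky * dilation)
                        y1 = H - max(0, ky * dilation)
                        x0 = max(0, -kx * dilation)
                        x1 = W - max(0, kx * dilation)
                        if z1 <= z0 or y1 <= y0 or x1 <= x0:
                            continue
                        shifted[:, z0:z1, y0:y1, x0:x1] = x[
                            c,
                            :,
                            z0 + kz * dilation : z1 + kz * dilation,
                            y0 + ky * dilation : y1 + ky * dilation,
                            x0 + kx * dilation : x1 + kx * dilation,
                        ]
                        y[o] += wv * shifted
    return y
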