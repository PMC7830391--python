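"""Exact ray/voxel intersection-length tracing (Siddon-style).

Rays are straight segments in world coordinates; the image grid is centred
on the origin with voxel centres at ``(i + 0.5 - n/2) * voxel_size``.  For
each ray the parametric crossings with every grid plane are computed, sorted
and converted into per-voxel chord lengths, yielding the sparse rows of the
system matrix.  Forward and back projection built on these entries form an
exactly matched (adjoint) operator pair.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["trace_rays", "rays_to_matrix"]

# Relative threshold below which a direction component is treated as
# axis-parallel (no crossings with that family of planes).
_DIR_EPS = 1e-12
# Parametric length below which a segment between consecutive crossings is
# dropped (duplicate planes at voxel corners).
_ALPHA_EPS = 1e-14


def trace_rays(
    p0: np.ndarray,
    p1: np.ndarray,
    shape: tuple[int, ...],
    voxel_size: tuple[float, ...],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersection lengths of segments ``p0 -> p1`` with a centred grid.

    Parameters
    ----------
    p0, p1
        Arrays of shape ``(n_rays, ndim)`` with segment end points in mm.
    shape
        Voxel counts per world axis.
    voxel_size
        Voxel edge length (mm) per world axis.

    Returns
    -------
    rows, cols, lengths
        COO-style triplets: ray index, flat (C-order) voxel index and the
        chord length (mm) of the ray inside that voxel.  Duplicate
        ``(row, col)`` pairs may occur and must be summed by the caller.
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=np.float64))
    p1 = np.atleast_2d(np.asarray(p1, dtype=np.float64))
    if p0.shape != p1.shape:
        raise ValueError("p0 and p1 must have identical shapes")
    n_rays, ndim = p0.shape
    if len(shape) != ndim or len(voxel_size) != ndim:
        raise ValueError("shape/voxel_size rank does not match ray dimension")

    d = p1 - p0
    seg_len = np.sqrt((d * d).sum(axis=1))

    amin = np.zeros(n_rays)
    amax = np.ones(n_rays)
    plane_alpha: list[np.ndarray] = []
    for ax in range(ndim):
        n_ax = shape[ax]
        vox = float(voxel_size[ax])
        planes = (np.arange(n_ax + 1) - n_ax / 2.0) * vox
        da = d[:, ax]
        pa = p0[:, ax]
        nz = np.abs(da) > _DIR_EPS * np.maximum(seg_len, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            al = (planes[None, :] - pa[:, None]) / da[:, None]
        lo = np.where(nz, np.minimum(al[:, 0], al[:, -1]), 0.0)
        hi = np.where(nz, np.maximum(al[:, 0], al[:, -1]), 1.0)
        # Axis-parallel ray outside the slab never enters the volume.
        inside = (pa > planes[0]) & (pa < planes[-1])
        hi = np.where(~nz & ~inside, -np.inf, hi)
        amin = np.maximum(amin, lo)
        amax = np.minimum(amax, hi)
        plane_alpha.append(np.where(nz[:, None], al, 0.0))

    alpha = np.concatenate(plane_alpha + [amin[:, None], amax[:, None]], axis=1)
    lo_b = amin[:, None]
    hi_b = np.maximum(amax, amin)[:, None]  # missing rays collapse to a point
    np.clip(alpha, lo_b, hi_b, out=alpha)
    alpha.sort(axis=1)

    diff = np.diff(alpha, axis=1)
    mid = 0.5 * (alpha[:, :-1] + alpha[:, 1:])
    keep = diff > _ALPHA_EPS
    if not keep.any():
        empty = np.empty(0)
        return empty.astype(np.int64), empty.astype(np.int64), empty

    idx_per_axis = []
    for ax in range(ndim):
        coord = p0[:, ax][:, None] + mid * d[:, ax][:, None]
        ia = np.floor(coord / voxel_size[ax] + shape[ax] / 2.0).astype(np.int64)
        np.clip(ia, 0, shape[ax] - 1, out=ia)
        idx_per_axis.append(ia[keep])

    rows = np.broadcast_to(np.arange(n_rays)[:, None], diff.shape)[keep]
    cols = np.ravel_multi_index(idx_per_axis, shape)
    lengths = (diff * seg_len[:, None])[keep]
    return rows.astype(np.int64), cols.astype(np.int64), lengths


def rays_to_matrix(
    p0: np.ndarray,
    p1: np.ndarray,
    shape: tuple[int, ...],
    voxel_size: tuple[float, ...],
) -> sparse.csr_matrix:
    """Sparse ``(n_rays, n_voxels)`` intersection-length matrix."""
    rows, cols, lengths = trace_rays(p0, p1, shape, voxel_size)
    n_rays = int(np.atleast_2d(p0).shape[0])
    n_vox = int(np.prod(shape))
    mat = sparse.coo_matrix(
        (lengths, (rows, cols)), shape=(n_rays, n_vox), dtype=np.float64
    )
    return mat.tocsr()  # duplicate entries are summed here
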