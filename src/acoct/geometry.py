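"""Scan geometry and matched forward/back projection operators.

The system matrix ``A`` holds exact ray-voxel intersection lengths and is
assembled lazily per view angle (sparse CSR, cached per geometry).  Forward
projection, back projection and the SART normalisation diagonals all reuse
the same entries, so the pair (``forward_project``, ``back_project``) is an
exact adjoint.

Conventions
-----------
* Volume arrays are indexed ``[i0, i1(, i2)]`` with array axis ``k`` mapped
  to world axis ``k``; voxel centres sit at ``(i + 0.5 - n/2) * voxel_size``.
* View angles are degrees, counter-clockwise from the +x axis.
* ``parallel2d``: detector axis ``u = (-sin t, cos t)``, rays run along
  ``(cos t, sin t)``.
* ``fan2d`` / ``cone3d``: point source at ``-dso * (cos t, sin t)``, flat
  detector centred on the ray through the origin at distance ``dsd`` from
  the source; ``cone3d`` adds the world z axis as detector row axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from ._siddon import rays_to_matrix

__all__ = [
    "ScanGeometry",
    "ImageVolume",
    "ProjectionSet",
    "make_angles",
    "parallel_geometry",
    "fan_geometry",
    "system_matrix",
    "forward_project",
    "back_project",
    "sart_weights",
]

BEAM_MODES = ("parallel2d", "fan2d", "cone3d")


def make_angles(span_degrees: float, n_views: int, start: float = 0.0) -> tuple[float, ...]:
    """Equally spaced view angles over a half-open span.

    ``n_views`` angles starting at ``start`` with increment
    ``span_degrees / n_views`` (the end angle is excluded, so a 360-degree
    span never duplicates the first view).
    """
    if n_views < 1:
        raise ValueError(f"n_views must be >= 1, got {n_views}")
    if not span_degrees > 0:
        raise ValueError(f"span_degrees must be positive, got {span_degrees}")
    inc = span_degrees / n_views
    return tuple(start + inc * k for k in range(n_views))


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition description defining the system operator A."""

    beam_mode: str
    angles: tuple[float, ...]
    volume_shape: tuple[int, ...]
    voxel_size: tuple[float, ...]
    detector_pixel_counts: tuple[int, ...]
    detector_pixel_pitch: tuple[float, ...]
    source_to_origin: float | None = None
    source_to_detector: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", tuple(float(a) for a in self.angles))
        object.__setattr__(self, "volume_shape", tuple(int(n) for n in self.volume_shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(
            self, "detector_pixel_counts", tuple(int(n) for n in self.detector_pixel_counts)
        )
        object.__setattr__(
            self, "detector_pixel_pitch", tuple(float(p) for p in self.detector_pixel_pitch)
        )
        if self.beam_mode not in BEAM_MODES:
            raise ValueError(f"beam_mode must be one of {BEAM_MODES}, got {self.beam_mode!r}")
        ndim = 3 if self.beam_mode == "cone3d" else 2
        det_ndim = ndim - 1
        if len(self.volume_shape) != ndim or len(self.voxel_size) != ndim:
            raise ValueError(f"{self.beam_mode} requires a {ndim}-D volume grid")
        if len(self.detector_pixel_counts) != det_ndim or len(self.detector_pixel_pitch) != det_ndim:
            raise ValueError(f"{self.beam_mode} requires a {det_ndim}-D detector")
        if len(self.angles) < 1:
            raise ValueError("at least one view angle is required")
        if not all(math.isfinite(a) for a in self.angles):
            raise ValueError("angles must be finite")
        if len(set(self.angles)) != len(self.angles):
            raise ValueError("angles must be distinct")
        if any(n < 1 for n in self.volume_shape + self.detector_pixel_counts):
            raise ValueError("volume_shape and detector_pixel_counts must all be >= 1")
        if any(v <= 0 for v in self.voxel_size + self.detector_pixel_pitch):
            raise ValueError("voxel_size and detector_pixel_pitch must be positive")
        if self.beam_mode != "parallel2d":
            if self.source_to_origin is None or self.source_to_detector is None:
                raise ValueError(f"{self.beam_mode} requires source distances")
            if self.source_to_origin <= 0 or self.source_to_detector <= 0:
                raise ValueError("source distances must be strictly positive")
            if not self.source_to_detector > self.source_to_origin:
                raise ValueError("source_to_detector must exceed source_to_origin")

    @property
    def ndim(self) -> int:
        return 3 if self.beam_mode == "cone3d" else 2

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def rays_per_angle(self) -> int:
        return int(np.prod(self.detector_pixel_counts))

    @property
    def n_rays(self) -> int:
        return self.n_angles * self.rays_per_angle

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.volume_shape))

    def with_angles(self, angles: Iterable[float]) -> "ScanGeometry":
        return replace(self, angles=tuple(angles))

    def to_dict(self) -> dict:
        out = {
            "beam_mode": self.beam_mode,
            "angles": list(self.angles),
            "volume_shape": list(self.volume_shape),
            "voxel_size": list(self.voxel_size),
            "detector_pixel_counts": list(self.detector_pixel_counts),
            "detector_pixel_pitch": list(self.detector_pixel_pitch),
        }
        if self.beam_mode != "parallel2d":
            out["source_to_origin"] = self.source_to_origin
            out["source_to_detector"] = self.source_to_detector
        return out

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScanGeometry":
        cfg = dict(cfg)
        if "angles" not in cfg:
            cfg["angles"] = make_angles(
                cfg.pop("span_degrees"), cfg.pop("n_views"), cfg.pop("start", 0.0)
            )
        return cls(**cfg)


@dataclass(eq=False)
class ImageVolume:
    """Attenuation map (1/mm) on a centred voxel grid."""

    values: np.ndarray
    voxel_size: tuple[float, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.values.ndim:
            raise ValueError("voxel_size rank must match values rank")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.voxel_size)


@dataclass(eq=False)
class ProjectionSet:
    """Line integrals indexed by (view angle, detector pixel...)."""

    values: np.ndarray
    angles: tuple[float, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles = tuple(float(a) for a in self.angles)
        if self.values.shape[0] != len(self.angles):
            raise ValueError("first axis of values must match the number of angles")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection values must be finite")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    def copy(self) -> "ProjectionSet":
        return ProjectionSet(self.values.copy(), self.angles)


def parallel_geometry(
    n: int = 64,
    n_views: int = 50,
    span: float = 360.0,
    start: float = 0.0,
    voxel_size: float = 1.0,
    detector_count: int | None = None,
    detector_pitch: float | None = None,
) -> ScanGeometry:
    """Convenience 2-D parallel-beam geometry covering an n-by-n grid."""
    if detector_count is None:
        detector_count = int(math.ceil(n * math.sqrt(2.0))) + 2
    if detector_pitch is None:
        detector_pitch = voxel_size
    return ScanGeometry(
        beam_mode="parallel2d",
        angles=make_angles(span, n_views, start),
        volume_shape=(n, n),
        voxel_size=(voxel_size, voxel_size),
        detector_pixel_counts=(detector_count,),
        detector_pixel_pitch=(detector_pitch,),
    )


def fan_geometry(
    n: int = 64,
    n_views: int = 50,
    span: float = 360.0,
    start: float = 0.0,
    voxel_size: float = 1.0,
    dso: float | None = None,
    dsd: float | None = None,
    detector_count: int | None = None,
    detector_pitch: float | None = None,
) -> ScanGeometry:
    """Convenience 2-D fan-beam geometry covering an n-by-n grid."""
    fov = n * voxel_size
    if dso is None:
        dso = 3.0 * fov
    if dsd is None:
        dsd = 2.0 * dso
    mag = dsd / dso
    if detector_count is None:
        detector_count = int(math.ceil(n * math.sqrt(2.0) * mag)) + 4
    if detector_pitch is None:
        detector_pitch = voxel_size * mag
    return ScanGeometry(
        beam_mode="fan2d",
        angles=make_angles(span, n_views, start),
        volume_shape=(n, n),
        voxel_size=(voxel_size, voxel_size),
        detector_pixel_counts=(detector_count,),
        detector_pixel_pitch=(detector_pitch,),
        source_to_origin=dso,
        source_to_detector=dsd,
    )


def _detector_offsets(counts: Sequence[int], pitch: Sequence[float]) -> list[np.ndarray]:
    return [
        (np.arange(c) + 0.5 - c / 2.0) * p for c, p in zip(counts, pitch)
    ]


def _ray_endpoints(geom: ScanGeometry, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Segment end points for every detector pixel of one view."""
    t = math.radians(angle_deg)
    ct, st = math.cos(t), math.sin(t)
    if geom.beam_mode == "parallel2d":
        d = np.array([ct, st])
        u = np.array([-st, ct])
        (offs,) = _detector_offsets(geom.detector_pixel_counts, geom.detector_pixel_pitch)
        centers = offs[:, None] * u[None, :]
        half = 0.5 * math.hypot(
            geom.volume_shape[0] * geom.voxel_size[0],
            geom.volume_shape[1] * geom.voxel_size[1],
        )
        reach = 1.5 * half + 1.0
        return centers - reach * d[None, :], centers + reach * d[None, :]

    dso = float(geom.source_to_origin)
    dsd = float(geom.source_to_detector)
    if geom.beam_mode == "fan2d":
        c = np.array([ct, st])
        u = np.array([-st, ct])
        src = -dso * c
        (offs,) = _detector_offsets(geom.detector_pixel_counts, geom.detector_pixel_pitch)
        dets = src[None, :] + dsd * c[None, :] + offs[:, None] * u[None, :]
        p0 = np.broadcast_to(src, dets.shape).copy()
        return p0, dets

    # cone3d: detector pixel order is (row = z axis, column = transaxial u)
    c = np.array([ct, st, 0.0])
    u = np.array([-st, ct, 0.0])
    v = np.array([0.0, 0.0, 1.0])
    src = -dso * c
    offs_v, offs_u = _detector_offsets(geom.detector_pixel_counts, geom.detector_pixel_pitch)
    gu, gv = np.meshgrid(offs_u, offs_v)  # gv varies along rows
    dets = (
        src[None, :]
        + dsd * c[None, :]
        + gu.ravel()[:, None] * u[None, :]
        + gv.ravel()[:, None] * v[None, :]
    )
    p0 = np.broadcast_to(src, dets.shape).copy()
    return p0, dets


@lru_cache(maxsize=512)
def _angle_matrix(geom: ScanGeometry, angle_index: int) -> sparse.csr_matrix:
    p0, p1 = _ray_endpoints(geom, geom.angles[angle_index])
    return rays_to_matrix(p0, p1, geom.volume_shape, geom.voxel_size)


@lru_cache(maxsize=64)
def _full_matrix(geom: ScanGeometry) -> sparse.csr_matrix:
    return sparse.vstack(
        [_angle_matrix(geom, i) for i in range(geom.n_angles)], format="csr"
    )


def system_matrix(geom: ScanGeometry, angle_index: int | None = None) -> sparse.csr_matrix:
    """Sparse intersection-length system matrix.

    With ``angle_index`` the block for one view is returned (rows ordered by
    detector pixel); otherwise the full matrix with view-major row blocks.
    Results are cached per geometry.
    """
    if angle_index is None:
        return _full_matrix(geom)
    if not 0 <= angle_index < geom.n_angles:
        raise IndexError(f"angle_index {angle_index} out of range")
    return _angle_matrix(geom, angle_index)


def _check_volume(vol: ImageVolume, geom: ScanGeometry) -> None:
    if vol.shape != geom.volume_shape:
        raise ValueError(f"volume shape {vol.shape} does not match geometry {geom.volume_shape}")


def _check_projections(proj: ProjectionSet, geom: ScanGeometry) -> None:
    expected = (geom.n_angles, *geom.detector_pixel_counts)
    if proj.values.shape != expected:
        raise ValueError(f"projection shape {proj.values.shape} does not match geometry {expected}")


def forward_project(vol: ImageVolume, geom: ScanGeometry) -> ProjectionSet:
    """Line integrals of ``vol`` along every ray of ``geom`` (A @ x)."""
    _check_volume(vol, geom)
    data = system_matrix(geom) @ vol.values.ravel()
    return ProjectionSet(data.reshape(geom.n_angles, *geom.detector_pixel_counts), geom.angles)


def back_project(proj: ProjectionSet, geom: ScanGeometry) -> ImageVolume:
    """Exact adjoint of :func:`forward_project` (A.T @ y)."""
    _check_projections(proj, geom)
    data = system_matrix(geom).T @ proj.values.ravel()
    return ImageVolume(data.reshape(geom.volume_shape), geom.voxel_size)


def sart_weights(
    geom: ScanGeometry, angle_index: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row and column sums of the intersection-length matrix.

    ``row_sums[r]`` is the total chord length of ray ``r`` through the grid,
    ``col_sums[v]`` the total length of all rays through voxel ``v``; these
    are the SART W and V diagonals.  Restricting to one view is supported for
    per-angle sweeps.
    """
    mat = system_matrix(geom, angle_index)
    row_sums = np.asarray(mat.sum(axis=1)).ravel()
    col_sums = np.asarray(mat.sum(axis=0)).ravel()
    return row_sums, col_sums
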