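"""Synthetic piecewise-constant phantoms and mixed Poisson-Gaussian CT noise.

The thorax-like phantom is a stand-in for an anthropomorphic attenuation
map: a soft-tissue body outline, two low-attenuation lungs, a mid-intensity
heart blob and high-attenuation spine/rib features, all built from additive
ellipses/ellipsoids.  Attenuation values stay within [0, 0.025] per mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageVolume, ProjectionSet

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "NoiseModel",
    "render_phantom",
    "thorax_like_spec",
    "add_ct_noise",
]


@dataclass(frozen=True)
class Ellipse:
    """One additive ellipse (2-D) or ellipsoid (3-D).

    ``center`` and ``semi_axes`` are fractions of the field of view (the
    grid spans [-0.5, 0.5] per axis); ``rotation`` rotates the first two
    axes counter-clockwise in degrees; ``intensity`` is the additive
    attenuation contribution (may be negative for carve-outs as long as the
    per-voxel sum stays non-negative).
    """

    center: tuple[float, ...]
    semi_axes: tuple[float, ...]
    intensity: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", tuple(float(s) for s in self.semi_axes))
        if len(self.center) != len(self.semi_axes):
            raise ValueError("center and semi_axes rank mismatch")
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be strictly positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Boolean mask for points (n, ndim) in FOV-fraction coordinates."""
        rel = pts - np.asarray(self.center)[None, :]
        if self.rotation:
            t = math.radians(self.rotation)
            ct, st = math.cos(t), math.sin(t)
            x = ct * rel[:, 0] + st * rel[:, 1]
            y = -st * rel[:, 0] + ct * rel[:, 1]
            rel = rel.copy()
            rel[:, 0] = x
            rel[:, 1] = y
        q = (rel / np.asarray(self.semi_axes)[None, :]) ** 2
        return q.sum(axis=1) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Additive ellipse/ellipsoid phantom description."""

    elements: tuple[Ellipse, ...]
    grid_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 1")
        for el in self.elements:
            if len(el.center) != len(self.grid_shape):
                raise ValueError("element rank does not match grid rank")

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "elements": [
                {
                    "center": list(e.center),
                    "semi_axes": list(e.semi_axes),
                    "intensity": e.intensity,
                    "rotation": e.rotation,
                }
                for e in self.elements
            ],
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "PhantomSpec":
        return cls(
            elements=tuple(Ellipse(**{**e, "center": tuple(e["center"]),
                                      "semi_axes": tuple(e["semi_axes"])})
                           for e in cfg["elements"]),
            grid_shape=tuple(cfg["grid_shape"]),
        )


@dataclass(frozen=True)
class NoiseModel:
    """Mixed Poisson-Gaussian projection noise in the photon-count domain."""

    max_photon_count: float = 60_000.0
    gaussian_mean: float = 0.0
    gaussian_sd: float = 0.5
    seed: int = 0
    count_floor: float = 1.0  # counts clipped here before the log

    def __post_init__(self) -> None:
        if not self.max_photon_count > 0:
            raise ValueError("max_photon_count must be positive")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be non-negative")
        if not self.count_floor > 0:
            raise ValueError("count_floor must be positive")


def render_phantom(spec: PhantomSpec, voxel_size: tuple[float, ...] | float = 1.0) -> ImageVolume:
    """Rasterise a phantom: each voxel sums the intensities of the elements
    containing its centre.  Deterministic; negative voxels reject the spec."""
    shape = spec.grid_shape
    ndim = len(shape)
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * ndim
    axes = [(np.arange(n) + 0.5) / n - 0.5 for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    values = np.zeros(pts.shape[0])
    for el in spec.elements:
        values[el.contains(pts)] += el.intensity
    if (values < 0).any():
        raise ValueError("spec produces negative attenuation voxels")
    return ImageVolume(values.reshape(shape), voxel_size)


# Base thorax-like layout: (center, semi_axes, intensity, rotation, is_bone),
# 2-D.  Intensities are per-mm attenuation increments; sums stay in
# [0, 0.025] for every variant (bone is scaled by at most 1.15 and never
# overlaps more than the body outline).
_THORAX_2D = [
    # body outline (soft tissue)
    ((0.0, 0.0), (0.46, 0.36), 0.018, 0.0, False),
    # lungs: carve most of the soft tissue out
    ((-0.19, 0.02), (0.15, 0.22), -0.014, 8.0, False),
    ((0.19, 0.02), (0.15, 0.22), -0.014, -8.0, False),
    # heart-like blob between the lungs
    ((-0.03, -0.08), (0.11, 0.09), 0.004, 20.0, False),
    # spine (posterior high-attenuation feature)
    ((0.0, 0.27), (0.05, 0.05), 0.006, 0.0, True),
    # rib-like high-attenuation spots on the outline
    ((-0.38, -0.10), (0.030, 0.045), 0.006, 25.0, True),
    ((0.38, -0.10), (0.030, 0.045), 0.006, -25.0, True),
    ((-0.30, 0.22), (0.030, 0.040), 0.006, 55.0, True),
    ((0.30, 0.22), (0.030, 0.040), 0.006, -55.0, True),
    # small low-contrast nodule inside a lung
    ((-0.17, 0.10), (0.035, 0.035), 0.003, 0.0, False),
]


def thorax_like_spec(
    grid_shape: tuple[int, ...] = (64, 64),
    variant: str = "train",
    intensity_scale: float = 1.0,
) -> PhantomSpec:
    """Deterministic thorax-like phantom spec.

    ``variant`` selects documented perturbations of sizes/intensities so the
    cross-sample experiments have distinct but comparable subjects:

    * ``"train"`` - the base layout;
    * ``"male"``  - slightly larger body, thicker bony features;
    * ``"female"`` - wider ribcage/lungs, thinner bony features.

    Renders with at least four distinct intensity levels and voxel values
    within [0, 0.025] (times ``intensity_scale``).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    ndim = len(grid_shape)
    if ndim not in (2, 3):
        raise ValueError("grid_shape must be 2-D or 3-D")
    if variant not in ("train", "male", "female"):
        raise ValueError(f"unknown variant {variant!r}")

    size_xy = {"train": (1.0, 1.0), "male": (1.05, 1.02), "female": (1.1, 0.96)}[variant]
    bone_scale = {"train": 1.0, "male": 1.15, "female": 0.85}[variant]

    elements = []
    for center, axes, inten, rot, is_bone in _THORAX_2D:
        cx, cy = center
        ax, ay = axes
        cx *= size_xy[0]
        cy *= size_xy[1]
        ax = min(ax * size_xy[0], 0.49)
        ay = min(ay * size_xy[1], 0.49)
        if is_bone:
            inten = inten * bone_scale
        inten *= intensity_scale
        if ndim == 2:
            elements.append(Ellipse((cx, cy), (ax, ay), inten, rot))
        else:
            # extrude along z with a slightly shorter half-height
            cz = 0.0
            az = 0.42 if abs(inten) > 0.01 * intensity_scale else 0.30
            elements.append(Ellipse((cx, cy, cz), (ax, ay, az), inten, rot))
    return PhantomSpec(tuple(elements), grid_shape)


def add_ct_noise(proj: ProjectionSet, noise: NoiseModel) -> ProjectionSet:
    """Apply mixed Poisson-Gaussian noise to line integrals.

    For each reading ``p``: expected counts ``I = I0 * exp(-p)``, noisy
    counts = ``Poisson(I) + Normal(mean, sd)`` clipped below at
    ``count_floor``, returned as ``p' = ln(I0 / counts)``.  Deterministic
    for a fixed :class:`NoiseModel` seed.
    """
    p = proj.values
    if (p < 0).any():
        raise ValueError("line integrals must be non-negative")
    rng = np.random.default_rng(noise.seed)
    expected = noise.max_photon_count * np.exp(-p)
    counts = rng.poisson(expected).astype(np.float64)
    if noise.gaussian_sd > 0 or noise.gaussian_mean != 0:
        counts = counts + rng.normal(noise.gaussian_mean, noise.gaussian_sd, size=p.shape)
    counts = np.maximum(counts, noise.count_floor)
    return ProjectionSet(np.log(noise.max_photon_count / counts), proj.angles)
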