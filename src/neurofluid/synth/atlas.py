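"""Geometric phantom atlases: boxes and ellipsoids painted into a label grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import LabelAtlas

__all__ = ["RegionDef", "PhantomSpec", "make_phantom_atlas"]


@dataclass(frozen=True)
class RegionDef:
    """One geometric primitive: a box or an ellipsoid in voxel coordinates.

    ``center`` and ``radii`` are in voxels; a box spans center +/- radii
    (inclusive bounds after rounding), an ellipsoid is the standard quadric.
    """

    label: int
    name: str
    shape: str  # "box" | "ellipsoid"
    center: tuple
    radii: tuple

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError("region labels must be positive integers")
        if self.shape not in ("box", "ellipsoid"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if len(self.center) != 3 or len(self.radii) != 3:
            raise ValueError("center and radii must be 3-vectors")
        if any(r < 0 for r in self.radii):
            raise ValueError("radii must be non-negative")


@dataclass
class PhantomSpec:
    grid_shape: tuple
    voxel_size_mm: tuple
    region_defs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive reals")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        names = {}
        for rd in self.region_defs:
            if rd.label in names and names[rd.label] != rd.name:
                raise ValueError(f"label {rd.label} reused with a different name")
            names[rd.label] = rd.name


def _primitive_mask(rd: RegionDef, grid_shape) -> np.ndarray:
    cx, cy, cz = rd.center
    rx, ry, rz = rd.radii
    lo = np.array([cx - rx, cy - ry, cz - rz])
    hi = np.array([cx + rx, cy + ry, cz + rz])
    if np.any(lo < -0.5) or np.any(hi > np.array(grid_shape) - 0.5):
        raise ValueError(
            f"region {rd.name!r} (label {rd.label}) extends outside the grid"
        )
    ix, iy, iz = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
    if rd.shape == "box":
        return (
            (np.abs(ix - cx) <= rx + 1e-9)
            & (np.abs(iy - cy) <= ry + 1e-9)
            & (np.abs(iz - cz) <= rz + 1e-9)
        )
    # ellipsoid; zero radius along an axis collapses to the center plane
    rx, ry, rz = (max(r, 1e-9) for r in (rx, ry, rz))
    return ((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2 + ((iz - cz) / rz) ** 2 <= 1.0 + 1e-9


def make_phantom_atlas(spec: PhantomSpec) -> LabelAtlas:
    """Paint primitives into an integer grid; later regions overwrite earlier."""
    grid = np.zeros(tuple(int(s) for s in spec.grid_shape), dtype=np.int32)
    labels = {}
    for rd in spec.region_defs:
        grid[_primitive_mask(rd, grid.shape)] = rd.label
        labels[rd.label] = rd.name
    return LabelAtlas(grid, spec.voxel_size_mm, labels)
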