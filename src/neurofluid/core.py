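"""Shared containers: frame schedules, label atlases, dynamic images, NIfTI I/O.

All images are plain numpy arrays in voxel space; geometry is carried as a
voxel size triple (mm). Axis convention throughout the package: axis 0 = x
(left-right), axis 1 = y (posterior-anterior), axis 2 = z (inferior-superior),
axis 3 = time / cardiac phase. NIfTI affines are diagonal, built from the
voxel size, so round-trips through disk preserve geometry exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FrameSchedule",
    "LabelAtlas",
    "DynamicImage",
    "save_nifti",
    "load_nifti",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered PET frame timing: per-frame start and duration in seconds.

    Frames must be contiguous and non-overlapping with positive durations.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("start_s and duration_s must be equal-length 1-D")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def n_frames(self) -> int:
        return self.start_s.size

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1])

    @classmethod
    def from_blocks(cls, blocks) -> "FrameSchedule":
        """Build from (count, duration_s) blocks, e.g. [(4, 15), (8, 30)]."""
        durs = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def pib_default(cls) -> "FrameSchedule":
        """The 70-min dynamic 11C-PiB schedule: 4x15, 8x30, 9x60, 2x180, 10x300 s."""
        return cls.from_blocks([(4, 15), (8, 30), (9, 60), (2, 180), (10, 300)])

    def to_json(self, path) -> None:
        rows = [
            {"start_s": float(s), "duration_s": float(d)}
            for s, d in zip(self.start_s, self.duration_s)
        ]
        Path(path).write_text(json.dumps(rows, indent=1))

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        rows = json.loads(Path(path).read_text())
        return cls(
            np.array([r["start_s"] for r in rows]),
            np.array([r["duration_s"] for r in rows]),
        )


@dataclass
class LabelAtlas:
    """Integer region map with voxel geometry and a label dictionary."""

    data: np.ndarray
    voxel_size_mm: tuple
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("atlas data must be integer-typed")
        if self.data.ndim != 3:
            raise ValueError("atlas must be 3-D")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be 3 positive values")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def mask(self, label: int) -> np.ndarray:
        return self.data == int(label)

    def save(self, path) -> None:
        save_nifti(self.data.astype(np.int16), self.voxel_size_mm, path)
        sidecar = Path(str(path).split(".nii")[0] + "_labels.json")
        sidecar.write_text(json.dumps({str(k): v for k, v in self.labels.items()}))

    @classmethod
    def load(cls, path) -> "LabelAtlas":
        data, vox = load_nifti(path)
        sidecar = Path(str(path).split(".nii")[0] + "_labels.json")
        labels = {}
        if sidecar.exists():
            labels = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return cls(np.rint(data).astype(np.int32), vox[:3], labels)


@dataclass
class DynamicImage:
    """4-D activity grid (x, y, z, frame) bound to a FrameSchedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis ({self.data.shape[3]}) does not match the "
                f"schedule ({self.schedule.n_frames} frames)"
            )

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames


def save_nifti(data: np.ndarray, voxel_size_mm, path) -> None:
    """Write an array as NIfTI-1 with a diagonal RAS affine."""
    vox = list(voxel_size_mm)[:3]
    affine = np.diag(vox + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = tuple(vox) + ((1.0,) * (data.ndim - 3) if data.ndim > 3 else ())
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_nifti(path):
    """Read a NIfTI-1 volume; returns (array, voxel_size_mm tuple)."""
    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), vox
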