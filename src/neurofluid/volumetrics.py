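"""Parasagittal-dural (PSD) volumetrics and subsegmentation.

Coordinates follow the package convention: axis 0 = x (left-right), axis 1 =
y (posterior-anterior, +y anterior), axis 2 = z (inferior-superior, +z
dorsal), 0-based voxel indices. The PSD mask is partitioned into prefrontal,
frontal, parietal and occipital compartments by three planes:

* an oblique plane through the pituitary gland and the rostrum of the corpus
  callosum whose normal lies in the mid-sagittal (y-z) plane, separating the
  prefrontal (ventral) from the frontal (dorsal) PSD;
* a coronal plane through the central-sulcus apex, separating frontal from
  parietal;
* a coronal plane through the parieto-occipital fissure, separating parietal
  from occipital.

Coronal cuts approximate the curved sulcal surfaces; boundary voxels exactly
on a plane are assigned to the more anterior/dorsal compartment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import LabelAtlas

__all__ = [
    "LandmarkSet",
    "region_volume",
    "partition_psd",
    "icv_adjust",
    "PSD_SUBREGIONS",
]

PSD_SUBREGIONS = ("prefrontal", "frontal", "parietal", "occipital")


@dataclass(frozen=True)
class LandmarkSet:
    """Anatomical landmarks in voxel coordinates (x, y, z)."""

    pituitary: tuple
    cc_rostrum: tuple
    central_sulcus: tuple
    parieto_occipital: tuple

    def __post_init__(self):
        for name in ("pituitary", "cc_rostrum", "central_sulcus", "parieto_occipital"):
            p = getattr(self, name)
            if len(p) != 3:
                raise ValueError(f"landmark {name} must be a 3-D point")
        pit, ros = np.asarray(self.pituitary), np.asarray(self.cc_rostrum)
        if np.allclose(pit[1:], ros[1:]):
            raise ValueError(
                "pituitary and corpus-callosum rostrum coincide in the "
                "mid-sagittal plane; the oblique plane is degenerate"
            )
        if not (ros[1] >= pit[1] and ros[2] >= pit[2]):
            raise ValueError("rostrum must lie dorsal-anterior to the pituitary")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "axis_convention": "x=LR, y=PA(+anterior), z=IS(+dorsal), 0-based voxels",
                    "pituitary": list(self.pituitary),
                    "cc_rostrum": list(self.cc_rostrum),
                    "central_sulcus": list(self.central_sulcus),
                    "parieto_occipital": list(self.parieto_occipital),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["pituitary"]),
            tuple(d["cc_rostrum"]),
            tuple(d["central_sulcus"]),
            tuple(d["parieto_occipital"]),
        )


def region_volume(atlas: LabelAtlas, label: int) -> float:
    """Voxel count times voxel volume, in cm^3.

    A label listed in the atlas dictionary but absent from the grid yields 0
    (an empty segmentation); a label unknown to the dictionary also yields 0
    but with a warning, since it was likely never segmented.
    """
    n = int(np.count_nonzero(atlas.data == int(label)))
    if n == 0 and label not in atlas.labels:
        warnings.warn(
            f"label {label} is not in the atlas dictionary; volume reported as 0",
            stacklevel=2,
        )
    return n * atlas.voxel_volume_mm3 / 1000.0


def partition_psd(psd_mask: np.ndarray, landmarks: LandmarkSet) -> dict:
    """Split a PSD mask into the four subregion masks (see module docstring).

    Returns a dict name -> boolean mask; every input voxel receives exactly
    one subregion label.
    """
    mask = np.asarray(psd_mask, dtype=bool)
    if not mask.any():
        raise ValueError("PSD mask is empty")
    idx = np.argwhere(mask).astype(float)  # (n, 3) voxel coordinates

    pit = np.asarray(landmarks.pituitary, dtype=float)
    ros = np.asarray(landmarks.cc_rostrum, dtype=float)
    # Oblique plane through pituitary and rostrum, normal confined to the
    # mid-sagittal plane: n = x_hat x (ros - pit), oriented dorsal (+z).
    d = ros - pit
    normal = np.cross([1.0, 0.0, 0.0], d)
    if np.linalg.norm(normal) < 1e-12:
        raise ValueError("degenerate pituitary/rostrum landmarks")
    if normal[2] < 0:
        normal = -normal
    dorsal = (idx - pit) @ normal >= 0.0  # boundary -> dorsal (frontal)

    y = idx[:, 1]
    y_cs = float(landmarks.central_sulcus[1])
    y_po = float(landmarks.parieto_occipital[1])
    if y_po > y_cs:
        raise ValueError(
            "parieto-occipital landmark must be posterior to the central sulcus"
        )
    anterior_cs = y >= y_cs  # boundary -> anterior (frontal side)
    anterior_po = y >= y_po

    sub = np.empty(len(idx), dtype=object)
    sub[anterior_cs & dorsal] = "frontal"
    sub[anterior_cs & ~dorsal] = "prefrontal"
    sub[~anterior_cs & anterior_po] = "parietal"
    sub[~anterior_po] = "occipital"

    out = {}
    coords = np.argwhere(mask)
    for name in PSD_SUBREGIONS:
        m = np.zeros_like(mask)
        sel = coords[sub == name]
        m[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        out[name] = m
    return out


def icv_adjust(volume_cm3: float, icv_cm3: float) -> float:
    """Volume as a unitless fraction of intracranial volume."""
    if icv_cm3 <= 0:
        raise ValueError("intracranial volume must be positive")
    if volume_cm3 < 0:
        raise ValueError("volume must be non-negative")
    return volume_cm3 / icv_cm3
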