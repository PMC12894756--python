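"""Voxel-to-world affine transforms.

The world (scene) coordinate system is right-handed with z up, in
scene-meters.  Two families of mappings are supported:

* ``PX_TO_CM`` (default): every xy pixel maps to one centimeter of scene
  space regardless of the stored pixel size, and the z spacing is stretched
  by the z/xy pixel-size ratio so the volume appears isotropic.  This keeps
  arbitrary data near the meter scale where viewport navigation is
  comfortable.
* Physical modes (``UM_TO_M``, ``NM_TO_M``, ``ANGSTROM_TO_M``, ``M_TO_M``):
  one unit of the named physical length maps to one scene-meter (a literal
  unit relabeling), so externally produced meshes or annotations with real
  coordinates line up without rescaling.

By default the volume is centered in the XY plane (the XY bounding-box
center maps to world x = y = 0) and sits on z = 0; ``CORNER_ORIGIN`` puts
the voxel (0,0,0) corner at the world origin instead.

Voxel indices follow the voxel-center convention: index i spans the world
interval [i*s, (i+1)*s) and its center sits at (i + 0.5)*s + translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import ValidationError
from .multiscale import isotropy_factor
from .volume_io import MultiscaleLevel, VolumeDataset


class UnitMode(str, Enum):
    PX_TO_CM = "px_to_cm"
    UM_TO_M = "um_to_m"
    NM_TO_M = "nm_to_m"
    ANGSTROM_TO_M = "angstrom_to_m"
    M_TO_M = "m_to_m"


class CenterMode(str, Enum):
    XY_CENTERED = "xy_centered"
    CORNER_ORIGIN = "corner_origin"


_UNIT_IN_METERS = {
    "meter": 1.0,
    "micrometer": 1e-6,
    "nanometer": 1e-9,
    "angstrom": 1e-10,
}

_MODE_UNIT_IN_METERS = {
    UnitMode.UM_TO_M: 1e-6,
    UnitMode.NM_TO_M: 1e-9,
    UnitMode.ANGSTROM_TO_M: 1e-10,
    UnitMode.M_TO_M: 1.0,
}


@dataclass(frozen=True)
class SceneTransform:
    """Axis-aligned voxel -> world affine: world = spacing * (idx + 0.5) + t.

    ``spacing_world`` and ``translation_world`` are (x, y, z) in
    scene-meters; voxel indices are given as (z, y, x).
    """

    unit_mode: UnitMode
    center_mode: CenterMode
    spacing_world: tuple[float, float, float]
    translation_world: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_world):
            raise ValidationError("world spacing must be positive")

    def voxel_to_world(self, ijk_zyx) -> np.ndarray:
        """Map (…, 3) voxel indices (z, y, x) to world points (x, y, z)."""
        idx = np.asarray(ijk_zyx, dtype=np.float64)[..., ::-1]  # -> (x, y, z)
        return (idx + 0.5) * np.asarray(self.spacing_world) + np.asarray(
            self.translation_world
        )

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world`; returns fractional (z, y, x)."""
        p = np.asarray(xyz, dtype=np.float64)
        idx = (p - np.asarray(self.translation_world)) / np.asarray(
            self.spacing_world
        ) - 0.5
        return idx[..., ::-1]

    def bounds(self, shape_zyx) -> tuple[np.ndarray, np.ndarray]:
        """World-space AABB (min_xyz, max_xyz) of a volume of this shape."""
        size_xyz = np.asarray(shape_zyx, dtype=np.float64)[::-1]
        lo = np.asarray(self.translation_world, dtype=np.float64)
        return lo, lo + size_xyz * np.asarray(self.spacing_world)

    def to_dict(self) -> dict:
        return {
            "unit_mode": self.unit_mode.value,
            "center_mode": self.center_mode.value,
            "spacing_world": [float(v) for v in self.spacing_world],
            "translation_world": [float(v) for v in self.translation_world],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTransform":
        return cls(
            UnitMode(d["unit_mode"]),
            CenterMode(d["center_mode"]),
            tuple(float(v) for v in d["spacing_world"]),
            tuple(float(v) for v in d["translation_world"]),
        )


def build_transform(
    dataset: VolumeDataset,
    level: Optional[MultiscaleLevel] = None,
    unit_mode: UnitMode = UnitMode.PX_TO_CM,
    center_mode: CenterMode = CenterMode.XY_CENTERED,
) -> SceneTransform:
    """Build the voxel->world transform for one pyramid level of a dataset.

    Physical unit modes require the dataset to carry a physical pixel unit;
    data read with the "pixel" fallback must be given an explicit pixel
    size/unit override first.
    """
    level = level if level is not None else dataset.levels[0]
    px, py, pz = dataset.pixel_size
    if unit_mode is UnitMode.PX_TO_CM:
        sx = sy = 0.01
        sz = 0.01 * isotropy_factor(dataset.pixel_size)
    else:
        if dataset.pixel_unit == "pixel":
            raise ValidationError(
                f"unit mode {unit_mode.value!r} needs a physical pixel size; "
                "pass a pixel_size/pixel_unit override when reading the dataset"
            )
        to_m = _UNIT_IN_METERS[dataset.pixel_unit]
        mode_unit = _MODE_UNIT_IN_METERS[unit_mode]
        sx, sy, sz = (p * to_m / mode_unit for p in (px, py, pz))
    # coarser levels have proportionally larger voxels
    fz, fy, fx = (float(f) for f in level.downscale_factors)
    sx, sy, sz = sx * fx, sy * fy, sz * fz

    Z, Y, X = level.shape_zyx
    if center_mode is CenterMode.XY_CENTERED:
        translation = (-X * sx / 2.0, -Y * sy / 2.0, 0.0)
    elif center_mode is CenterMode.CORNER_ORIGIN:
        translation = (0.0, 0.0, 0.0)
    else:  # pragma: no cover - enum is closed
        raise ValidationError(f"unknown center mode {center_mode!r}")
    return SceneTransform(unit_mode, center_mode, (sx, sy, sz), translation)


def voxel_to_world(transform: SceneTransform, ijk_zyx) -> np.ndarray:
    """Functional alias for :meth:`SceneTransform.voxel_to_world`."""
    return transform.voxel_to_world(ijk_zyx)


def world_to_voxel(transform: SceneTransform, xyz) -> np.ndarray:
    """Functional alias for :meth:`SceneTransform.world_to_voxel`."""
    return transform.world_to_voxel(xyz)
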