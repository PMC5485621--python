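"""Voxel-grid containers shared by every pipeline stage.

A :class:`VolumeGrid` is a plain 3D scalar array plus the geometric metadata
needed to place it in world (patient) space: voxel spacing in mm, the world
position of the corner of the first voxel, and an axis-orientation tag.  The
same container carries CT Hounsfield units, Dixon MR signals, 511-keV linear
attenuation coefficients, relative electron density and absorbed dose — the
``role`` of the values is contextual, the geometry handling is shared.

Coordinate convention (used everywhere in this package): voxel indices are
0-based and the world coordinate of the *center* of voxel ``(i, j, k)`` is
``origin + (index + 0.5) * spacing``, axis order (x, y, z) matching the array
axes, orientation tag ``"RAS"`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk


@dataclass
class VolumeGrid:
    """A 3D scalar volume with spacing (mm), origin (mm) and orientation."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points, (N, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing) - 0.5

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.spacing)

    # -- compatibility checks ----------------------------------------------
    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and self.orientation == other.orientation
        )

    def require_same_grid(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} are on different grids: shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """New grid with identical geometry and replaced values."""
        return replace(self, values=np.asarray(values))

    def copy(self) -> "VolumeGrid":
        return replace(self, values=self.values.copy())

    # -- SimpleITK bridge ---------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        # our array axis order is (x, y, z); SimpleITK expects (z, y, x) arrays
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
        img.SetSpacing(self.spacing)
        # SimpleITK origin is the center of voxel (0,0,0)
        img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(self.origin, self.spacing)))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, orientation: str = "RAS") -> "VolumeGrid":
        values = sitk.GetArrayFromImage(img).T
        spacing = img.GetSpacing()
        origin = tuple(o - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
        return cls(values=values, spacing=spacing, origin=origin, orientation=orientation)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid (body, lungs, heart, cord, spine, PTV)."""

    masks: dict[str, VolumeGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.masks.values())
        for g in grids[1:]:
            grids[0].require_same_grid(g, "structure masks")
        for name, g in self.masks.items():
            vals = np.unique(g.values)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask '{name}' is not {{0,1}}-valued")

    def __getitem__(self, name: str) -> VolumeGrid:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def add(self, name: str, mask: VolumeGrid) -> None:
        if self.masks:
            next(iter(self.masks.values())).require_same_grid(mask, "structure masks")
        self.masks[name] = mask

    def array(self, name: str) -> np.ndarray:
        return self.masks[name].values.astype(bool)

    def lung_minus_ptv(self) -> np.ndarray:
        """Evaluation lung: union of both lungs with the PTV removed."""
        lung = self.array("lung_left") | self.array("lung_right")
        if "PTV" in self.masks:
            lung &= ~self.array("PTV")
        return lung
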