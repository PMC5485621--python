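"""Attenuation map -> synthetic CT: HU conversion, resampling, alignment.

The 511-keV attenuation map is converted to kilovoltage CT numbers with a
piecewise-linear map that reproduces every printed anchor exactly: the four
Dixon-class LACs go to -1000 (air), -767 (lung), -110 (fat) and 70 (soft
tissue) HU, and bone LACs in (0.1, 0.2485] map linearly onto (70, 2661] HU.
The map is monotone non-decreasing over its whole domain.

The module also provides grid resampling (clinical planning grid default
1.25 x 1.25 x 2.5 mm), rigid+deformable alignment of synCT onto the
planning CT, the PTV water-density override (-4 HU) and the per-organ
mean-HU comparison table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk

from . import tissues as T
from .classify import AttenuationMap
from .grid import StructureSet, VolumeGrid
from .registration import (
    SpatialTransform,
    bspline_refine,
    demons_refine,
    rigid_register,
    warp_volume,
)

log = logging.getLogger(__name__)

PLANNING_SPACING_MM = (1.25, 1.25, 2.5)

# monotone piecewise-linear LAC->HU anchors (cm^-1, HU)
_LAC_ANCHORS = np.array([T.LAC_AIR, T.LAC_LUNG, T.LAC_FAT, T.LAC_BONE_MIN, T.LAC_BONE_MAX])
_HU_ANCHORS = np.array([T.HU_AIR, T.HU_LUNG, T.HU_FAT, T.HU_BONE_MIN, T.HU_BONE_MAX])


@dataclass
class CTVolume:
    """Hounsfield-unit volume with a provenance tag (synCT or planCT)."""

    grid: VolumeGrid
    provenance: str = "synCT"

    def __post_init__(self) -> None:
        if self.provenance not in ("synCT", "planCT"):
            raise ValueError(f"provenance must be 'synCT' or 'planCT', got {self.provenance!r}")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def lac_to_hu_values(mu: np.ndarray) -> np.ndarray:
    """LAC (cm^-1) -> HU for raw arrays; exact on the five printed anchors."""
    mu = np.asarray(mu, dtype=float)
    bad = (mu < -1e-12) | (mu > T.LAC_BONE_MAX + 1e-12)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} voxels carry attenuation coefficients outside "
            f"[0, {T.LAC_BONE_MAX}] cm^-1"
        )
    hu = np.interp(mu, _LAC_ANCHORS, _HU_ANCHORS)
    return np.clip(hu, *T.HU_CLAMP)


def lac_to_hu(amap: AttenuationMap, provenance: str = "synCT") -> CTVolume:
    """Convert an attenuation map to a synthetic CT volume."""
    return CTVolume(amap.grid.with_values(lac_to_hu_values(amap.values)), provenance)


def resample(
    volume: VolumeGrid,
    target_spacing,
    mode: str = "linear",
    fill: float = 0.0,
) -> VolumeGrid:
    """Resample to a new voxel spacing, preserving world extent within one voxel.

    ``mode`` is ``"linear"`` (continuous volumes) or ``"nearest"``
    (labels/masks, value set preserved).
    """
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be strictly positive")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"interpolation mode must be 'linear' or 'nearest', got {mode!r}")

    new_size = [max(1, int(round(n * s / t))) for n, s, t in
                zip(volume.shape, volume.spacing, target)]
    ref = sitk.Image(new_size, sitk.sitkFloat64)
    ref.SetSpacing(target)
    ref.SetOrigin(tuple(o + 0.5 * t for o, t in zip(volume.origin, target)))

    img = sitk.Cast(volume.to_sitk(), sitk.sitkFloat64)
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(img, ref, sitk.Transform(), interp, float(fill))
    res = VolumeGrid.from_sitk(out, orientation=volume.orientation)
    res.origin = volume.origin
    if mode == "nearest":
        res.values = res.values.astype(volume.values.dtype)
    return res


def register_synct_to_ct(
    synct: CTVolume,
    planct: CTVolume,
    deformable: bool = True,
    method: str = "bspline",
) -> tuple[SpatialTransform, CTVolume]:
    """Align synCT onto the planning CT: rigid (6-DOF) then deformable
    refinement (coarse-control-grid B-spline by default, demons optional).

    Returns the transform (planCT space -> synCT space) and the synCT
    resampled onto the planCT grid.  Each stage verifies that its similarity
    metric improved and raises otherwise.
    """
    fixed, moving = planct.grid, synct.grid
    t = rigid_register(fixed, moving)
    if deformable:
        refine = {"bspline": bspline_refine, "demons": demons_refine}[method]
        t = refine(fixed, moving, initial=t)
    resampled = warp_volume(moving, fixed, t, order=1, fill=T.HU_AIR)
    return t, CTVolume(resampled, provenance=synct.provenance)


def override_ptv_density(ct: CTVolume, ptv: VolumeGrid) -> CTVolume:
    """Set every PTV voxel to water-equivalent tumor density (-4 HU).

    Applied identically to synCT and planCT before dose calculation;
    idempotent.  An empty mask only logs a warning.
    """
    ct.grid.require_same_grid(ptv, "CT and PTV mask")
    mask = ptv.values.astype(bool)
    if not mask.any():
        log.warning("PTV density override: mask is empty, nothing overridden")
    vals = ct.grid.values.copy()
    vals[mask] = T.HU_PTV_OVERRIDE
    return CTVolume(ct.grid.with_values(vals), ct.provenance)


def crop_to_structures(ct: CTVolume, structures: StructureSet,
                       margin_mm: float = 10.0) -> tuple[CTVolume, tuple[slice, ...]]:
    """Axis-aligned bounding-box crop around the structure set plus a margin."""
    union = np.zeros(ct.grid.shape, dtype=bool)
    for name in structures.names:
        union |= structures.array(name)
    if not union.any():
        raise ValueError("cannot crop: structure set is empty")
    sl = []
    for ax in range(3):
        proj = union.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        pad = int(np.ceil(margin_mm / ct.grid.spacing[ax]))
        sl.append(slice(max(0, idx[0] - pad), min(ct.grid.shape[ax], idx[-1] + 1 + pad)))
    sl = tuple(sl)
    vals = ct.grid.values[sl]
    origin = tuple(
        o + s.start * sp for o, s, sp in zip(ct.grid.origin, sl, ct.grid.spacing)
    )
    return CTVolume(VolumeGrid(vals, ct.grid.spacing, origin, ct.grid.orientation),
                    ct.provenance), sl


def organ_mean_hu(ct: CTVolume, structures: StructureSet,
                  organs: list[str] | None = None) -> pd.DataFrame:
    """Mean HU per organ for one CT volume; empty masks are flagged."""
    organs = organs or [n for n in structures.names if n not in ("body", "PTV")]
    rows = []
    for name in organs:
        mask = structures.array(name)
        if not mask.any():
            rows.append({"organ": name, "provenance": ct.provenance,
                         "mean_hu": None, "n_voxels": 0, "flag": "empty mask"})
            continue
        rows.append({"organ": name, "provenance": ct.provenance,
                     "mean_hu": float(ct.values[mask].mean()),
                     "n_voxels": int(mask.sum()), "flag": ""})
    return pd.DataFrame(rows)


def organ_mean_hu_table(synct: CTVolume, planct: CTVolume,
                        structures: StructureSet,
                        organs: list[str] | None = None) -> pd.DataFrame:
    """Paired per-organ mean-HU comparison (synCT vs planCT)."""
    a = organ_mean_hu(synct, structures, organs).set_index("organ")
    b = organ_mean_hu(planct, structures, organs).set_index("organ")
    out = pd.DataFrame({
        "mean_hu_synct": a["mean_hu"],
        "mean_hu_planct": b["mean_hu"],
        "n_voxels": a["n_voxels"],
        "flag": a["flag"].where(a["flag"] != "", b["flag"]),
    })
    out["difference"] = out["mean_hu_synct"] - out["mean_hu_planct"]
    return out.reset_index()
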