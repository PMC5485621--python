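"""Atlas-based bone insertion into the attenuation map.

Dixon classification cannot see cortical bone (it reads as soft tissue), so
bone attenuation is restored from an atlas: a pre-aligned MR volume with
bone masks carrying per-voxel 511-keV LACs, registered to the patient MR in
two stages (landmark least-squares affine, then optional demons deformable
refinement) and pasted into the patient attenuation map.

Within each atlas bone the LAC runs linearly from the cortical rim
(0.2485 cm^-1) to the marrow core (0.1 cm^-1), the published range for bone.
Bone may overwrite fat and soft tissue only — never air or lung — keeping
the map anatomically possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import tissues as T
from .classify import AttenuationMap
from .dixon import DixonPair
from .grid import VolumeGrid
from .registration import (
    RegistrationError,
    SpatialTransform,
    bspline_refine,
    demons_refine,
    landmark_affine,
    warp_volume,
)

log = logging.getLogger(__name__)


@dataclass
class BoneAtlas:
    """Atlas MR plus bone LAC masks and anatomical landmarks (world mm).

    Bones listed in ``gradient_bones`` carry the parametric rim-to-core LAC
    model rather than measured values; on insertion their gradient is
    recomputed natively on the warped mask instead of interpolating the LAC
    values (interpolation smooths the cortical rim and would bias the
    inserted bone toward lower attenuation).
    """

    mr_water: VolumeGrid
    bone_lac: dict[str, VolumeGrid] = field(default_factory=dict)
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    gradient_bones: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, vol in self.bone_lac.items():
            vals = vol.values[vol.values > 0]
            if vals.size and (
                (vals < T.LAC_BONE_MIN - 1e-9).any() or (vals > T.LAC_BONE_MAX + 1e-9).any()
            ):
                raise ValueError(
                    f"bone mask '{name}' carries LACs outside "
                    f"[{T.LAC_BONE_MIN}, {T.LAC_BONE_MAX}] cm^-1"
                )


def bone_lac_gradient(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel bone LAC: 0.2485 at the cortical rim down to 0.1 at the core."""
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    out = np.zeros(mask.shape)
    if mask.any():
        d = edt[mask]
        dmin, dmax = d.min(), d.max()
        span = dmax - dmin
        depth = (d - dmin) / span if span > 0 else np.zeros(d.size)
        out[mask] = T.LAC_BONE_MAX - (T.LAC_BONE_MAX - T.LAC_BONE_MIN) * depth
    return out


def build_spine_atlas(spec=None) -> BoneAtlas:
    """Construct the desk-scale atlas from the canonical noiseless phantom.

    The atlas MR is the simulated Dixon water image; the single bone mask is
    the vertebral column with the rim-to-core LAC gradient.  The interface
    accepts arbitrary additional masks (skull, femur, hip) for larger atlases.
    """
    from .phantom import PhantomSpec, build_phantom, simulate_dixon
    from .synct import resample

    if spec is None:
        spec = PhantomSpec(hu_noise_sd=0.0, mr_noise_sd=0.0)
    labels, _, structures = build_phantom(spec)
    dixon = simulate_dixon(labels, spec)
    spine_mr = resample(structures["spine"], spec.mr_spacing, mode="nearest")
    lac = bone_lac_gradient(spine_mr.values.astype(bool), spec.mr_spacing)
    return BoneAtlas(
        mr_water=dixon.water,
        bone_lac={"spine": spine_mr.with_values(lac)},
        landmarks=spec.landmarks(),
        gradient_bones=("spine",),
    )


def register_atlas(
    atlas: BoneAtlas,
    patient_mr: DixonPair,
    patient_landmarks: dict[str, np.ndarray],
    deformable: bool = True,
    method: str = "bspline",
    **refine_kwargs,
) -> SpatialTransform:
    """Two-stage atlas-to-patient registration.

    Stage 1 is a least-squares affine on the landmarks shared by atlas and
    patient; stage 2 (optional) is an intensity-based deformable refinement
    of the water images (coarse-control-grid B-spline by default, demons
    optional).  The transform maps patient world points into atlas space.
    """
    common = sorted(set(atlas.landmarks) & set(patient_landmarks))
    if len(common) < 4:
        raise RegistrationError(
            f"need >= 4 shared landmarks for the affine stage, got {len(common)}"
        )
    fixed_pts = np.array([patient_landmarks[k] for k in common])
    moving_pts = np.array([atlas.landmarks[k] for k in common])
    affine = landmark_affine(fixed_pts, moving_pts)
    if not deformable:
        return affine
    refine = {"bspline": bspline_refine, "demons": demons_refine}[method]
    return refine(patient_mr.water, atlas.mr_water, initial=affine, **refine_kwargs)


def insert_bones(
    amap: AttenuationMap,
    atlas: BoneAtlas,
    transform: SpatialTransform,
    outside_body_tolerance: float = 0.02,
) -> AttenuationMap:
    """Paste warped atlas bone LACs into the attenuation map.

    Bone overwrites fat and soft-tissue voxels only; air and lung are never
    replaced.  Idempotent for a fixed transform.  If more than
    ``outside_body_tolerance`` of the warped bone lands outside the body
    (non-air region), a warning is logged.
    """
    grid = amap.grid
    mu = amap.values.copy()
    soft_or_fat = np.isclose(mu, T.LAC_FAT) | np.isclose(mu, T.LAC_SOFT) | (
        mu >= T.LAC_BONE_MIN - 1e-9
    )
    body = mu > 0

    for name, lac_vol in atlas.bone_lac.items():
        mask_vol = lac_vol.with_values((lac_vol.values > 0).astype(float))
        warped_mask = warp_volume(mask_vol, grid, transform, order=1).values > 0.5
        if not warped_mask.any():
            continue
        if name in atlas.gradient_bones:
            # parametric bone: rebuild the rim-to-core gradient on the warped
            # mask (value interpolation would flatten the cortical rim)
            warped_lac = bone_lac_gradient(warped_mask, grid.spacing)
        else:
            warped_lac = warp_volume(lac_vol, grid, transform, order=1).values
        outside = warped_mask & ~body
        frac_out = outside.sum() / warped_mask.sum()
        if frac_out > outside_body_tolerance:
            log.warning(
                "bone mask '%s': %.1f%% of warped voxels fall outside the body",
                name, 100.0 * frac_out,
            )
        target = warped_mask & soft_or_fat
        mu[target] = np.clip(warped_lac[target], T.LAC_BONE_MIN, T.LAC_BONE_MAX)

    return AttenuationMap(grid.with_values(mu))
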