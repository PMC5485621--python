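"""Spatial transforms and registration (landmark affine, rigid, demons).

Transform convention: a :class:`SpatialTransform` maps *fixed* (patient)
world points to *moving* (atlas / unregistered) world points — the
resampling convention — as ``T(p) = A @ (p + u(p))`` where ``A`` is the
affine stage and ``u`` the dense displacement refinement defined on the
fixed grid.  Estimation uses closed-form least squares for landmarks and
SimpleITK for intensity-based rigid and demons stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .grid import VolumeGrid


class RegistrationError(RuntimeError):
    """Registration could not be estimated or diverged; message carries the trace."""


@dataclass
class SpatialTransform:
    """Affine (4x4, fixed->moving world) plus optional dense displacement.

    ``displacement`` has shape ``(3, nx, ny, nz)`` in mm on ``field_grid``
    (the fixed grid); outside that grid it is extended by nearest value.
    """

    affine: np.ndarray
    displacement: np.ndarray | None = None
    field_grid: VolumeGrid | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if (self.displacement is None) != (self.field_grid is None):
            raise ValueError("displacement and field_grid must be given together")

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(np.eye(4))

    def displacement_at(self, points_mm: np.ndarray) -> np.ndarray:
        if self.displacement is None:
            return np.zeros_like(np.atleast_2d(points_mm), dtype=float)
        idx = self.field_grid.world_to_index(points_mm).T  # (3, N)
        out = np.empty((idx.shape[1], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.displacement[c], idx, order=1, mode="nearest"
            )
        return out

    def transform_points(self, points_mm: np.ndarray) -> np.ndarray:
        """Map fixed-space world points to moving-space world points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        pts = pts + self.displacement_at(pts)
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def dense_field(self, grid: VolumeGrid) -> np.ndarray:
        """T(p) - p at every voxel center of ``grid``; shape (3, *grid.shape), mm."""
        idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
        pts = grid.index_to_world(idx)
        disp = (self.transform_points(pts) - pts).T
        return disp.reshape((3,) + grid.shape)

    def max_affine_translation(self) -> float:
        return float(np.linalg.norm(self.affine[:3, 3]))


def warp_volume(
    moving: VolumeGrid,
    fixed_grid: VolumeGrid,
    transform: SpatialTransform,
    order: int = 1,
    fill: float = 0.0,
) -> VolumeGrid:
    """Resample ``moving`` onto ``fixed_grid`` through ``transform``."""
    idx = np.indices(fixed_grid.shape, dtype=float).reshape(3, -1).T
    pts = fixed_grid.index_to_world(idx)
    mpts = transform.transform_points(pts)
    midx = moving.world_to_index(mpts).T
    vals = ndimage.map_coordinates(
        moving.values.astype(float), midx, order=order, mode="grid-constant", cval=fill
    )
    return fixed_grid.with_values(vals.reshape(fixed_grid.shape))


# ---------------------------------------------------------------------------
# landmark affine (closed form)
# ---------------------------------------------------------------------------

def landmark_affine(fixed_pts: np.ndarray, moving_pts: np.ndarray) -> SpatialTransform:
    """Least-squares affine mapping fixed landmarks onto moving landmarks.

    Requires at least 4 landmarks in general position (non-coplanar);
    fewer, or collinear/coplanar sets, cannot determine an affine and raise.
    """
    F = np.atleast_2d(np.asarray(fixed_pts, float))
    M = np.atleast_2d(np.asarray(moving_pts, float))
    if F.shape != M.shape or F.shape[1] != 3:
        raise ValueError("landmark arrays must both be (N, 3)")
    n = F.shape[0]
    if n < 4:
        raise RegistrationError(
            f"affine landmark registration needs >= 4 landmarks, got {n}"
        )
    centered = F - F.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 3:
        raise RegistrationError(
            "landmarks are collinear or coplanar; affine is underdetermined"
        )
    X = np.hstack([F, np.ones((n, 1))])
    sol, *_ = np.linalg.lstsq(X, M, rcond=None)
    affine = np.eye(4)
    affine[:3, :3] = sol[:3].T
    affine[:3, 3] = sol[3]
    return SpatialTransform(affine)


# ---------------------------------------------------------------------------
# intensity-based stages (SimpleITK)
# ---------------------------------------------------------------------------

def _as_float_sitk(vol: VolumeGrid) -> sitk.Image:
    return sitk.Cast(vol.to_sitk(), sitk.sitkFloat32)


def _mean_squared_difference(fixed: VolumeGrid, moving_resampled: VolumeGrid) -> float:
    return float(np.mean((fixed.values - moving_resampled.values) ** 2))


def rigid_register(
    fixed: VolumeGrid,
    moving: VolumeGrid,
    iterations: int = 200,
    shrink: tuple[int, ...] = (4, 2, 1),
) -> SpatialTransform:
    """6-DOF rigid registration (mean-squares metric, multi-resolution)."""
    f, m = _as_float_sitk(fixed), _as_float_sitk(moving)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=iterations,
        gradientMagnitudeTolerance=1e-7,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel([s - 1 for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    tx = reg.Execute(f, m)

    euler = sitk.Euler3DTransform(tx.GetNthTransform(0) if isinstance(tx, sitk.CompositeTransform) else tx)
    R = np.asarray(euler.GetMatrix()).reshape(3, 3)
    c = np.asarray(euler.GetCenter())
    t = np.asarray(euler.GetTranslation())
    affine = np.eye(4)
    affine[:3, :3] = R
    affine[:3, 3] = c + t - R @ c
    out = SpatialTransform(affine)
    _check_improved(fixed, moving, out, "rigid registration")
    return out


def _check_improved(fixed: VolumeGrid, moving: VolumeGrid,
                    transform: SpatialTransform, stage: str) -> None:
    before = _mean_squared_difference(fixed, warp_volume(moving, fixed, SpatialTransform.identity()))
    after = _mean_squared_difference(fixed, warp_volume(moving, fixed, transform))
    if after > before * (1.0 + 1e-9):
        raise RegistrationError(
            f"{stage} diverged: mean-squared difference {before:.4g} -> {after:.4g}"
        )


def bspline_refine(
    fixed: VolumeGrid,
    moving: VolumeGrid,
    initial: SpatialTransform | None = None,
    knot_spacing_mm: float = 60.0,
    iterations: int = 40,
    shrink: tuple[int, ...] = (4, 2),
    sampling_fraction: float = 0.25,
) -> SpatialTransform:
    """Free-form-deformation refinement on a coarse B-spline control grid.

    Suited to smooth, breathing-scale misalignments: the control-grid
    parametrization (default 60 mm knot spacing) interpolates the field
    through flat image regions where intensity provides no signal.  The
    moving volume is pre-warped through the affine stage of ``initial``;
    the returned transform composes both stages.
    """
    initial = initial or SpatialTransform.identity()
    moving_aff = warp_volume(moving, fixed, SpatialTransform(initial.affine))
    f_img = _as_float_sitk(fixed)
    m_img = _as_float_sitk(moving_aff)

    mesh = [max(1, int(round(n * s / knot_spacing_mm)))
            for n, s in zip(fixed.shape, fixed.spacing)]
    tx0 = sitk.BSplineTransformInitializer(f_img, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    if sampling_fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.REGULAR)
        reg.SetMetricSamplingPercentage(sampling_fraction, seed=12345)
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                             numberOfIterations=int(iterations))
    reg.SetInitialTransform(tx0, inPlace=True)
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel([s - 1 for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    tx = reg.Execute(f_img, m_img)

    field = sitk.TransformToDisplacementField(
        tx, sitk.sitkVectorFloat64, f_img.GetSize(), f_img.GetOrigin(),
        f_img.GetSpacing(), f_img.GetDirection(),
    )
    arr = sitk.GetArrayFromImage(field)
    disp = np.moveaxis(arr, -1, 0).transpose(0, 3, 2, 1)
    out = SpatialTransform(initial.affine, displacement=disp, field_grid=fixed)

    msd_before = _mean_squared_difference(fixed, moving_aff)
    msd_after = _mean_squared_difference(fixed, warp_volume(moving, fixed, out))
    if msd_after > msd_before * (1.0 + 1e-9):
        raise RegistrationError(
            f"B-spline refinement diverged: mean-squared difference "
            f"{msd_before:.4g} -> {msd_after:.4g}"
        )
    return out


def demons_refine(
    fixed: VolumeGrid,
    moving: VolumeGrid,
    initial: SpatialTransform | None = None,
    iterations: tuple[int, ...] = (40, 30, 20),
    shrink: tuple[int, ...] = (4, 2, 1),
    field_sigma_vox: float = 1.5,
) -> SpatialTransform:
    """Demons deformable refinement of ``initial`` (multi-resolution).

    The moving volume is first resampled through the affine stage of
    ``initial``; demons then estimates a residual displacement field on the
    fixed grid.  The returned transform composes both stages.  Raises
    :class:`RegistrationError` if the similarity metric worsens.
    """
    initial = initial or SpatialTransform.identity()
    moving_aff = warp_volume(moving, fixed, SpatialTransform(initial.affine))
    f_img = _as_float_sitk(fixed)
    m_img = _as_float_sitk(moving_aff)

    field = None
    for sf, nit in zip(shrink, iterations):
        f_lvl = sitk.Shrink(f_img, [int(sf)] * 3) if sf > 1 else f_img
        m_lvl = sitk.Shrink(m_img, [int(sf)] * 3) if sf > 1 else m_img
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(nit))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(field_sigma_vox)
        if field is None:
            field = demons.Execute(f_lvl, m_lvl)
        else:
            field = sitk.Resample(field, f_lvl)
            field = demons.Execute(f_lvl, m_lvl, field)
    field = sitk.Resample(field, f_img)

    arr = sitk.GetArrayFromImage(field)  # (z, y, x, 3), physical mm offsets
    disp = np.moveaxis(arr, -1, 0).transpose(0, 3, 2, 1)
    out = SpatialTransform(initial.affine, displacement=disp, field_grid=fixed)

    msd_before = _mean_squared_difference(fixed, moving_aff)
    msd_after = _mean_squared_difference(fixed, warp_volume(moving, fixed, out))
    if msd_after > msd_before * (1.0 + 1e-9):
        raise RegistrationError(
            f"demons refinement diverged: mean-squared difference "
            f"{msd_before:.4g} -> {msd_after:.4g}"
        )
    return out
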