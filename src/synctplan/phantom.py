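"""Digital thorax phantoms with ground-truth CT, Dixon MR and structure masks.

The phantom emulates the statistical structure of the study inputs: a body
of soft tissue wrapped in a subcutaneous fat shell, two air-filled lungs,
a heart, a spinal cord inside a vertebral column, piecewise-constant
ground-truth Hounsfield units plus Gaussian noise, a spherical planning
target volume (PTV) placed inside a lung in one of three size classes and
four location classes, and a smooth random breath-hold-vs-free-breathing
misalignment field.

All geometry is parametric and seeded: a fixed :class:`PhantomSpec` always
produces byte-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import tissues as T
from .grid import StructureSet, VolumeGrid

# PTV size classes: mean and SD of sphere volume in cm^3
PTV_SIZE_CLASSES: dict[str, tuple[float, float]] = {
    "small": (11.9, 5.5),
    "medium": (83.5, 14.5),
    "large": (222.3, 39.8),
}
PTV_LOCATION_CLASSES = ("apex", "mediastinum", "ribs", "spine")

# volume draws are truncated at +-1.5 SD (inside the modelled +-2 SD band)
# so that the largest draws still admit a placement inside a phantom lung
_TRUNC_SD = 1.5


class PTVPlacementError(RuntimeError):
    """No lung position can contain the requested PTV sphere."""


@dataclass
class PhantomSpec:
    """Parametric description of one digital thorax phantom.

    Geometric parameters are in mm, relative to the center of the field of
    view; ``anatomy_scale``/``anatomy_shift`` apply a per-axis affine to all
    organ geometry (used to emulate differently sized patients).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    mr_spacing: tuple[float, float, float] = (2.6, 2.6, 3.12)

    # organ geometry (canonical thorax)
    body_semiaxes: tuple[float, float] = (110.0, 85.0)   # elliptic cylinder, x/y
    fat_shell_scale: float = 0.9                          # fat between this scale and 1
    lung_center: tuple[float, float, float] = (47.0, -8.0, 0.0)  # right lung; left mirrored
    lung_semiaxes: tuple[float, float, float] = (44.0, 58.0, 97.0)
    heart_center: tuple[float, float, float] = (0.0, 30.0, -40.0)
    heart_radius: float = 24.0
    spine_center_y: float = 58.0
    spine_radius: float = 16.0
    cord_radius: float = 5.0
    anatomy_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    anatomy_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    # ground-truth intensities
    hu_means: dict[int, float] = field(
        default_factory=lambda: dict(T.CLASS_HU)
    )
    hu_noise_sd: float = 20.0
    lung_hu_offset: float = 0.0   # patient-level lung HU deviation from nominal
    spine_model: str = "gradient"  # "gradient" (cortical rim -> marrow) or "uniform"
    spine_uniform_hu: float = 336.0

    # Dixon signal table: label -> (water, fat) signal means, arbitrary units
    dixon_signal: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {
            T.AIR: (0.0, 0.0),
            T.LUNG: (12.0, 4.0),
            T.SOFT_TISSUE: (100.0, 12.0),
            T.FAT: (15.0, 110.0),
        }
    )
    mr_noise_sd: float = 0.0

    # PTV
    ptv_size_class: str = "medium"
    ptv_location_class: str = "mediastinum"
    ptv_volume_cm3: float | None = None   # explicit volume overrides the class draw
    ptv_lung_side: str | None = None      # "left" | "right" | None (seeded choice)

    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing) or any(s <= 0 for s in self.mr_spacing):
            raise ValueError("voxel spacings must be strictly positive")
        if self.ptv_size_class not in PTV_SIZE_CLASSES:
            raise ValueError(f"unknown PTV size class {self.ptv_size_class!r}")
        if self.ptv_location_class not in PTV_LOCATION_CLASSES:
            raise ValueError(f"unknown PTV location class {self.ptv_location_class!r}")
        if self.spine_model not in ("gradient", "uniform"):
            raise ValueError(f"unknown spine model {self.spine_model!r}")

    # -- derived geometry ---------------------------------------------------
    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def center_mm(self) -> tuple[float, float, float]:
        return tuple(f / 2 for f in self.fov_mm)

    def _world(self, rel: tuple[float, float, float]) -> np.ndarray:
        """Organ coordinate (relative to FOV center) -> world mm, with anatomy affine."""
        r = np.asarray(rel, float) * np.asarray(self.anatomy_scale)
        return np.asarray(self.center_mm) + r + np.asarray(self.anatomy_shift)

    def landmarks(self) -> dict[str, np.ndarray]:
        """Anatomical landmark world coordinates embedded in the phantom."""
        lc = np.asarray(self.lung_center)
        la = np.asarray(self.lung_semiaxes)
        zs = self.fov_mm[2]
        sy = self.spine_center_y
        pts = {
            "heart_center": self._world(self.heart_center),
            "lung_right_center": self._world(tuple(lc)),
            "lung_left_center": self._world((-lc[0], lc[1], lc[2])),
            "lung_right_apex": self._world((lc[0], lc[1], lc[2] + la[2])),
            "lung_left_apex": self._world((-lc[0], lc[1], lc[2] + la[2])),
            "cord_superior": self._world((0.0, sy, zs / 2 - self.spacing[2])),
            "cord_inferior": self._world((0.0, sy, -zs / 2 + self.spacing[2])),
            "sternum": self._world((0.0, -self.body_semiaxes[1] * self.fat_shell_scale, 0.0)),
        }
        return pts


@dataclass
class Phantom:
    """Bundle of everything :func:`build_phantom` knows about one phantom."""

    spec: PhantomSpec
    labels: T.TissueLabelMap
    ct: VolumeGrid
    structures: StructureSet
    landmarks: dict[str, np.ndarray]
    ptv_volume_cm3: float


# ---------------------------------------------------------------------------
# label-map construction
# ---------------------------------------------------------------------------

def _coordinate_grids(shape, spacing):
    xs = (np.arange(shape[0]) + 0.5) * spacing[0]
    ys = (np.arange(shape[1]) + 0.5) * spacing[1]
    zs = (np.arange(shape[2]) + 0.5) * spacing[2]
    return np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)


def _build_labels_and_masks(spec: PhantomSpec):
    X, Y, Z = _coordinate_grids(spec.shape, spec.spacing)
    scale = np.asarray(spec.anatomy_scale)
    shift = np.asarray(spec.anatomy_shift)
    cx, cy, cz = (np.asarray(spec.center_mm) + shift)

    # organ coordinates, undoing the anatomy affine
    x = (X - cx) / scale[0]
    y = (Y - cy) / scale[1]
    z = (Z - cz) / scale[2]

    ax, ay = spec.body_semiaxes
    body_r2 = (x / ax) ** 2 + (y / ay) ** 2
    body = np.broadcast_to(body_r2 <= 1.0, spec.shape)
    soft_interior = np.broadcast_to(body_r2 <= spec.fat_shell_scale**2, spec.shape)

    labels = np.full(spec.shape, T.AIR, dtype=np.int16)
    labels[body] = T.FAT
    labels[soft_interior] = T.SOFT_TISSUE

    la = np.asarray(spec.lung_semiaxes)
    lungs = {}
    for side, sx in (("right", 1.0), ("left", -1.0)):
        c = np.asarray(spec.lung_center) * np.array([sx, 1.0, 1.0])
        m = (
            ((x - c[0]) / la[0]) ** 2
            + ((y - c[1]) / la[1]) ** 2
            + ((z - c[2]) / la[2]) ** 2
        ) <= 1.0
        lungs[side] = m
        labels[m] = T.LUNG

    hc = np.asarray(spec.heart_center)
    heart = ((x - hc[0]) ** 2 + (y - hc[1]) ** 2 + (z - hc[2]) ** 2) <= spec.heart_radius**2
    heart &= soft_interior
    labels[heart] = T.SOFT_TISSUE

    spine_r2 = np.broadcast_to(x**2 + (y - spec.spine_center_y) ** 2, spec.shape)
    spine = (spine_r2 <= spec.spine_radius**2) & soft_interior
    cord = (spine_r2 <= spec.cord_radius**2) & soft_interior
    spine_only = spine & ~cord
    labels[spine_only] = T.BONE
    labels[cord] = T.SOFT_TISSUE

    # structure masks reflect final precedence (later organs carve earlier ones)
    taken = heart | spine | cord
    masks = {
        "body": body,
        "lung_right": lungs["right"] & ~taken,
        "lung_left": lungs["left"] & ~taken,
        "heart": heart,
        "spinal_cord": cord,
        "spine": spine_only,
    }
    return labels, masks


def _draw_ptv_volume(spec: PhantomSpec, rng: np.random.Generator) -> float:
    if spec.ptv_volume_cm3 is not None:
        return float(spec.ptv_volume_cm3)
    mean, sd = PTV_SIZE_CLASSES[spec.ptv_size_class]
    lo, hi = mean - _TRUNC_SD * sd, mean + _TRUNC_SD * sd
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return mean  # pragma: no cover - truncation loop essentially always exits


def _ptv_keypoint(spec: PhantomSpec, side: str) -> np.ndarray:
    """Target location (world mm) for each PTV location class."""
    sx = 1.0 if side == "right" else -1.0
    lc = np.asarray(spec.lung_center) * np.array([sx, 1.0, 1.0])
    la = np.asarray(spec.lung_semiaxes)
    loc = spec.ptv_location_class
    if loc == "apex":
        rel = (lc[0], lc[1], lc[2] + la[2])
    elif loc == "mediastinum":
        rel = (lc[0] - sx * la[0], lc[1], lc[2])
    elif loc == "ribs":
        rel = (lc[0] + sx * la[0], lc[1], lc[2])
    else:  # spine
        rel = (lc[0], spec.spine_center_y, lc[2])
    return spec._world(tuple(rel))


def _place_ptv(spec: PhantomSpec, lung_masks, rng: np.random.Generator):
    side = spec.ptv_lung_side or ("right" if rng.random() < 0.5 else "left")
    if side not in ("left", "right"):
        raise ValueError(f"ptv_lung_side must be 'left' or 'right', got {side!r}")
    lung = lung_masks[f"lung_{side}"]
    voxvol = float(np.prod(spec.spacing))  # mm^3
    target_cm3 = _draw_ptv_volume(spec, rng)
    n_target = max(1, int(round(target_cm3 * 1000.0 / voxvol)))
    r_eff = (3.0 * n_target * voxvol / (4.0 * np.pi)) ** (1.0 / 3.0)

    edt = ndimage.distance_transform_edt(lung, sampling=spec.spacing)
    margin = float(max(spec.spacing))
    feasible = edt >= (r_eff + margin)
    if not feasible.any():
        raise PTVPlacementError(
            f"PTV of {target_cm3:.1f} cm3 (radius {r_eff:.1f} mm) cannot be placed "
            f"inside {side} lung at location '{spec.ptv_location_class}': no lung voxel "
            f"is at least {r_eff + margin:.1f} mm from the lung surface"
        )
    key = _ptv_keypoint(spec, side)
    idx = np.argwhere(feasible)
    centers = (idx + 0.5) * np.asarray(spec.spacing)
    center = centers[np.argmin(((centers - key) ** 2).sum(axis=1))]

    # take exactly n_target voxels closest to the center -> volume within half
    # a voxel of the drawn target
    X, Y, Z = _coordinate_grids(spec.shape, spec.spacing)
    d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    flat = np.argsort(d2, axis=None, kind="stable")[:n_target]
    ptv = np.zeros(spec.shape, dtype=bool)
    ptv.flat[flat] = True
    if not np.all(lung[ptv]):
        raise PTVPlacementError(
            "selected PTV voxels escape the lung mask; lung too small for "
            f"PTV of {target_cm3:.1f} cm3"
        )
    return ptv, target_cm3


# ---------------------------------------------------------------------------
# ground-truth CT
# ---------------------------------------------------------------------------

def bone_hu_gradient(spine_mask: np.ndarray, spacing) -> np.ndarray:
    """Ground-truth HU inside a bone mask: cortical rim -> marrow core.

    Linear in LAC from 0.2485 cm^-1 at the rim to 0.1 cm^-1 at the deepest
    core, then mapped through the bilinear LAC->HU conversion (70..2661 HU).
    Matches the atlas bone model so that a perfect pipeline reproduces the
    ground truth exactly.
    """
    from .bones import bone_lac_gradient
    from .synct import lac_to_hu_values

    lac = bone_lac_gradient(spine_mask, spacing)
    out = np.zeros(spine_mask.shape)
    if spine_mask.any():
        out[spine_mask] = lac_to_hu_values(lac[spine_mask])
    return out


def _ground_truth_ct(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    hu = np.zeros(spec.shape)
    means = dict(spec.hu_means)
    means[T.LUNG] = means.get(T.LUNG, T.HU_LUNG) + spec.lung_hu_offset
    for code in (T.AIR, T.FAT, T.LUNG, T.SOFT_TISSUE):
        hu[labels == code] = means.get(code, T.CLASS_HU[code])
    bone = labels == T.BONE
    if bone.any():
        if spec.spine_model == "gradient":
            hu[bone] = bone_hu_gradient(bone, spec.spacing)[bone]
        else:
            hu[bone] = spec.spine_uniform_hu
    if spec.hu_noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=spec.shape)
    return hu


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def build_phantom(spec: PhantomSpec):
    """Build one phantom: (label map, ground-truth CT, structure set).

    The PTV is a sphere of lung voxels (the tumor density override happens at
    planning time, as in the clinical workflow), rasterized to exactly
    ``round(volume / voxel_volume)`` voxels so the mask volume is within half
    a voxel of the drawn class volume.
    """
    rng = np.random.default_rng(spec.seed)
    labels, masks = _build_labels_and_masks(spec)
    ptv, drawn_cm3 = _place_ptv(spec, masks, rng)
    masks["PTV"] = ptv
    ct_values = _ground_truth_ct(spec, labels, rng)

    def _grid(v, dtype=None):
        arr = v if dtype is None else v.astype(dtype)
        return VolumeGrid(arr, spec.spacing)

    label_map = T.TissueLabelMap(_grid(labels))
    ct = _grid(ct_values)
    structures = StructureSet({k: _grid(m, np.uint8) for k, m in masks.items()})
    return label_map, ct, structures


def make_phantom(spec: PhantomSpec) -> Phantom:
    """:func:`build_phantom` plus landmarks, bundled."""
    labels, ct, structures = build_phantom(spec)
    voxvol = float(np.prod(spec.spacing))
    vol = float(structures.array("PTV").sum() * voxvol / 1000.0)
    return Phantom(spec, labels, ct, structures, spec.landmarks(), vol)


def simulate_dixon(labels: T.TissueLabelMap, spec: PhantomSpec):
    """Simulate a two-point Dixon water/fat signal pair from a label map.

    Bone voxels receive the soft-tissue signal signature — marrow and
    cortical bone are not separable in Dixon contrast, which is why the bone
    atlas stage exists.  The pair is produced on the (typically coarser) MR
    grid of ``spec`` when it differs from the label grid.
    """
    from .dixon import DixonPair  # local import: avoid cycle at module load
    from .synct import resample

    grid = labels.grid
    if tuple(spec.mr_spacing) != tuple(grid.spacing):
        lab = resample(grid, spec.mr_spacing, mode="nearest")
    else:
        lab = grid
    codes = labels.values if lab is grid else lab.values
    codes = np.where(codes == T.BONE, T.SOFT_TISSUE, codes)

    water = np.zeros(lab.shape)
    fat = np.zeros(lab.shape)
    for code, (w, f) in spec.dixon_signal.items():
        sel = codes == code
        water[sel] = w
        fat[sel] = f
    if spec.mr_noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        water = water + rng.normal(0.0, spec.mr_noise_sd, water.shape)
        fat = fat + rng.normal(0.0, spec.mr_noise_sd, fat.shape)
    water = np.clip(water, 0.0, None)
    fat = np.clip(fat, 0.0, None)
    return DixonPair(
        water=lab.with_values(water),
        fat=lab.with_values(fat),
        noise_sd=spec.mr_noise_sd,
    )


def perturb_geometry(volume: VolumeGrid, magnitude_mm: float, seed: int,
                     n_control: int = 4, order: int = 1):
    """Warp a volume by a smooth random displacement field.

    The field is drawn on a coarse control grid, upsampled with cubic
    splines, and scaled so its maximum voxel norm equals ``magnitude_mm``.
    Returns ``(warped volume, field)`` where ``field`` has shape
    ``(3, *volume.shape)`` in mm: the warped volume samples the input at
    ``x + field(x)`` (so ``field`` is the ground truth a registration of
    the warped volume back onto the input should recover).
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude must be >= 0")
    shape = volume.shape
    field_mm = np.zeros((3,) + shape)
    if magnitude_mm > 0:
        rng = np.random.default_rng(seed)
        coarse = rng.normal(size=(3, n_control, n_control, n_control))
        zoom = [n / n_control for n in shape]
        for c in range(3):
            field_mm[c] = ndimage.zoom(coarse[c], zoom, order=3, mode="nearest",
                                       grid_mode=True)
        norms = np.sqrt((field_mm**2).sum(axis=0))
        peak = norms.max()
        if peak > 0:
            field_mm *= magnitude_mm / peak
    if magnitude_mm == 0:
        return volume.copy(), field_mm

    idx = np.indices(shape, dtype=float)
    sample = idx + field_mm / np.asarray(volume.spacing)[:, None, None, None]
    warped = ndimage.map_coordinates(volume.values.astype(float), sample,
                                     order=order, mode="nearest")
    return volume.with_values(warped), field_mm


def patient_spec_variants(base: PhantomSpec, n_patients: int, seed: int) -> list[PhantomSpec]:
    """Per-patient anatomy variants: per-axis scaling (±6%) and shifts (±4 mm)."""
    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_patients):
        scale = tuple(1.0 + rng.uniform(-0.06, 0.06, 3))
        shift = tuple(rng.uniform(-4.0, 4.0, 3))
        out.append(replace(base, anatomy_scale=scale, anatomy_shift=shift,
                           seed=int(rng.integers(0, 2**31 - 1))))
    return out
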