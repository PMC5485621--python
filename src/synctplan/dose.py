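"""Simplified heterogeneity-corrected photon dose engine and plan handling.

This is a declared stand-in for a commercial convolution/superposition
algorithm.  The dose model keeps the physics that makes lung planning
sensitive to CT-number errors — photon attenuation along the radiological
(water-equivalent) path and density-dependent lateral spread — while
remaining closed-form testable:

    D(r) = w * ISF(r) * exp(-mu_eff * d_rad(r)) * P(lateral; sigma_eff)

where ``d_rad`` is the cumulative density-weighted path from the beam entry,
``ISF`` the inverse-square factor (divergent mode), and ``P`` a flat field
with Gaussian penumbra whose width ``sigma_eff = sigma_lat / max(rho,
rho_floor)`` broadens in low-density lung.  ``mu_eff`` defaults to
0.005 mm^-1 (6-MV-like effective attenuation).

Plans are sets of coplanar beams with scalar weights (monitor-unit
surrogates): weights are fitted by non-negative least squares against PTV
target dose and organ-at-risk upper bounds, then the plan is normalized so
95% of the PTV receives the full prescription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.special import erf

from .dvh import dose_at_volume
from .grid import StructureSet, VolumeGrid
from .synct import CTVolume

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# HU -> relative electron density
# ---------------------------------------------------------------------------

DEFAULT_CALIBRATION_POINTS: tuple[tuple[float, float], ...] = (
    (-1024.0, 0.0),
    (-1000.0, 0.0),
    (0.0, 1.0),
    (70.0, 1.04),
    (1000.0, 1.52),
    (3071.0, 2.59),
)


@dataclass
class CalibrationCurve:
    """Piecewise-linear HU -> relative electron density curve.

    HU strictly increasing, density non-negative and non-decreasing,
    covering the clamped CT range [-1024, 3071]; clamped at the ends.
    """

    points: tuple[tuple[float, float], ...] = DEFAULT_CALIBRATION_POINTS

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("calibration curve needs >= 2 (HU, density) points")
        hu, rho = pts[:, 0], pts[:, 1]
        if not np.all(np.diff(hu) > 0):
            raise ValueError("calibration curve HU values must be strictly increasing")
        if (rho < 0).any() or not np.all(np.diff(rho) >= -1e-12):
            raise ValueError("calibration densities must be non-negative and non-decreasing")
        if hu[0] > -1024 or hu[-1] < 3071:
            raise ValueError("calibration curve must cover HU range [-1024, 3071]")
        self._hu, self._rho = hu, rho

    def density(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(hu, dtype=float), self._hu, self._rho)


def hu_to_density(curve: CalibrationCurve, ct: CTVolume) -> VolumeGrid:
    """Relative-electron-density volume for dose calculation."""
    return ct.grid.with_values(curve.density(ct.grid.values))


# ---------------------------------------------------------------------------
# plan / beam specifications
# ---------------------------------------------------------------------------

@dataclass
class BeamSpec:
    """One coplanar photon beam.

    Gantry angle in degrees rotates the source around the patient z
    (superior-inferior) axis; 0 deg means the beam travels along +y.
    ``weight`` is the monitor-unit surrogate.
    """

    gantry_deg: float
    isocenter_mm: tuple[float, float, float]
    field_size_mm: tuple[float, float] = (50.0, 50.0)
    weight: float = 1.0
    sad_mm: float = 1000.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("beam weight must be >= 0")
        if any(f <= 0 for f in self.field_size_mm):
            raise ValueError("field size must be > 0")

    def direction(self) -> np.ndarray:
        th = np.deg2rad(self.gantry_deg)
        return np.array([np.sin(th), np.cos(th), 0.0])

    def lateral_axis(self) -> np.ndarray:
        th = np.deg2rad(self.gantry_deg)
        return np.array([np.cos(th), -np.sin(th), 0.0])


@dataclass
class PlanSpec:
    """Prescription, fractionation and beam arrangement."""

    beams: list[BeamSpec]
    prescription_gy: float
    dose_per_fraction_gy: float
    n_fractions: int
    scheme: str = "custom"
    normalization_factor: float | None = None

    def __post_init__(self) -> None:
        if abs(self.prescription_gy - self.dose_per_fraction_gy * self.n_fractions) > 1e-6:
            raise ValueError(
                f"prescription {self.prescription_gy} Gy != "
                f"{self.dose_per_fraction_gy} Gy/fx x {self.n_fractions} fx"
            )

    @property
    def weights(self) -> np.ndarray:
        return np.array([b.weight for b in self.beams])

    def with_weights(self, weights) -> "PlanSpec":
        beams = [replace(b, weight=float(w)) for b, w in zip(self.beams, weights)]
        return replace(self, beams=beams)

    @classmethod
    def imrt(cls, isocenter_mm, n_beams: int = 7, field_size_mm=(50.0, 50.0)) -> "PlanSpec":
        """Conventionally fractionated plan: 59.40 Gy at 1.8 Gy x 33 fx."""
        return cls(equispaced_beams(isocenter_mm, n_beams, field_size_mm),
                   59.40, 1.8, 33, scheme="IMRT")

    @classmethod
    def sbrt(cls, isocenter_mm, n_beams: int = 7, field_size_mm=(50.0, 50.0)) -> "PlanSpec":
        """Stereotactic plan: 60 Gy at 20 Gy x 3 fx."""
        return cls(equispaced_beams(isocenter_mm, n_beams, field_size_mm),
                   60.0, 20.0, 3, scheme="SBRT")


def equispaced_beams(isocenter_mm, n_beams: int, field_size_mm=(50.0, 50.0),
                     start_deg: float = 0.0) -> list[BeamSpec]:
    """Equispaced coplanar beam arrangement (the default for 5/7/9-beam plans)."""
    if n_beams < 1:
        raise ValueError("need at least one beam")
    angles = start_deg + np.arange(n_beams) * 360.0 / n_beams
    return [BeamSpec(gantry_deg=float(a), isocenter_mm=tuple(isocenter_mm),
                     field_size_mm=tuple(field_size_mm)) for a in angles]


@dataclass
class EngineConfig:
    """Dose-engine constants."""

    mu_eff_per_mm: float = 0.005   # effective linear attenuation in water
    sigma_lat_mm: float = 3.0      # lateral penumbra sigma in water
    rho_floor: float = 0.15        # density floor for penumbra broadening
    mode: str = "divergent"        # "divergent" | "parallel"
    # lateral beam-frame coverage beyond the field edge (mm); None = cover
    # the whole grid (exact, slower)
    lateral_margin_mm: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("divergent", "parallel"):
            raise ValueError(f"mode must be 'divergent' or 'parallel', got {self.mode!r}")


# ---------------------------------------------------------------------------
# Siddon ray tracing
# ---------------------------------------------------------------------------

@dataclass
class RayProfile:
    """Exact voxel-intersection profile of one ray through a density grid.

    ``t`` are distances (mm) from the ray origin at segment boundaries
    (len N+1), ``indices`` the traversed voxels (N, 3), ``seg_lengths`` the
    geometric intersection lengths (mm), and ``weq_cum`` the cumulative
    water-equivalent depth (mm) at each segment end.
    """

    t: np.ndarray
    indices: np.ndarray
    seg_lengths: np.ndarray
    weq_cum: np.ndarray

    @property
    def empty(self) -> bool:
        return self.seg_lengths.size == 0

    @property
    def total_weq(self) -> float:
        return float(self.weq_cum[-1]) if not self.empty else 0.0


def radiological_depth(density: VolumeGrid, origin_mm, direction) -> RayProfile:
    """Siddon-style exact ray tracing: water-equivalent depth along a ray.

    The water-equivalent depth is the sum of (density x geometric
    intersection length) over traversed voxels.  A ray missing the grid
    returns an empty profile.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("ray direction must be non-zero")
    d = d / norm
    o = np.asarray(origin_mm, dtype=float)
    g0 = np.asarray(density.origin)
    sp = np.asarray(density.spacing)
    n = np.asarray(density.shape)

    # slab intersection
    tmin, tmax = -np.inf, np.inf
    for ax in range(3):
        lo, hi = g0[ax], g0[ax] + n[ax] * sp[ax]
        if d[ax] == 0:
            if not (lo <= o[ax] <= hi):
                return RayProfile(np.empty(0), np.empty((0, 3), int), np.empty(0), np.empty(0))
        else:
            t0, t1 = (lo - o[ax]) / d[ax], (hi - o[ax]) / d[ax]
            tmin, tmax = max(tmin, min(t0, t1)), min(tmax, max(t0, t1))
    if tmax <= tmin:
        return RayProfile(np.empty(0), np.empty((0, 3), int), np.empty(0), np.empty(0))
    tmin = max(tmin, 0.0)
    if tmax <= tmin:
        return RayProfile(np.empty(0), np.empty((0, 3), int), np.empty(0), np.empty(0))

    ts = [np.array([tmin, tmax])]
    for ax in range(3):
        if d[ax] != 0:
            planes = g0[ax] + np.arange(n[ax] + 1) * sp[ax]
            tp = (planes - o[ax]) / d[ax]
            ts.append(tp[(tp > tmin) & (tp < tmax)])
    t_all = np.unique(np.concatenate(ts))
    mid = o[None, :] + 0.5 * (t_all[:-1, None] + t_all[1:, None]) * d[None, :]
    idx = np.floor((mid - g0) / sp).astype(int)
    valid = np.all((idx >= 0) & (idx < n), axis=1)
    seg = np.diff(t_all)
    # drop degenerate slivers from coincident planes
    keep = valid & (seg > 1e-12)
    idx, seg = idx[keep], seg[keep]
    t_edges = np.concatenate([[tmin], tmin + np.cumsum(np.diff(t_all)[keep])]) if keep.any() else np.empty(0)
    rho = density.values[idx[:, 0], idx[:, 1], idx[:, 2]] if idx.size else np.empty(0)
    weq = np.cumsum(rho * seg)
    return RayProfile(t_edges, idx, seg, weq)


# ---------------------------------------------------------------------------
# beam dose (beam-frame broad-beam model)
# ---------------------------------------------------------------------------

def _edge_profile(x: np.ndarray, half_width: float, sigma: np.ndarray) -> np.ndarray:
    """Flat field of given half width convolved with a Gaussian penumbra."""
    s = np.sqrt(2.0) * sigma
    return 0.5 * (erf((half_width - x) / s) + erf((half_width + x) / s))


def _beam_frame(beam: BeamSpec, grid: VolumeGrid, margin_mm: float | None):
    """Lattices (u lateral, v axial-z, w depth) around the isocenter.

    The depth axis always spans the whole grid (attenuation needs the full
    entry path); the lateral axes span the whole grid too unless a finite
    ``margin_mm`` truncates them at field edge + margin (dose beyond is
    penumbra tail, treated as zero)."""
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    sp = grid.spacing
    sp_lat = min(sp[0], sp[1])
    # x-y corner radius around the isocenter
    xs = [grid.origin[0], grid.origin[0] + grid.shape[0] * sp[0]]
    ys = [grid.origin[1], grid.origin[1] + grid.shape[1] * sp[1]]
    r = max(np.hypot(x - iso[0], y - iso[1]) for x in xs for y in ys)
    n_w = int(np.ceil(2 * r / sp_lat)) + 3
    w = (np.arange(n_w) - (n_w - 1) / 2) * sp_lat
    half_u = r if margin_mm is None else min(r, beam.field_size_mm[0] / 2 + margin_mm)
    n_u = int(np.ceil(2 * half_u / sp_lat)) + 3
    u = (np.arange(n_u) - (n_u - 1) / 2) * sp_lat
    v = grid.voxel_centers(2) - iso[2]
    if margin_mm is not None:
        half_v = beam.field_size_mm[1] / 2 + margin_mm
        keep = np.abs(v) <= half_v
        if keep.any():
            v = v[keep]
    return u, v, w, sp_lat


def beam_dose(beam: BeamSpec, density: VolumeGrid,
              config: EngineConfig | None = None) -> VolumeGrid:
    """Dose of a single beam on the density grid (Gy per unit weight x weight).

    The density is resampled into the beam frame, the radiological depth is
    accumulated along the beam axis, and the attenuation x inverse-square x
    penumbra model is evaluated there and mapped back to the patient grid.
    A zero-density volume yields a uniform unattenuated beam (logged).
    """
    config = config or EngineConfig()
    iso = np.asarray(beam.isocenter_mm, dtype=float)
    e1, e3 = beam.lateral_axis(), beam.direction()
    e2 = np.array([0.0, 0.0, 1.0])
    u, v, w, sp_lat = _beam_frame(beam, density, config.lateral_margin_mm)

    if not np.any(density.values > 0):
        log.info("beam %s deg: zero density everywhere, uniform unattenuated beam",
                 beam.gantry_deg)

    U, V, W = np.meshgrid(u, v, w, indexing="ij")
    pts = (iso[None, :]
           + U.reshape(-1, 1) * e1[None, :]
           + V.reshape(-1, 1) * e2[None, :]
           + W.reshape(-1, 1) * e3[None, :])
    bidx = density.world_to_index(pts).T
    rho_b = ndimage.map_coordinates(
        density.values.astype(np.float32), bidx.astype(np.float32),
        order=1, mode="grid-constant", cval=0.0,
    ).reshape(U.shape)

    sp_w = w[1] - w[0] if w.size > 1 else sp_lat
    d_rad = np.cumsum(rho_b, axis=2) * sp_w - 0.5 * rho_b * sp_w
    atten = np.exp(-config.mu_eff_per_mm * d_rad)

    if config.mode == "divergent":
        dist = beam.sad_mm + W
        dist = np.maximum(dist, 1.0)
        isf = (beam.sad_mm / dist) ** 2
        proj = beam.sad_mm / dist
    else:
        isf = 1.0
        proj = 1.0

    sigma_eff = config.sigma_lat_mm / np.maximum(rho_b, config.rho_floor)
    hx, hz = beam.field_size_mm[0] / 2.0, beam.field_size_mm[1] / 2.0
    profile = (_edge_profile(U * proj, hx, sigma_eff)
               * _edge_profile(V * proj, hz, sigma_eff))

    dose_b = (beam.weight * atten * isf * profile).astype(np.float32)

    # map back to the patient grid
    idx = np.indices(density.shape, dtype=float).reshape(3, -1).T
    p = density.index_to_world(idx) - iso
    cu = (p @ e1 - u[0]) / sp_lat
    cv = (p @ e2 - v[0]) / (v[1] - v[0] if v.size > 1 else density.spacing[2])
    cw = (p @ e3 - w[0]) / sp_w
    vals = ndimage.map_coordinates(
        dose_b, np.stack([cu, cv, cw]).astype(np.float32),
        order=1, mode="grid-constant", cval=0.0,
    )
    return density.with_values(np.maximum(vals.reshape(density.shape), 0.0).astype(float))


def unit_beam_doses(plan: PlanSpec, density: VolumeGrid,
                    config: EngineConfig | None = None) -> list[VolumeGrid]:
    """Per-beam doses at unit weight (cached building block for optimization)."""
    return [beam_dose(replace(b, weight=1.0), density, config) for b in plan.beams]


def compose_plan(plan: PlanSpec, density: VolumeGrid,
                 config: EngineConfig | None = None,
                 unit_doses: list[VolumeGrid] | None = None) -> VolumeGrid:
    """Total plan dose: weighted sum of per-beam doses."""
    if not plan.beams:
        raise ValueError("plan has no beams")
    if unit_doses is None:
        unit_doses = unit_beam_doses(plan, density, config)
    total = np.zeros(density.shape)
    for b, ud in zip(plan.beams, unit_doses):
        total += b.weight * ud.values
    return density.with_values(total)


# ---------------------------------------------------------------------------
# weight optimization and normalization
# ---------------------------------------------------------------------------

@dataclass
class Objectives:
    """Dose objectives: PTV target plus organ-at-risk upper bounds (Gy)."""

    ptv_dose_gy: float
    oar_bounds_gy: dict[str, float] = field(default_factory=dict)
    oar_penalty: float = 0.3
    n_samples: int = 400


def optimize_weights(
    plan: PlanSpec,
    density: VolumeGrid,
    structures: StructureSet,
    objectives: Objectives,
    config: EngineConfig | None = None,
    unit_doses: list[VolumeGrid] | None = None,
    seed: int = 0,
) -> PlanSpec:
    """Fit non-negative beam weights by least squares on sampled voxels.

    PTV voxels target the prescription; OAR voxels above their bound are
    penalized toward it.  If the initial weights already achieve an equal or
    lower objective value, they are kept (the objective never increases).
    Infeasible bounds produce a best-effort solution with a warning.
    """
    config = config or EngineConfig()
    if unit_doses is None:
        unit_doses = unit_beam_doses(plan, density, config)
    rng = np.random.default_rng(seed)

    def _sample(mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        if len(idx) > objectives.n_samples:
            idx = idx[rng.choice(len(idx), objectives.n_samples, replace=False)]
        return idx

    rows, targets, wts = [], [], []
    ptv_idx = _sample(structures.array("PTV"))
    if ptv_idx.size == 0:
        raise ValueError("objectives require a non-empty PTV")
    A_ptv = np.stack(
        [ud.values[ptv_idx[:, 0], ptv_idx[:, 1], ptv_idx[:, 2]] for ud in unit_doses],
        axis=1,
    )
    rows.append(A_ptv)
    targets.append(np.full(len(ptv_idx), objectives.ptv_dose_gy))
    wts.append(np.ones(len(ptv_idx)))

    for organ, bound in objectives.oar_bounds_gy.items():
        if organ not in structures:
            continue
        oidx = _sample(structures.array(organ))
        if oidx.size == 0:
            continue
        A = np.stack(
            [ud.values[oidx[:, 0], oidx[:, 1], oidx[:, 2]] for ud in unit_doses],
            axis=1,
        )
        rows.append(A)
        targets.append(np.full(len(oidx), bound))
        wts.append(np.full(len(oidx), objectives.oar_penalty))

    A = np.vstack(rows)
    b = np.concatenate(targets)
    sw = np.sqrt(np.concatenate(wts))

    def _objective(x):
        r = A @ x - b
        # OAR rows only penalize exceeding the bound
        n_ptv = len(ptv_idx)
        r[n_ptv:] = np.maximum(r[n_ptv:], 0.0)
        return float(np.sum((sw * r) ** 2))

    x_nnls, _ = optimize.nnls(sw[:, None] * A, sw * b)
    x0 = plan.weights
    if _objective(x0) <= _objective(x_nnls) + 1e-9:
        best = x0
    else:
        best = x_nnls

    # feasibility report
    for organ, bound in objectives.oar_bounds_gy.items():
        if organ not in structures:
            continue
        mask = structures.array(organ)
        dose = sum(w * ud.values[mask] for w, ud in zip(best, unit_doses))
        if np.size(dose) and np.max(dose) > bound * 1.05:
            log.warning(
                "objective set infeasible: %s max dose %.2f Gy exceeds bound %.2f Gy "
                "(best-effort weights kept)", organ, float(np.max(dose)), bound,
            )
    return plan.with_weights(best)


def normalize_plan(
    plan: PlanSpec,
    dose: VolumeGrid,
    ptv: VolumeGrid,
    prescription_gy: float | None = None,
) -> tuple[PlanSpec, VolumeGrid, float]:
    """Scale the plan so 95% of the PTV receives the full prescription.

    The single global factor is s = prescription / D95(PTV); weights and
    dose are multiplied by s and s is recorded on the plan.  Normalizing an
    already-normalized plan yields s = 1.
    """
    prescription = prescription_gy if prescription_gy is not None else plan.prescription_gy
    mask = ptv.values.astype(bool)
    if not mask.any():
        raise ValueError("cannot normalize: PTV mask is empty")
    d95 = dose_at_volume(dose.values[mask], 95.0)
    if d95 <= 0:
        raise ValueError("cannot normalize: PTV D95 is zero")
    s = prescription / d95
    scaled_plan = plan.with_weights(plan.weights * s)
    scaled_plan.normalization_factor = s
    return scaled_plan, dose.with_values(dose.values * s), s


def recompute_on(
    plan: PlanSpec,
    other_ct: CTVolume,
    curve: CalibrationCurve,
    config: EngineConfig | None = None,
    reference_grid: VolumeGrid | None = None,
) -> VolumeGrid:
    """Recalculate the plan on another CT with identical beams and weights.

    Only the density grid changes ("same MUs"); the CT must already live on
    the planning grid used for the original calculation.
    """
    density = hu_to_density(curve, other_ct)
    if reference_grid is not None and not density.same_grid(reference_grid):
        raise ValueError(
            "CT grid does not match the planning grid; register/resample first"
        )
    return compose_plan(plan, density, config)
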