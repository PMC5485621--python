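"""End-to-end phantom study: phantom -> synCT -> plans -> dose agreement.

Mirrors the clinical workflow: tissue classification of the simulated Dixon
pair, atlas bone insertion, LAC-to-HU conversion (synCT), the ground-truth
CT acting as the planning CT (optionally degraded by a patient-level lung
HU offset, voxel noise and a smooth residual misalignment field), PTV
density override on both, plan optimization and normalization on the
synCT, recalculation on the planCT with the same beam weights, then DVH
metrics, 3D gamma analysis and group statistics.

Two stock configurations:

* :func:`identity_config` — zero noise, matched grids, no misalignment:
  the synCT must reproduce the planCT exactly, so the doses agree at every
  gamma criterion.
* :func:`standard_fixture_config` — the 43-PTV study layout (18 small, 13
  medium, 12 large; 9 apex / 16 mediastinum / 9 ribs / 9 spine) across 11
  anatomy variants, with a ~30 HU lung offset scale and 2 mm residual
  misalignment.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phantom as ph
from . import tissues as T
from .bones import build_spine_atlas, insert_bones, register_atlas
from .classify import assign_lac, classify_voxels, compute_body_mask
from .dose import (
    CalibrationCurve,
    EngineConfig,
    Objectives,
    PlanSpec,
    compose_plan,
    hu_to_density,
    normalize_plan,
    optimize_weights,
    unit_beam_doses,
)
from .dvh import compute_metric_set
from .gamma import STANDARD_CRITERIA, GammaCriteria, gamma_map
from .grid import StructureSet, VolumeGrid
from .stats import build_report, paired_metric_table
from .synct import CTVolume, lac_to_hu, override_ptv_density, resample

log = logging.getLogger(__name__)

STUDY_SIZE_COUNTS = {"small": 18, "medium": 13, "large": 12}
STUDY_LOCATION_COUNTS = {"apex": 9, "mediastinum": 16, "ribs": 9, "spine": 9}


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; defaults give the standard fixture."""

    seed: int = 0
    n_patients: int = 11
    size_counts: dict = field(default_factory=lambda: dict(STUDY_SIZE_COUNTS))
    location_counts: dict = field(default_factory=lambda: dict(STUDY_LOCATION_COUNTS))

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    mr_spacing: tuple[float, float, float] = (2.6, 2.6, 3.12)
    vary_anatomy: bool = True

    hu_noise_sd: float = 20.0
    mr_noise_sd: float = 2.0
    lung_hu_offset_max: float = 30.0   # per-patient offset ~ U(-max, +max)
    misalignment_mm: float = 2.0       # residual synCT-vs-planCT misalignment
    deformable_atlas: bool = False     # landmark affine only inside the loop

    n_beams: int = 7
    field_margin_mm: float = 8.0
    cord_bound_gy: float = 45.0
    heart_bound_gy: float = 40.0
    sbrt_for_small: bool = True

    gamma_threshold_pct: float = 10.0
    gamma_refine: bool = False         # coarse-only: conservative pass rates
    engine: EngineConfig = field(default_factory=lambda: EngineConfig(lateral_margin_mm=50.0))
    calibration: CalibrationCurve = field(default_factory=CalibrationCurve)


def identity_config(n_plans: int = 3) -> PipelineConfig:
    """Zero-noise, matched-grid, zero-misalignment configuration."""
    sizes = ["small", "medium", "large"]
    locs = ["apex", "ribs", "spine", "mediastinum"]
    return PipelineConfig(
        n_patients=1,
        size_counts={s: sum(1 for i in range(n_plans) if sizes[i % 3] == s) for s in sizes},
        location_counts={l: sum(1 for i in range(n_plans) if locs[i % 4] == l) for l in locs},
        mr_spacing=(2.5, 2.5, 2.5),
        vary_anatomy=False,
        hu_noise_sd=0.0,
        mr_noise_sd=0.0,
        lung_hu_offset_max=0.0,
        misalignment_mm=0.0,
    )


def standard_fixture_config(seed: int = 0) -> PipelineConfig:
    """The 43-PTV study fixture with paper-scale perturbations."""
    return PipelineConfig(seed=seed)


@dataclass
class PlanOutcome:
    plan_id: int
    patient: int
    size_class: str
    location_class: str
    ptv_volume_cm3: float
    prescription_gy: float
    normalization_factor: float
    metrics_syn: dict
    metrics_plan: dict
    gamma_pass: dict  # criterion label -> pass rate %


@dataclass
class PipelineResult:
    config: PipelineConfig
    outcomes: list[PlanOutcome]
    metrics: pd.DataFrame        # long table with synCT/planCT values + differences
    gamma: pd.DataFrame          # per plan x criterion pass rates
    organ_hu: pd.DataFrame       # per patient organ mean HU comparison
    runtime_s: float

    def gamma_mean(self, criterion_label: str) -> float:
        sub = self.gamma[self.gamma["criterion"] == criterion_label]
        return float(sub["pass_rate"].mean())

    def mean_metric_difference(self, metric: str) -> float:
        sub = self.metrics[self.metrics["metric"] == metric]
        return float(sub["difference"].mean())


def _plan_roster(config: PipelineConfig, rng: np.random.Generator):
    sizes = [s for s, n in config.size_counts.items() for _ in range(n)]
    locs = [l for l, n in config.location_counts.items() for _ in range(n)]
    if len(sizes) != len(locs):
        raise ValueError(
            f"size counts ({len(sizes)}) and location counts ({len(locs)}) disagree"
        )
    rng.shuffle(locs)
    return list(zip(sizes, locs))


def _patient_specs(config: PipelineConfig, rng: np.random.Generator):
    base = ph.PhantomSpec(
        shape=config.shape,
        spacing=config.spacing,
        mr_spacing=config.mr_spacing,
        hu_noise_sd=config.hu_noise_sd,
        mr_noise_sd=config.mr_noise_sd,
    )
    if config.vary_anatomy:
        specs = ph.patient_spec_variants(base, config.n_patients,
                                         seed=int(rng.integers(2**31 - 1)))
    else:
        specs = [dataclasses.replace(base, seed=int(rng.integers(2**31 - 1)))
                 for _ in range(config.n_patients)]
    if config.lung_hu_offset_max > 0:
        specs = [
            dataclasses.replace(
                s, lung_hu_offset=float(rng.uniform(-config.lung_hu_offset_max,
                                                    config.lung_hu_offset_max)))
            for s in specs
        ]
    return specs


@dataclass
class _PatientData:
    spec: ph.PhantomSpec
    structures_nonptv: dict
    lung_masks: dict
    synct: CTVolume
    planct: CTVolume


def _build_patient(config: PipelineConfig, spec: ph.PhantomSpec, atlas,
                   rng: np.random.Generator) -> _PatientData:
    labels_arr, masks = ph._build_labels_and_masks(spec)
    ct_true = ph._ground_truth_ct(spec, labels_arr, np.random.default_rng(spec.seed))
    truth = VolumeGrid(ct_true, spec.spacing)

    # planning CT: ground truth plus the residual misalignment
    if config.misalignment_mm > 0:
        warped, _ = ph.perturb_geometry(truth, config.misalignment_mm,
                                        seed=int(rng.integers(2**31 - 1)))
        planct = CTVolume(warped, "planCT")
    else:
        planct = CTVolume(truth.copy(), "planCT")

    # synCT branch: Dixon -> classification -> LAC -> bones -> HU
    label_map = T.TissueLabelMap(VolumeGrid(labels_arr, spec.spacing))
    dixon = ph.simulate_dixon(label_map, spec)
    body = compute_body_mask(dixon)
    mr_labels = classify_voxels(dixon, body)
    amap = assign_lac(mr_labels)
    t_atlas = register_atlas(atlas, dixon, spec.landmarks(),
                             deformable=config.deformable_atlas)
    amap = insert_bones(amap, atlas, t_atlas)
    synct = lac_to_hu(amap, provenance="synCT")
    if not synct.grid.same_grid(planct.grid):
        synct = CTVolume(
            resample(synct.grid, config.spacing, mode="linear", fill=T.HU_AIR),
            "synCT",
        )
        if synct.grid.shape != planct.grid.shape:  # FOV rounding
            synct = CTVolume(_match_shape(synct.grid, planct.grid, T.HU_AIR), "synCT")

    structures = {k: v for k, v in masks.items()}
    return _PatientData(
        spec=spec,
        structures_nonptv=structures,
        lung_masks={"lung_left": masks["lung_left"], "lung_right": masks["lung_right"]},
        synct=synct,
        planct=planct,
    )


def _match_shape(vol: VolumeGrid, ref: VolumeGrid, fill: float) -> VolumeGrid:
    out = np.full(ref.shape, fill, dtype=float)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(vol.shape, ref.shape))
    out[sl] = vol.values[sl]
    return ref.with_values(out)


def _field_size_for(ptv_volume_cm3: float, margin_mm: float) -> tuple[float, float]:
    r = (3.0 * ptv_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    side = 2.0 * r + 2.0 * margin_mm
    return (side, side)


def run_plan(config: PipelineConfig, patient: _PatientData, plan_id: int,
             patient_id: int, size_class: str, location_class: str,
             seed: int) -> PlanOutcome:
    """Plan one PTV on the patient's synCT and recompute on the planCT."""
    spec = dataclasses.replace(
        patient.spec, ptv_size_class=size_class,
        ptv_location_class=location_class, seed=seed,
    )
    rng = np.random.default_rng(seed)
    ptv_arr, drawn_cm3 = ph._place_ptv(
        spec, {k: v for k, v in patient.lung_masks.items()}, rng
    )
    grid = patient.planct.grid
    masks = {k: grid.with_values(v.astype(np.uint8))
             for k, v in patient.structures_nonptv.items()}
    masks["PTV"] = grid.with_values(ptv_arr.astype(np.uint8))
    structures = StructureSet(masks)
    ptv_volume = float(ptv_arr.sum() * grid.voxel_volume_mm3 / 1000.0)

    synct_o = override_ptv_density(patient.synct, masks["PTV"])
    planct_o = override_ptv_density(patient.planct, masks["PTV"])

    # plan on the synCT
    idx = np.argwhere(ptv_arr)
    iso = tuple(grid.index_to_world(idx.mean(axis=0))[0])
    field_size = _field_size_for(ptv_volume, config.field_margin_mm)
    if config.sbrt_for_small and size_class == "small":
        plan = PlanSpec.sbrt(iso, config.n_beams, field_size)
    else:
        plan = PlanSpec.imrt(iso, config.n_beams, field_size)

    dens_syn = hu_to_density(config.calibration, synct_o)
    uds = unit_beam_doses(plan, dens_syn, config.engine)
    objectives = Objectives(
        ptv_dose_gy=plan.prescription_gy,
        oar_bounds_gy={"spinal_cord": config.cord_bound_gy,
                       "heart": config.heart_bound_gy},
    )
    plan = optimize_weights(plan, dens_syn, structures, objectives,
                            config.engine, unit_doses=uds, seed=seed)
    dose_syn = compose_plan(plan, dens_syn, config.engine, unit_doses=uds)
    plan, dose_syn, s = normalize_plan(plan, dose_syn, masks["PTV"])

    # same MUs on the planCT
    dens_plan = hu_to_density(config.calibration, planct_o)
    dose_plan = compose_plan(plan, dens_plan, config.engine)

    m_syn = compute_metric_set(dose_syn, structures, plan.prescription_gy).as_dict()
    m_plan = compute_metric_set(dose_plan, structures, plan.prescription_gy).as_dict()

    gamma_pass = {}
    for dd, dta in STANDARD_CRITERIA:
        c = GammaCriteria(dd_pct=dd, dta_mm=dta,
                          threshold_pct=config.gamma_threshold_pct)
        res = gamma_map(dose_plan, dose_syn, c, refine=config.gamma_refine)
        gamma_pass[c.label()] = res.pass_rate_pct

    return PlanOutcome(
        plan_id=plan_id, patient=patient_id, size_class=size_class,
        location_class=location_class, ptv_volume_cm3=ptv_volume,
        prescription_gy=plan.prescription_gy, normalization_factor=s,
        metrics_syn=m_syn, metrics_plan=m_plan, gamma_pass=gamma_pass,
    )


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Run the full study: all patients, all PTVs, metrics, gamma, report."""
    t0 = time.time()
    config = config or standard_fixture_config()
    rng = np.random.default_rng(config.seed)
    roster = _plan_roster(config, rng)
    specs = _patient_specs(config, rng)

    atlas_spec = ph.PhantomSpec(
        shape=config.shape, spacing=config.spacing, mr_spacing=config.mr_spacing,
        hu_noise_sd=0.0, mr_noise_sd=0.0,
    )
    atlas = build_spine_atlas(atlas_spec)

    from .synct import organ_mean_hu_table

    patients: list[_PatientData] = []
    organ_rows = []
    for pid, spec in enumerate(specs):
        log.info("pipeline: building patient %d/%d", pid + 1, len(specs))
        pdata = _build_patient(config, spec, atlas, rng)
        patients.append(pdata)
        grid = pdata.planct.grid
        st = StructureSet({k: grid.with_values(v.astype(np.uint8))
                           for k, v in pdata.structures_nonptv.items()})
        tab = organ_mean_hu_table(pdata.synct, pdata.planct, st)
        tab.insert(0, "patient", pid)
        organ_rows.append(tab)

    plan_seeds = rng.integers(0, 2**31 - 1, size=len(roster))
    outcomes = []
    for plan_id, (size_class, location_class) in enumerate(roster):
        pid = plan_id % len(patients)
        log.info("pipeline: plan %d/%d (%s, %s, patient %d)",
                 plan_id + 1, len(roster), size_class, location_class, pid)
        outcomes.append(
            run_plan(config, patients[pid], plan_id, pid, size_class,
                     location_class, int(plan_seeds[plan_id]))
        )

    metric_rows, gamma_rows = [], []
    for oc in outcomes:
        for metric in oc.metrics_syn:
            metric_rows.append({
                "plan_id": oc.plan_id, "size_class": oc.size_class,
                "location_class": oc.location_class, "metric": metric,
                "synct_value": oc.metrics_syn[metric],
                "planct_value": oc.metrics_plan[metric],
            })
        for crit, pr in oc.gamma_pass.items():
            gamma_rows.append({
                "plan_id": oc.plan_id, "size_class": oc.size_class,
                "location_class": oc.location_class, "criterion": crit,
                "pass_rate": pr,
            })
    metrics = paired_metric_table(pd.DataFrame(metric_rows))
    gamma = pd.DataFrame(gamma_rows)
    organ_hu = pd.concat(organ_rows, ignore_index=True)

    result = PipelineResult(config, outcomes, metrics, gamma, organ_hu,
                            runtime_s=time.time() - t0)
    if out_dir is not None:
        build_report(out_dir, metrics=metrics, organ_hu=organ_hu,
                     gamma_results=gamma)
    return result
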