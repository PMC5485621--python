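"""Volume, mask, plan and config I/O (NIfTI + JSON + YAML).

Volumes round-trip losslessly: values, spacing, origin and orientation are
preserved bit-for-bit.  Only axis-aligned, positively oriented volumes are
accepted on read; an unexpected orientation raises instead of silently
reorienting.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dose import BeamSpec, PlanSpec
from .grid import StructureSet, VolumeGrid


def write_volume(volume: VolumeGrid, path) -> Path:
    """Write a volume as NIfTI; origin is encoded as the voxel-(0,0,0) center."""
    path = Path(path)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    affine[:3, 3] = [o + 0.5 * s for o, s in zip(volume.origin, volume.spacing)]
    img = nib.Nifti1Image(np.asarray(volume.values), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_volume(path, orientation: str = "RAS") -> VolumeGrid:
    img = nib.load(str(path))
    affine = img.affine
    off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
    if not np.allclose(off_diag, 0.0, atol=1e-6) or np.any(np.diag(affine[:3, :3]) <= 0):
        raise ValueError(
            f"{path}: unsupported orientation (affine must be axis-aligned with "
            "positive spacing); reorient explicitly, no silent reorientation"
        )
    spacing = tuple(np.diag(affine[:3, :3]))
    origin = tuple(affine[i, 3] - 0.5 * spacing[i] for i in range(3))
    values = np.asanyarray(img.dataobj)
    return VolumeGrid(values, spacing, origin, orientation)


def write_mask(mask: VolumeGrid, path) -> Path:
    return write_volume(mask.with_values(mask.values.astype(np.uint8)), path)


def write_structures(structures: StructureSet, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return {name: write_mask(structures[name], out / f"{name}.nii.gz")
            for name in structures.names}


def read_structures(in_dir) -> StructureSet:
    masks = {}
    for p in sorted(Path(in_dir).glob("*.nii*")):
        name = p.name.split(".nii")[0]
        masks[name] = read_volume(p)
    if not masks:
        raise FileNotFoundError(f"no NIfTI masks found in {in_dir}")
    return StructureSet(masks)


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

def plan_to_dict(plan: PlanSpec) -> dict:
    return {
        "prescription_gy": plan.prescription_gy,
        "dose_per_fraction_gy": plan.dose_per_fraction_gy,
        "n_fractions": plan.n_fractions,
        "scheme": plan.scheme,
        "normalization_factor": plan.normalization_factor,
        "beams": [dataclasses.asdict(b) for b in plan.beams],
    }


def plan_from_dict(d: dict) -> PlanSpec:
    beams = [BeamSpec(**{**b,
                         "isocenter_mm": tuple(b["isocenter_mm"]),
                         "field_size_mm": tuple(b["field_size_mm"])})
             for b in d["beams"]]
    return PlanSpec(
        beams=beams,
        prescription_gy=d["prescription_gy"],
        dose_per_fraction_gy=d["dose_per_fraction_gy"],
        n_fractions=d["n_fractions"],
        scheme=d.get("scheme", "custom"),
        normalization_factor=d.get("normalization_factor"),
    )


def write_plan(plan: PlanSpec, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(plan_to_dict(plan), indent=2))
    return path


def read_plan(path) -> PlanSpec:
    return plan_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# configs (dataclass <-> YAML)
# ---------------------------------------------------------------------------

def save_config(config, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))
    return path


def load_config(cls, path):
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    # restore tuples for sequence-typed fields and nested config dataclasses
    from .dose import CalibrationCurve, EngineConfig

    kwargs = {k: tuple(v) if isinstance(v, list) and k.endswith(("shape", "spacing"))
              else v for k, v in data.items()}
    if isinstance(kwargs.get("engine"), dict):
        kwargs["engine"] = EngineConfig(**kwargs["engine"])
    if isinstance(kwargs.get("calibration"), dict):
        pts = kwargs["calibration"].get("points", [])
        kwargs["calibration"] = CalibrationCurve(tuple(tuple(p) for p in pts))
    return cls(**kwargs)
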