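"""Tissue classes, their 511-keV attenuation coefficients and CT numbers.

The soft-tissue classes produced by Dixon classification (air, fat, lung,
soft tissue) each carry a single linear attenuation coefficient (LAC, cm^-1)
at 511 keV; bone is added later from an atlas and spans a continuous LAC
interval from marrow (0.1 cm^-1) to dense cortical bone (0.2485 cm^-1).
The corresponding kilovoltage-CT Hounsfield units are the anchor values of
the bilinear LAC-to-HU conversion: -1000 (air), -110 (fat), -767 (lung) and
70 (soft tissue), with bone mapped linearly onto [70, 2661] HU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid

# integer label codes
AIR = 0
FAT = 1
LUNG = 2
SOFT_TISSUE = 3
BONE = 4

LABEL_NAMES: dict[int, str] = {
    AIR: "air",
    FAT: "fat",
    LUNG: "lung",
    SOFT_TISSUE: "soft_tissue",
    BONE: "bone",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

# 511 keV linear attenuation coefficients, cm^-1
LAC_AIR = 0.0
LAC_FAT = 0.0854
LAC_LUNG = 0.0224
LAC_SOFT = 0.1
LAC_BONE_MIN = 0.1     # marrow
LAC_BONE_MAX = 0.2485  # cortical rim

CLASS_LAC: dict[int, float] = {
    AIR: LAC_AIR,
    FAT: LAC_FAT,
    LUNG: LAC_LUNG,
    SOFT_TISSUE: LAC_SOFT,
}

# CT Hounsfield units for the four soft classes and the bone interval ends
HU_AIR = -1000.0
HU_FAT = -110.0
HU_LUNG = -767.0
HU_SOFT = 70.0
HU_BONE_MIN = 70.0
HU_BONE_MAX = 2661.0

CLASS_HU: dict[int, float] = {
    AIR: HU_AIR,
    FAT: HU_FAT,
    LUNG: HU_LUNG,
    SOFT_TISSUE: HU_SOFT,
}

HU_CLAMP = (-1024.0, 3071.0)

# PTV density override: lung air replaced by water-equivalent tumor density
HU_PTV_OVERRIDE = -4.0


@dataclass
class TissueLabelMap:
    """Per-voxel tissue label on a :class:`VolumeGrid`."""

    labels: VolumeGrid

    def __post_init__(self) -> None:
        vals = np.unique(self.labels.values)
        known = np.array(sorted(LABEL_NAMES))
        if not np.all(np.isin(vals, known)):
            bad = sorted(set(vals.tolist()) - set(known.tolist()))
            raise ValueError(f"unknown tissue label codes: {bad}")

    @property
    def values(self) -> np.ndarray:
        return self.labels.values

    @property
    def grid(self) -> VolumeGrid:
        return self.labels

    def counts(self) -> dict[str, int]:
        """Per-class voxel counts (for logging / reports)."""
        out = {}
        for code, name in LABEL_NAMES.items():
            out[name] = int(np.count_nonzero(self.labels.values == code))
        return out

    def collapse_bone_to_soft(self) -> "TissueLabelMap":
        """Project to the four Dixon-visible classes (bone reads as soft tissue).

        Cortical bone and marrow have soft-tissue-like Dixon signal, which is
        exactly why bone must be restored from an atlas rather than from the
        MR classification.
        """
        vals = self.labels.values.copy()
        vals[vals == BONE] = SOFT_TISSUE
        return TissueLabelMap(self.labels.with_values(vals))
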