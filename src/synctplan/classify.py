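"""Rule-based Dixon tissue classification and 511-keV attenuation maps.

Stage 1 of synthetic-CT generation: each Dixon voxel is classified as air,
fat, lung or soft tissue and assigned the corresponding 511-keV linear
attenuation coefficient (LAC).  The classifier is deliberately simple and
deterministic: body masking by combined-signal threshold, fat/soft split by
fat fraction F/(W+F), and lung detection as large low-signal components
enclosed by the body.

All intensity thresholds are *relative* (fractions of a robust signal
maximum), so the classification is invariant to a global positive rescaling
of both Dixon channels; this is the documented absolute/relative split —
no absolute thresholds are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import tissues as T
from .dixon import DixonPair
from .grid import VolumeGrid

log = logging.getLogger(__name__)


@dataclass
class ClassificationConfig:
    """Thresholds of the rule-based classifier.

    body_signal_frac / lung_signal_frac are fractions of the 99th percentile
    of the combined water+fat signal; fat_fraction_threshold splits fat from
    soft tissue (ties -> fat); min_lung_volume_cm3 separates lungs from
    small pockets of internal air.
    """

    body_signal_frac: float = 0.3
    lung_signal_frac: float = 0.3
    fat_fraction_threshold: float = 0.5
    min_lung_volume_cm3: float = 50.0


@dataclass
class AttenuationMap:
    """Per-voxel 511-keV linear attenuation coefficient (cm^-1)."""

    mu: VolumeGrid

    def __post_init__(self) -> None:
        vals = self.mu.values
        if (vals < 0).any() or (vals > T.LAC_BONE_MAX + 1e-12).any():
            raise ValueError(
                f"attenuation coefficients must lie in [0, {T.LAC_BONE_MAX}] cm^-1"
            )

    @property
    def values(self) -> np.ndarray:
        return self.mu.values

    @property
    def grid(self) -> VolumeGrid:
        return self.mu


def _robust_max(total: np.ndarray) -> float:
    return float(np.percentile(total, 99.0))


def compute_body_mask(dixon: DixonPair, config: ClassificationConfig | None = None) -> VolumeGrid:
    """Body outline: largest above-threshold connected component, holes filled.

    The filled holes are exactly the enclosed low-signal regions (lungs,
    internal air), so the body mask covers every fat and soft-tissue voxel.
    """
    config = config or ClassificationConfig()
    total = dixon.total
    peak = _robust_max(total)
    fg = total >= config.body_signal_frac * peak
    if peak <= 0 or not fg.any():
        raise ValueError("no body detected: combined Dixon signal is empty")
    lab, n = ndimage.label(fg)
    largest = np.argmax(ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))) + 1
    body = ndimage.binary_fill_holes(lab == largest)
    return dixon.grid.with_values(body.astype(np.uint8))


def classify_voxels(
    dixon: DixonPair,
    body: VolumeGrid | None = None,
    config: ClassificationConfig | None = None,
) -> T.TissueLabelMap:
    """Classify Dixon voxels into air / fat / lung / soft tissue.

    Outside the body everything is air.  Inside, low-combined-signal
    components large enough to be lungs are labelled lung (smaller pockets
    stay air); remaining voxels split by fat fraction, ties going to fat.
    """
    config = config or ClassificationConfig()
    if body is None:
        body = compute_body_mask(dixon, config)
    dixon.grid.require_same_grid(body, "Dixon volume and body mask")
    body_arr = body.values.astype(bool)

    total = dixon.total
    peak = _robust_max(total)
    low = total < config.lung_signal_frac * peak

    labels = np.full(dixon.grid.shape, T.AIR, dtype=np.int16)
    inside_low = body_arr & low
    lab, n = ndimage.label(inside_low)
    voxvol_cm3 = dixon.grid.voxel_volume_mm3 / 1000.0
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        lung_ids = np.flatnonzero(sizes * voxvol_cm3 >= config.min_lung_volume_cm3) + 1
        lung_mask = np.isin(lab, lung_ids)
    else:
        lung_mask = np.zeros_like(inside_low)

    tissue = body_arr & ~inside_low
    ff = dixon.fat_fraction()
    labels[tissue & (ff >= config.fat_fraction_threshold)] = T.FAT
    labels[tissue & (ff < config.fat_fraction_threshold)] = T.SOFT_TISSUE
    labels[lung_mask] = T.LUNG
    out = T.TissueLabelMap(dixon.grid.with_values(labels))
    log.info("classified voxels: %s", out.counts())
    return out


def assign_lac(labels: T.TissueLabelMap) -> AttenuationMap:
    """Pure lookup of class LACs: air 0.0, fat 0.0854, lung 0.0224, soft 0.1 cm^-1.

    Bone is inserted later from the atlas; a bone label here is an error.
    """
    vals = labels.values
    if (vals == T.BONE).any():
        raise ValueError(
            "bone labels are not allowed before atlas insertion; "
            "assign_lac handles the four Dixon classes only"
        )
    mu = np.zeros(vals.shape)
    for code, lac in T.CLASS_LAC.items():
        mu[vals == code] = lac
    return AttenuationMap(labels.grid.with_values(mu))
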