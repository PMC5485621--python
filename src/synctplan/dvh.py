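"""Cumulative dose-volume histograms and the standard lung-plan metric set.

Conventions, applied consistently everywhere:

* ``Dx`` — the largest dose d such that at least x% of the structure
  receives >= d.  On raw voxel doses this is exact order-statistic
  counting: the ceil(n*x/100)-th largest voxel dose (so 100 voxels dosed
  1..100 Gy give D95 = 6 Gy, D100 = 1 Gy).  PTV Dx values are reported as
  % of prescription when one is attached.
* ``Vx`` — 100 * (number of voxels with dose strictly greater than x Gy) /
  (number of voxels): "receiving dose larger than x Gy" read literally
  (1..100 Gy gives V20 = 80%, not 81%).
* Lung is evaluated as (left + right lung) minus PTV; heart by V40; spinal
  cord by maximum voxel dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import StructureSet, VolumeGrid

DEFAULT_BIN_WIDTH_GY = 0.01


def _masked_doses(dose, mask=None) -> np.ndarray:
    if isinstance(dose, VolumeGrid):
        if mask is None:
            raise ValueError("a mask is required with a dose volume")
        m = mask.values.astype(bool) if isinstance(mask, VolumeGrid) else np.asarray(mask, bool)
        vals = dose.values[m]
    else:
        vals = np.asarray(dose, dtype=float).ravel()
        if mask is not None:
            m = mask.values.astype(bool) if isinstance(mask, VolumeGrid) else np.asarray(mask, bool)
            vals = vals[m.ravel()]
    if vals.size == 0:
        raise ValueError("structure mask is empty: no doses to evaluate")
    return vals


@dataclass
class DVHCurve:
    """Cumulative DVH: % of structure receiving at least each edge dose."""

    dose_edges_gy: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self) -> None:
        v = self.volume_pct
        if np.any(np.diff(v) > 1e-9):
            raise ValueError("cumulative volume must be non-increasing in dose")
        if abs(v[0] - 100.0) > 1e-9 or abs(v[-1]) > 1e-9:
            raise ValueError("cumulative DVH must start at 100% and end at 0%")

    def dose_at_volume(self, x: float) -> float:
        """Largest dose with >= x% volume, linear between bins; plateaus
        resolve to the larger dose."""
        if not 0 < x <= 100:
            raise ValueError("x must be in (0, 100]")
        v, e = self.volume_pct, self.dose_edges_gy
        i = int(np.flatnonzero(v >= x)[-1])
        if i == len(v) - 1 or v[i] == x:
            return float(e[i])
        # interpolate toward the first bin below x
        return float(e[i] + (e[i + 1] - e[i]) * (v[i] - x) / (v[i] - v[i + 1]))

    def volume_at_dose(self, x: float) -> float:
        return float(np.interp(x, self.dose_edges_gy, self.volume_pct))


def cumulative_dvh(dose, mask=None, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> DVHCurve:
    """Cumulative DVH by exact voxel counting at fixed-width dose bins."""
    vals = _masked_doses(dose, mask)
    top = float(vals.max()) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    # % of voxels with dose >= edge
    counts = np.searchsorted(np.sort(vals), edges, side="left")
    vol = 100.0 * (vals.size - counts) / vals.size
    vol[0] = 100.0
    return DVHCurve(edges, vol)


def dose_at_volume(dose, x: float, mask=None) -> float:
    """Exact Dx in Gy: the ceil(n*x/100)-th largest voxel dose."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    vals = np.sort(_masked_doses(dose, mask))[::-1]
    k = int(np.ceil(vals.size * x / 100.0))
    return float(vals[k - 1])


def volume_at_dose(dose, x_gy: float, mask=None) -> float:
    """Vx in %: share of voxels with dose strictly greater than x Gy."""
    vals = _masked_doses(dose, mask)
    return float(100.0 * np.count_nonzero(vals > x_gy) / vals.size)


def max_dose(dose, mask=None) -> float:
    return float(_masked_doses(dose, mask).max())


@dataclass
class DVHMetricSet:
    """The evaluated metric set: PTV coverage, lung/heart volumes, cord max.

    PTV Dx in % of prescription; Vx in % volume; Dmax in Gy.
    Invariant: D100 <= D98 <= D95.
    """

    d95_pct: float
    d98_pct: float
    d100_pct: float
    lung_v10_pct: float
    lung_v20_pct: float
    heart_v40_pct: float
    cord_dmax_gy: float

    def __post_init__(self) -> None:
        if not (self.d100_pct <= self.d98_pct + 1e-9 <= self.d95_pct + 2e-9):
            raise ValueError("expected D100 <= D98 <= D95")

    def as_dict(self) -> dict[str, float]:
        return {
            "PTV_D95": self.d95_pct, "PTV_D98": self.d98_pct, "PTV_D100": self.d100_pct,
            "Lung_V10": self.lung_v10_pct, "Lung_V20": self.lung_v20_pct,
            "Heart_V40": self.heart_v40_pct, "Cord_Dmax": self.cord_dmax_gy,
        }


def compute_metric_set(dose: VolumeGrid, structures: StructureSet,
                       prescription_gy: float) -> DVHMetricSet:
    """Evaluate the full metric set for one dose distribution."""
    ptv = structures.array("PTV")
    lung = structures.lung_minus_ptv()
    if not lung.any():
        raise ValueError("lung mask is empty after PTV exclusion")
    dvals = dose.values

    def dx(x):
        return 100.0 * dose_at_volume(dvals[ptv], x) / prescription_gy

    return DVHMetricSet(
        d95_pct=dx(95.0),
        d98_pct=dx(98.0),
        d100_pct=dx(100.0),
        lung_v10_pct=volume_at_dose(dvals[lung], 10.0),
        lung_v20_pct=volume_at_dose(dvals[lung], 20.0),
        heart_v40_pct=volume_at_dose(dvals[structures.array("heart")], 40.0),
        cord_dmax_gy=max_dose(dvals[structures.array("spinal_cord")]),
    )
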