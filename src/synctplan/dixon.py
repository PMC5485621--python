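"""Dixon water/fat signal pair container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VolumeGrid


@dataclass
class DixonPair:
    """Water- and fat-signal volumes from a two-point Dixon acquisition.

    Signals are non-negative and share one grid; intensity units are
    arbitrary but consistent between the two channels.
    """

    water: VolumeGrid
    fat: VolumeGrid
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.water.require_same_grid(self.fat, "Dixon water/fat volumes")
        if (self.water.values < 0).any() or (self.fat.values < 0).any():
            raise ValueError("Dixon signals must be >= 0")

    @property
    def grid(self) -> VolumeGrid:
        return self.water

    @property
    def total(self) -> np.ndarray:
        return self.water.values + self.fat.values

    def fat_fraction(self) -> np.ndarray:
        """F/(W+F); signal-void voxels (W+F == 0) return 0."""
        tot = self.total
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, self.fat.values / np.where(tot > 0, tot, 1.0), 0.0)
        return f
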