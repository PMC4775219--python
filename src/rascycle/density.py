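"""Fluorescence intensity -> concentration -> Ras surface density.

A solution calibration ties fluorescence intensity to a three-dimensional
concentration (4.287 uM per AU).  The apparent 3-D concentration at the
bead surface is converted to a 2-D density by assuming the molecules are
confined within a length h = 0.055 um of the surface, and 1 uM = 602
molecules/um^3, so 1 uM corresponds to 602 x 0.055 ~ 33.1 molecules/um^2.
Beads are then assigned to the nearest of six canonical density bins
(150 ... 10000 molecules/um^2, roughly 2x spaced), with nearness measured
in log space.  The paper stresses this is a crude estimate; relative
densities between beads are what matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DensityCalibration",
    "DEFAULT_BINS",
    "intensity_to_concentration",
    "concentration_to_density",
    "density_to_concentration",
    "assign_density_bin",
]

DEFAULT_BINS: tuple[float, ...] = (150.0, 300.0, 600.0, 1200.0, 2500.0, 10000.0)

_TIE_TOL = 1e-9  # relative tolerance for log-distance ties


@dataclass(frozen=True)
class DensityCalibration:
    c_cal: float = 4.287        # uM per AU, solution calibration
    h: float = 0.055            # um, confinement length
    n_conv: float = 602.0       # molecules/um^3 per uM
    bins: tuple[float, ...] = DEFAULT_BINS

    def __post_init__(self) -> None:
        if self.c_cal <= 0 or self.h <= 0 or self.n_conv <= 0:
            raise ValueError("calibration constants must be positive")
        if len(self.bins) == 0 or any(
            b2 <= b1 for b1, b2 in zip(self.bins, self.bins[1:])
        ):
            raise ValueError("bins must be strictly increasing")

    @property
    def f_2d(self) -> float:
        """molecules/um^2 per uM (33.1 at defaults)."""
        return self.n_conv * self.h


def intensity_to_concentration(intensity_au: float, cal: DensityCalibration | None = None) -> float:
    """Apparent 3-D concentration (uM) from fluorescence intensity (AU)."""
    if cal is None:
        cal = DensityCalibration()
    if intensity_au < 0:
        raise ValueError(f"intensity must be >= 0, got {intensity_au}")
    return cal.c_cal * intensity_au


def concentration_to_density(conc_uM: float, cal: DensityCalibration | None = None) -> float:
    """2-D surface density (molecules/um^2) from 3-D concentration (uM)."""
    if cal is None:
        cal = DensityCalibration()
    if conc_uM < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_uM}")
    return conc_uM * cal.f_2d


def density_to_concentration(density: float, cal: DensityCalibration | None = None) -> float:
    """Inverse of :func:`concentration_to_density`."""
    if cal is None:
        cal = DensityCalibration()
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    return density / cal.f_2d


def assign_density_bin(density: float, cal: DensityCalibration | None = None) -> float:
    """Nearest canonical bin in log2 distance; ties break to the lower bin.

    The bins are roughly geometrically spaced, so log-space nearness is the
    natural metric (a linear metric would make the top bin's lower shoulder
    unreachable).
    """
    if cal is None:
        cal = DensityCalibration()
    if density <= 0:
        raise ValueError(f"density must be > 0, got {density}")
    logd = math.log2(density)
    best_i, best_d = 0, float("inf")
    for i, b in enumerate(cal.bins):
        d = abs(logd - math.log2(b))
        if d < best_d - _TIE_TOL:
            best_i, best_d = i, d
        # within tolerance of the incumbent: keep the lower bin (smaller i)
    return cal.bins[best_i]
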