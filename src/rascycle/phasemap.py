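"""Factorial GEF x GAP x Ras-density scans and interpolated phase diagrams.

The study characterises the output space of the GTPase network by running
the same step input against a factorial grid of network configurations:
four GEF input strengths, four GAP levels and six Ras surface densities
(96 configurations; 4 x 4 = 16 for the mutant-distortion comparison).
Output features (integrated signal, initial rate, transient score) are
interpolated over the (GEF, GAP) plane at fixed density to give phase
diagrams, whose contours ("isoclines") are neutral paths of constant
output along which configurations can move without changing that feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import kinetics
from .density import DEFAULT_BINS
from .features import Timecourse, extract_features
from .kinetics import (
    CANONICAL_INITIAL_STATE,
    MutantSpec,
    RateConstants,
    ReactionNetwork,
    build_three_state_model,
    simulate,
)

__all__ = [
    "ConfigGrid",
    "PhaseDiagram",
    "RAS_NM_PER_DENSITY",
    "density_to_ras_nM",
    "run_config_grid",
    "interpolate_phase",
    "extract_isocline",
]

#: Ras concentration (nM) per unit surface density (molecules/um^2):
#: the canonical 2500 molecules/um^2 bead maps to the model's canonical
#: 10 nM Ras.
RAS_NM_PER_DENSITY = 10.0 / 2500.0

DEFAULT_GEF_LEVELS = (20.0, 200.0, 1000.0, 2000.0)     # nM, spans 20 nM - 2 uM
DEFAULT_GAP_LEVELS = (0.0, 100.0, 1000.0, 10000.0)     # nM, includes GAP-free
FEATURE_NAMES = (
    "integrated_signal",
    "initial_rate",
    "peak_value",
    "peak_time",
    "final_value",
    "pulse_width_s",
    "transient_score",
)


def density_to_ras_nM(density: float) -> float:
    """Map bead surface density to the model's total Ras concentration."""
    return density * RAS_NM_PER_DENSITY


@dataclass(frozen=True)
class ConfigGrid:
    """Factorial scan specification (levels strictly increasing)."""

    gef_levels: tuple[float, ...] = DEFAULT_GEF_LEVELS
    gap_levels: tuple[float, ...] = DEFAULT_GAP_LEVELS
    density_levels: tuple[float, ...] = DEFAULT_BINS
    effector_conc: float = 50.0
    rates: RateConstants = field(default_factory=RateConstants)
    mutant: MutantSpec | None = None
    t_end: float = 42000.0
    sample_dt: float = 900.0

    def __post_init__(self) -> None:
        for name in ("gef_levels", "gap_levels", "density_levels"):
            levels = getattr(self, name)
            if len(levels) == 0 or any(
                b <= a for a, b in zip(levels, levels[1:])
            ):
                raise ValueError(f"{name} must be non-empty and strictly increasing")

    @property
    def n_configurations(self) -> int:
        return len(self.gef_levels) * len(self.gap_levels) * len(self.density_levels)


def run_config_grid(
    grid: ConfigGrid,
    builder: Callable[[RateConstants], ReactionNetwork] = build_three_state_model,
) -> pd.DataFrame:
    """Simulate every configuration and extract output features.

    Returns one row per (gef_nM, gap_nM, density) with a column per
    feature; deterministic, and the row set is independent of level order.
    """
    rows = []
    for gef in grid.gef_levels:
        rates = grid.rates.with_gef(gef)
        net = builder(rates)
        if grid.mutant is not None:
            net = kinetics.apply_mutant(net, grid.mutant)
        for gap in grid.gap_levels:
            for dens in grid.density_levels:
                ic = dict(CANONICAL_INITIAL_STATE)
                ic["GD"] = density_to_ras_nM(dens)
                ic["EFF"] = grid.effector_conc
                if "GAP" in net.species:
                    ic["GAP"] = gap
                elif gap != 0:
                    raise ValueError(
                        f"builder {builder.__name__} has no GAP species but gap={gap}"
                    )
                try:
                    res = simulate(net, ic, t_end=grid.t_end, sample_dt=grid.sample_dt)
                except kinetics.SimulationError as exc:
                    raise kinetics.SimulationError(
                        f"configuration (gef={gef}, gap={gap}, density={dens}) failed: {exc}"
                    ) from exc
                tc = Timecourse(res.times, res.observables["bound_effector_total"])
                fs = extract_features(tc)
                row = {"gef_nM": gef, "gap_nM": gap, "density": dens}
                row.update(fs.as_dict())
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PhaseDiagram:
    """A feature interpolated over log-scaled (GEF, GAP) coordinates."""

    gef_levels: np.ndarray            # nM, ascending
    gap_levels: np.ndarray            # nM, ascending (may include 0)
    grid_values: np.ndarray           # (n_gef, n_gap)
    feature_name: str
    density_level: float
    gap_eps: float                    # offset making log10(gap + eps) finite

    def __post_init__(self) -> None:
        self._log_gef = np.log10(self.gef_levels)
        self._log_gap = np.log10(self.gap_levels + self.gap_eps)
        self._interp = RegularGridInterpolator(
            (self._log_gef, self._log_gap), self.grid_values, method="linear",
            bounds_error=True,
        )

    def __call__(self, gef_nM, gap_nM):
        """Evaluate the bilinear surface at (gef, gap), in nM."""
        pts = np.column_stack(
            [np.log10(np.atleast_1d(np.asarray(gef_nM, dtype=float))),
             np.log10(np.atleast_1d(np.asarray(gap_nM, dtype=float)) + self.gap_eps)]
        )
        out = self._interp(pts)
        return float(out[0]) if np.isscalar(gef_nM) and np.isscalar(gap_nM) else out

    def to_frame(self) -> pd.DataFrame:
        gg, pp = np.meshgrid(self.gef_levels, self.gap_levels, indexing="ij")
        return pd.DataFrame(
            {
                "gef_nM": gg.ravel(),
                "gap_nM": pp.ravel(),
                "feature": self.feature_name,
                "value": self.grid_values.ravel(),
                "density": self.density_level,
            }
        )

    def plot(self, ax=None, **imshow_kw):
        """Heatmap of the gridded feature (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            self.grid_values.T, origin="lower", aspect="auto",
            extent=(self._log_gef[0], self._log_gef[-1],
                    self._log_gap[0], self._log_gap[-1]),
            **imshow_kw,
        )
        ax.set_xlabel("log10 GEF (nM)")
        ax.set_ylabel(f"log10 (GAP + {self.gap_eps:g}) (nM)")
        ax.set_title(f"{self.feature_name} @ {self.density_level:g} molecules/um^2")
        return im


def interpolate_phase(
    rows: pd.DataFrame, feature_name: str, density_level: float
) -> PhaseDiagram:
    """Build the bilinear (log GEF x log GAP) surface for one feature.

    ``rows`` must cover a complete rectangular (gef, gap) grid at the
    requested density; missing nodes are reported explicitly.
    """
    if feature_name not in rows.columns:
        raise KeyError(f"unknown feature {feature_name!r}")
    sub = rows[np.isclose(rows["density"], density_level)]
    if sub.empty:
        raise ValueError(f"no rows at density {density_level}")
    gefs = np.array(sorted(sub["gef_nM"].unique()))
    gaps = np.array(sorted(sub["gap_nM"].unique()))
    grid = np.full((len(gefs), len(gaps)), np.nan)
    for _, r in sub.iterrows():
        i = int(np.argmin(np.abs(gefs - r["gef_nM"])))
        j = int(np.argmin(np.abs(gaps - r["gap_nM"])))
        grid[i, j] = r[feature_name]
    if np.isnan(grid).any():
        ii, jj = np.nonzero(np.isnan(grid))
        missing = [(float(gefs[i]), float(gaps[j])) for i, j in zip(ii, jj)]
        raise ValueError(f"incomplete (gef, gap) grid; missing nodes: {missing}")
    nonzero = gaps[gaps > 0]
    eps = 0.1 * nonzero.min() if len(nonzero) else 1.0
    return PhaseDiagram(
        gef_levels=gefs, gap_levels=gaps, grid_values=grid,
        feature_name=feature_name, density_level=density_level, gap_eps=eps,
    )


def extract_isocline(pdg: PhaseDiagram, level: float) -> list[np.ndarray]:
    """Marching-squares contours of the phase surface at ``level``.

    Returns paths as (n, 2) arrays of (gef_nM, gap_nM); every path point
    evaluates to ``level`` under the bilinear interpolant (to within
    floating-point error).  A level outside the surface's range yields an
    empty list; a constant surface at exactly ``level`` has no isolated
    contour and also yields an empty list.
    """
    from skimage import measure

    vmin, vmax = pdg.grid_values.min(), pdg.grid_values.max()
    if level < vmin or level > vmax:
        return []
    if vmin == vmax:
        return []  # degenerate: the whole surface sits at the level
    paths = []
    for contour in measure.find_contours(pdg.grid_values, level):
        # contour points are in fractional grid-index coordinates; map each
        # axis piecewise-linearly onto the log coordinates, then back to nM
        log_gef = np.interp(contour[:, 0], np.arange(len(pdg.gef_levels)), pdg._log_gef)
        log_gap = np.interp(contour[:, 1], np.arange(len(pdg.gap_levels)), pdg._log_gap)
        gef = 10.0 ** log_gef
        gap = 10.0 ** log_gap - pdg.gap_eps
        paths.append(np.column_stack([gef, np.clip(gap, 0.0, None)]))
    return paths
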