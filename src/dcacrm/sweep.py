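"""Attenuation-space maps of firing behaviour.

Each cell of a grid over the (VA_DS^DC, VA_SD^DC, VA_SD^AC) cube is solved
for its passive parameters (holding r_N, tau_m and p fixed), simulated under
the triangular ramp, and labeled with its firing type.  Cells whose property
set is infeasible (e.g. AC attenuation above DC) are labeled without
simulation.  The bistable solution volume is the set of cells with all
three characteristic indexes positive; horizontal cross-sections quantify
how that volume changes with the AC attenuation level.  Exponential decay
constants measured on a morphology trace a physiological trajectory through
the cube, whose intersection with the volume gives the range of dendritic
path distances at which bistable firing is predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import firing
from .bifurcation import dendritic_fold_currents
from .dynamics import ActiveParameters, simulate, triangular_protocol
from .reduction import SystemProperties, feasibility

__all__ = [
    "SweepGrid",
    "SweepCell",
    "SweepResult",
    "AttenuationTrajectory",
    "sweep",
    "bistable_cells",
    "bistable_volume",
    "cross_section_area",
    "partition_regions",
    "physiological_trajectory",
    "intersection",
]


@dataclass(frozen=True)
class SweepGrid:
    """Axis ranges and counts for the attenuation cube; all values in (0, 1).

    The default resolution (step 0.04 on the DC axes, ~0.08 on the AC axis,
    ~8k cells) keeps a full sweep under about an hour on one CPU; coarser
    smoke grids are used in tests.
    """

    va_ds_dc: tuple = (0.02, 0.98, 25)
    va_sd_dc: tuple = (0.02, 0.98, 25)
    va_sd_ac: tuple = (0.04, 0.96, 13)

    def axes(self):
        return tuple(np.linspace(lo, hi, int(n)) for lo, hi, n in
                     (self.va_ds_dc, self.va_sd_dc, self.va_sd_ac))


@dataclass
class SweepCell:
    va_ds_dc: float
    va_sd_dc: float
    va_sd_ac: float
    label: str  # firing type, "infeasible" or "error"
    infeasible_reason: str | None = None
    ttp: float | None = None
    tes: float | None = None
    dsf: float | None = None


@dataclass
class SweepResult:
    grid: SweepGrid
    base_props: SystemProperties
    cells: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "va_ds_dc": c.va_ds_dc, "va_sd_dc": c.va_sd_dc,
                    "va_sd_ac": c.va_sd_ac, "label": c.label,
                    "ttp": c.ttp, "tes": c.tes, "dsf": c.dsf,
                    "infeasible_reason": c.infeasible_reason,
                }
                for c in self.cells
            ]
        )


def sweep(grid: SweepGrid, base_props: SystemProperties, active: ActiveParameters,
          protocol=None, progress: bool = False, **sim_kwargs) -> SweepResult:
    """Evaluate firing type in every cell of the attenuation cube.

    Deterministic and embarrassingly parallel in principle; cells are
    evaluated serially here.  Per-cell failures are recorded as "error"
    labels and never abort the sweep.  The per-cell output grid defaults to
    a coarser spacing than single-run simulations (classification is
    grid-refinement stable).
    """
    protocol = protocol or triangular_protocol()
    sim_kwargs.setdefault("dt_out", 0.2)
    ax_ds, ax_sd, ax_ac = grid.axes()
    result = SweepResult(grid=grid, base_props=base_props)
    for va_ac in ax_ac:
        for va_sd in ax_sd:
            for va_ds in ax_ds:
                cell = SweepCell(va_ds_dc=float(va_ds), va_sd_dc=float(va_sd),
                                 va_sd_ac=float(va_ac), label="error")
                props = base_props.replace(
                    va_sd_dc=float(va_sd), va_ds_dc=float(va_ds), va_sd_ac=float(va_ac)
                )
                report = feasibility(props)
                if not report.feasible:
                    cell.label = "infeasible"
                    cell.infeasible_reason = report.violated_conditions[0]
                else:
                    try:
                        folds = dendritic_fold_currents(
                            report.parameters, props.p, active.replace(g_na=0.0, g_k_s=0.0)
                        )
                        # structurally, the plateau must be evocable within the
                        # ramp and able to survive below rheobase to count
                        possible = folds is not None and folds[0] <= protocol.peak
                        sustain = folds[1] if folds is not None else None
                        trace = simulate(report.parameters, props.p, active, protocol,
                                         **sim_kwargs)
                        metrics = firing.analyze(trace, protocol,
                                                 plateau_possible=possible,
                                                 plateau_sustain_current=sustain)
                        cell.label = metrics.label
                        cell.ttp, cell.tes, cell.dsf = metrics.ttp, metrics.tes, metrics.dsf
                    except Exception:
                        cell.label = "error"
                result.cells.append(cell)
                if progress:
                    print(f"({va_ds:.2f},{va_sd:.2f},{va_ac:.2f}) -> {cell.label}", flush=True)
    return result


# ---------------------------------------------------------------------------
# Volume / cross-sections / regions
# ---------------------------------------------------------------------------

def bistable_cells(result: SweepResult) -> list:
    return [c for c in result.cells if c.label == "IV_bistable"]


def bistable_volume(result: SweepResult) -> float:
    """Fraction of grid cells in the fully-bistable volume."""
    n = len(result.cells)
    return len(bistable_cells(result)) / n if n else 0.0


def cross_section_area(result: SweepResult, va_sd_ac: float, atol: float = 1e-9) -> float:
    """Normalized bistable cell count on one horizontal (AC-level) slice."""
    ax_ds, ax_sd, ax_ac = result.grid.axes()
    level = ax_ac[np.argmin(np.abs(ax_ac - va_sd_ac))]
    in_slice = [c for c in result.cells if abs(c.va_sd_ac - level) < max(atol, 1e-9)]
    if not in_slice:
        return 0.0
    n_bi = sum(1 for c in in_slice if c.label == "IV_bistable")
    return n_bi / len(in_slice)


def partition_regions(result: SweepResult) -> dict:
    """Cells grouped by label; infeasible cells reported separately."""
    out: dict = {}
    for c in result.cells:
        out.setdefault(c.label, []).append(c)
    return out


# ---------------------------------------------------------------------------
# Physiological trajectories
# ---------------------------------------------------------------------------

@dataclass
class AttenuationTrajectory:
    """Attenuation triple as a function of path distance from the soma.

    Built from a decay-constant triple (eta_SD^DC, eta_DS^DC, eta_SD^AC):
    each coordinate is exp(-D_path/eta), so the curve starts at (1, 1, 1)
    and decreases monotonically with distance.
    """

    eta_sd_dc: float
    eta_ds_dc: float
    eta_sd_ac: float
    d_path: np.ndarray
    points: np.ndarray  # (n, 3) columns: va_ds_dc, va_sd_dc, va_sd_ac

    def at(self, d_path):
        d = np.asarray(d_path, float)
        return np.stack(
            [np.exp(-d / self.eta_ds_dc), np.exp(-d / self.eta_sd_dc),
             np.exp(-d / self.eta_sd_ac)], axis=-1
        )


def physiological_trajectory(eta_sd_dc: float, eta_ds_dc: float, eta_sd_ac: float,
                             d_path_max: float = 1854.0, n: int = 200) -> AttenuationTrajectory:
    if min(eta_sd_dc, eta_ds_dc, eta_sd_ac) <= 0:
        raise ValueError("decay constants must be positive")
    d = np.linspace(0.0, d_path_max, n)
    traj = AttenuationTrajectory(eta_sd_dc, eta_ds_dc, eta_sd_ac, d, None)
    traj.points = traj.at(d)
    return traj


def intersection(result: SweepResult, trajectory: AttenuationTrajectory) -> tuple | None:
    """Contiguous D_path interval whose nearest cells are fully bistable.

    Returns (d_min, d_max) of the longest contiguous bistable run along the
    trajectory, or None if it never enters the volume.
    """
    ax_ds, ax_sd, ax_ac = result.grid.axes()
    label_of = {
        (round(c.va_ds_dc, 9), round(c.va_sd_dc, 9), round(c.va_sd_ac, 9)): c.label
        for c in result.cells
    }

    def snap(ax, v):
        return round(float(ax[np.argmin(np.abs(ax - v))]), 9)

    inside = []
    for d, (va_ds, va_sd, va_ac) in zip(trajectory.d_path, trajectory.points):
        key = (snap(ax_ds, va_ds), snap(ax_sd, va_sd), snap(ax_ac, va_ac))
        inside.append(label_of.get(key) == "IV_bistable")
    inside = np.asarray(inside)
    if not inside.any():
        return None
    # longest contiguous run
    best, cur_start, best_span = None, None, -1.0
    for k, flag in enumerate(inside):
        if flag and cur_start is None:
            cur_start = k
        if (not flag or k == len(inside) - 1) and cur_start is not None:
            end = k if flag else k - 1
            span = trajectory.d_path[end] - trajectory.d_path[cur_start]
            if span > best_span:
                best_span = span
                best = (float(trajectory.d_path[cur_start]), float(trajectory.d_path[end]))
            cur_start = None
    return best
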