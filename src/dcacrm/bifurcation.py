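"""Fixed points, stability, Hopf/fold detection and the plateau threshold.

Equilibria of the 5-D system have all gates at steady state, which reduces
the search to the (V_S, V_D) plane; they are found at each injected somatic
current by multi-start Newton iteration seeded on a coarse grid, then
deduplicated.  Stability comes from the eigenvalues of the full 5-D
Jacobian (finite differences).  Somatic spiking onset is a Hopf bifurcation
(complex pair crossing the imaginary axis on the resting branch); the
dendritic plateau arises at a saddle-node (fold) of the S-shaped V_D branch.

The plateau-threshold current is capacitance-independent when somatic
spiking is blocked (fixed points do not involve capacitances); with spiking
active the trajectory jumps to the plateau branch earlier or later depending
on how much spike (AC) signal reaches the dendrite, so the threshold is then
measured from a slow-ramp simulation as the current at dendritic plateau
onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .dynamics import (
    ActiveParameters,
    SimulationTrace,
    derivatives,
    simulate,
    steady_gates,
    triangular_protocol,
)
from .firing import detect_plateau_onset
from .reduction import PassiveParameters

__all__ = [
    "Equilibrium",
    "BifurcationDiagram",
    "dendritic_scurve",
    "dendritic_fold_currents",
    "dendritic_fold_exists",
    "fixed_points",
    "jacobian",
    "stability",
    "branch_diagram",
    "hopf_current",
    "fold_currents",
    "low_branch_end",
    "plateau_threshold",
    "limit_cycle_envelope",
]

V_RANGE = (-0.9, 1.1)


def dendritic_scurve(passive: PassiveParameters, p: float, active: ActiveParameters,
                     vd_range=(-0.7, 1.0), n: int = 2000):
    """Somatic current on the spikes-blocked fixed-point branch, vs V_D.

    With G_Na = G_K,S = 0 the somatic steady state is linear in V_S, so the
    equilibrium manifold can be parametrized by V_D in closed form:
    I_S(V_D) with dendritic gates at steady state.  A non-monotone curve
    (two turning points) is the S-shape whose folds are the plateau
    saddle-nodes.  Returns (v_d grid, i_s values).
    """
    a_c = passive.g_c / p
    b_c = passive.g_c / (1.0 - p)
    e_l = active.e_leak
    v_d = np.linspace(vd_range[0], vd_range[1], n)
    m = active.m_d_inf(v_d)
    nd = active.n_d_inf(v_d)
    i_act = active.g_ca * m * (v_d - active.e_ca) + active.g_k_d * nd * (v_d - active.e_k)
    num = (passive.g_m_d * (v_d - e_l) + i_act + b_c * v_d) * (passive.g_m_s + a_c) \
        - b_c * (passive.g_m_s * e_l + a_c * v_d)
    return v_d, num / b_c


def dendritic_fold_currents(passive: PassiveParameters, p: float, active: ActiveParameters,
                            vd_range=(-0.7, 1.0), n: int = 2000):
    """(onset, offset) saddle-node currents of the blocked S-shaped branch.

    The onset fold is where the hyperpolarized branch ends (plateau evoked,
    local maximum of I_S along the branch); the offset fold is where the
    plateau branch ends on the way down (plateau deactivated, local
    minimum).  Returns None when the branch is monotone (no plateau
    mechanism).  Active spike conductances are ignored -- pass a
    spikes-blocked parameter set.
    """
    _, i_s = dendritic_scurve(passive, p, active, vd_range, n)
    d = np.sign(np.diff(i_s))
    turns = np.flatnonzero(np.diff(d) != 0)
    if len(turns) < 2:
        return None
    return float(i_s[turns[0]]), float(i_s[turns[-1]])


def dendritic_fold_exists(passive: PassiveParameters, p: float, active: ActiveParameters,
                          vd_range=(-0.7, 1.0), n: int = 2000) -> bool:
    """Whether the blocked dendritic branch is S-shaped (has saddle-node folds).

    This is the structural prerequisite for a regenerative plateau: without
    folds the dendrite depolarizes smoothly with current and any F-I
    hysteresis is slow-gate lag, not bistability of attractors.
    """
    return dendritic_fold_currents(passive, p, active, vd_range, n) is not None


@dataclass
class Equilibrium:
    i_s: float
    state: np.ndarray  # (V_S, V_D, n_S, m_D, n_D)
    eigenvalues: np.ndarray | None = None

    @property
    def v_s(self) -> float:
        return float(self.state[0])

    @property
    def v_d(self) -> float:
        return float(self.state[1])

    @property
    def stable(self) -> bool:
        return bool(np.max(np.real(self.eigenvalues)) < 0)


@dataclass
class BifurcationDiagram:
    i_grid: np.ndarray
    equilibria: list  # list (per i_s) of lists of Equilibrium
    hopf_currents: list = field(default_factory=list)
    fold_currents: list = field(default_factory=list)
    envelopes: dict = field(default_factory=dict)  # i_s -> (vs_min, vs_max, vd_min, vd_max)


# ---------------------------------------------------------------------------
# Equilibria
# ---------------------------------------------------------------------------

def _reduced_residual(passive, p, active, i_s):
    def F(x):
        v_s, v_d = x
        st = (v_s, v_d) + steady_gates(active, v_s, v_d)
        d = derivatives(st, 0.0, passive, p, active, i_s, 0.0)
        return (d[0] * passive.c_m_s, d[1] * passive.c_m_d)

    return F


def fixed_points(passive: PassiveParameters, p: float, active: ActiveParameters,
                 i_s: float, n_starts: int = 16, tol: float = 1e-11) -> list:
    """All equilibria at one somatic current via multi-start Newton.

    Starting points tile the (V_S, V_D) square; converged solutions with
    residual below ``tol`` are deduplicated at 1e-6 resolution and returned
    with full-system eigenvalues attached.
    """
    F = _reduced_residual(passive, p, active, i_s)
    vs = np.linspace(V_RANGE[0], V_RANGE[1], n_starts)
    found = []
    for v_s0 in vs:
        for v_d0 in vs:
            sol = root(F, (v_s0, v_d0), method="hybr", tol=1e-13)
            if not sol.success:
                continue
            r = F(sol.x)
            if max(abs(r[0]), abs(r[1])) > tol:
                continue
            v_s, v_d = sol.x
            if not (V_RANGE[0] - 0.3 < v_s < V_RANGE[1] + 0.3):
                continue
            key = (round(v_s, 6), round(v_d, 6))
            if any(abs(v_s - e.v_s) < 1e-5 and abs(v_d - e.v_d) < 1e-5 for e in found):
                continue
            st = np.array((v_s, v_d) + steady_gates(active, v_s, v_d))
            eq = Equilibrium(i_s=i_s, state=st)
            eq.eigenvalues = np.linalg.eigvals(jacobian(st, passive, p, active, i_s))
            found.append(eq)
    found.sort(key=lambda e: e.v_d)
    return found


def jacobian(state, passive, p, active, i_s: float, eps: float = 1e-7) -> np.ndarray:
    """Finite-difference Jacobian of the full 5-D vector field."""
    state = np.asarray(state, float)
    n = len(state)
    J = np.empty((n, n))
    f0 = np.asarray(derivatives(state, 0.0, passive, p, active, i_s, 0.0))
    for j in range(n):
        dp = state.copy()
        h = eps * max(1.0, abs(state[j]))
        dp[j] += h
        J[:, j] = (np.asarray(derivatives(dp, 0.0, passive, p, active, i_s, 0.0)) - f0) / h
    return J


def stability(eq: Equilibrium) -> str:
    ev = eq.eigenvalues
    if np.max(np.real(ev)) < 0:
        return "stable"
    return "unstable"


# ---------------------------------------------------------------------------
# Branches, Hopf, folds
# ---------------------------------------------------------------------------

def branch_diagram(passive, p, active, i_grid, envelopes: bool = False,
                   **sim_kwargs) -> BifurcationDiagram:
    """Equilibria (and optionally limit-cycle envelopes) over a current grid."""
    i_grid = np.asarray(i_grid, float)
    eq_lists = [fixed_points(passive, p, active, i) for i in i_grid]
    diag = BifurcationDiagram(i_grid=i_grid, equilibria=eq_lists)
    diag.hopf_currents = _hopf_from_branches(i_grid, eq_lists)
    diag.fold_currents = _folds_from_counts(passive, p, active, i_grid, eq_lists)
    if envelopes:
        for i_s in i_grid:
            diag.envelopes[float(i_s)] = limit_cycle_envelope(
                passive, p, active, i_s, **sim_kwargs
            )
    return diag


def _lowest_branch(eq_list):
    return min(eq_list, key=lambda e: e.v_s) if eq_list else None


def _max_re_complex_pair(eq) -> float:
    ev = eq.eigenvalues
    cplx = ev[np.abs(np.imag(ev)) > 1e-9]
    pool = cplx if len(cplx) else ev
    return float(np.max(np.real(pool)))


def _hopf_from_branches(i_grid, eq_lists):
    """Sign changes of the leading complex-pair real part on the low branch."""
    hopfs = []
    prev = None
    for i_s, eqs in zip(i_grid, eq_lists):
        low = _lowest_branch(eqs)
        if low is None:
            prev = None
            continue
        cur = _max_re_complex_pair(low)
        if prev is not None and prev[1] < 0 <= cur:
            # linear interpolation of the crossing current
            i0, r0 = prev
            hopfs.append(i0 + (i_s - i0) * (-r0) / (cur - r0))
        prev = (i_s, cur)
    return hopfs


def hopf_current(passive, p, active, i_range=(0.0, 3.0), coarse: int = 61,
                 refine_tol: float = 1e-4) -> float:
    """Rheobase: Hopf current of the resting branch, refined by bisection."""

    def lead_re(i_s):
        eqs = fixed_points(passive, p, active, i_s, n_starts=8)
        low = _lowest_branch(eqs)
        if low is None:
            raise RuntimeError(f"no equilibrium at I_S = {i_s}")
        return _max_re_complex_pair(low)

    grid = np.linspace(i_range[0], i_range[1], coarse)
    prev_i, prev_r = grid[0], lead_re(grid[0])
    for i_s in grid[1:]:
        r = lead_re(i_s)
        if prev_r < 0 <= r:
            return float(brentq(lead_re, prev_i, i_s, xtol=refine_tol))
        prev_i, prev_r = i_s, r
    raise RuntimeError("no Hopf bifurcation found in the current range")


def _folds_from_counts(passive, p, active, i_grid, eq_lists, n_starts: int = 14):
    """Fold currents located where the equilibrium count changes, bisected."""
    folds = []
    counts = [len(e) for e in eq_lists]

    def count_at(i_s):
        return len(fixed_points(passive, p, active, i_s, n_starts=n_starts))

    for k in range(1, len(i_grid)):
        if counts[k] != counts[k - 1]:
            lo, hi = float(i_grid[k - 1]), float(i_grid[k])
            c_lo = counts[k - 1]
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if count_at(mid) == c_lo:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-5:
                    break
            folds.append(0.5 * (lo + hi))
    return folds


def fold_currents(passive, p, active, i_range=(0.0, 3.0), n: int = 61,
                  n_starts: int = 14) -> list:
    i_grid = np.linspace(i_range[0], i_range[1], n)
    eq_lists = [fixed_points(passive, p, active, i, n_starts=n_starts) for i in i_grid]
    return _folds_from_counts(passive, p, active, i_grid, eq_lists, n_starts=n_starts)


def low_branch_end(passive, p, active, i_range=(0.0, 3.0), n: int = 31,
                   jump: float = 0.1, n_starts: int = 14) -> float:
    """Current at which the hyperpolarized (low-V_D) branch disappears.

    The lowest equilibrium is tracked along an increasing current grid; the
    saddle-node where it merges with the middle branch shows up as an upward
    jump of the minimum V_D, which is then refined by bisection on the
    existence of an equilibrium below the pre-jump level.
    """
    i_grid = np.linspace(i_range[0], i_range[1], n)
    prev_i, prev_vd = None, None
    for i_s in i_grid:
        eqs = fixed_points(passive, p, active, i_s, n_starts=n_starts)
        if not eqs:
            continue
        vd_low = min(e.v_d for e in eqs)
        if prev_vd is not None and vd_low - prev_vd > jump:
            v_ref = prev_vd + 0.5 * jump

            def has_low(i_mid):
                eqs_m = fixed_points(passive, p, active, i_mid, n_starts=n_starts)
                return any(e.v_d < v_ref for e in eqs_m)

            lo, hi = prev_i, float(i_s)
            for _ in range(25):
                mid = 0.5 * (lo + hi)
                if has_low(mid):
                    lo = mid
                else:
                    hi = mid
                if hi - lo < 1e-5:
                    break
            return 0.5 * (lo + hi)
        prev_i, prev_vd = float(i_s), vd_low
    raise RuntimeError("no plateau mechanism: low branch persists over the current range")


# ---------------------------------------------------------------------------
# Plateau threshold
# ---------------------------------------------------------------------------

def plateau_threshold(passive: PassiveParameters, p: float, active: ActiveParameters,
                      i_range=(0.0, 3.0), n: int = 61, ramp_peak: float = 2.5,
                      ramp_t_peak: float = 1350.0, **sim_kwargs) -> float:
    """Somatic current at which the dendritic plateau is evoked.

    With somatic spike currents blocked (G_Na = G_K,S = 0) this is the lower
    saddle-node fold of the fixed-point structure and is independent of the
    capacitances.  With spiking active, back-propagated spikes tip the
    dendrite over the fold early, so the threshold is measured from a slow
    ascending triangular ramp as the current at plateau onset.
    """
    if active.g_na == 0.0 and active.g_k_s == 0.0:
        return float(low_branch_end(passive, p, active, i_range=i_range, n=n))
    protocol = triangular_protocol(peak=ramp_peak, t_peak=ramp_t_peak)
    trace = simulate(passive, p, active, protocol, **sim_kwargs)
    onset = detect_plateau_onset(trace)
    if onset is None or onset > protocol.t_peak:
        raise RuntimeError("no plateau mechanism: no plateau evoked on the ascending ramp")
    return float(protocol.current(onset))


# ---------------------------------------------------------------------------
# Limit cycles
# ---------------------------------------------------------------------------

def limit_cycle_envelope(passive, p, active, i_s: float, t_end: float = 600.0,
                         transient_fraction: float = 0.3, **sim_kwargs):
    """(vs_min, vs_max, vd_min, vd_max) after discarding the transient.

    The system is started slightly depolarized from the lowest equilibrium
    and held at constant current; the attractor's post-transient extrema
    outline the oscillation (equal min/max indicates a stable equilibrium).
    """
    eqs = fixed_points(passive, p, active, i_s, n_starts=8)
    low = _lowest_branch(eqs)
    if low is None:
        raise RuntimeError(f"no equilibrium at I_S = {i_s}")
    y0 = low.state.copy()
    y0[0] += 0.05
    from .dynamics import StimulusProtocol

    protocol = StimulusProtocol(kind="step", t_end=t_end, baseline=i_s, pulses=())
    trace = simulate(passive, p, active, protocol, y0=y0, **sim_kwargs)
    keep = trace.t >= transient_fraction * t_end
    return (
        float(trace.v_s[keep].min()),
        float(trace.v_s[keep].max()),
        float(trace.v_d[keep].min()),
        float(trace.v_d[keep].max()),
    )
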