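"""Active dynamics of the two-compartment reduced model.

The somatic compartment carries Morris-Lecar-type spike currents (an
instantaneously activating inward "Na" current and a delayed-rectifier K
current with first-order gate n_S, producing repetitive firing through a
Hopf bifurcation).  The dendritic compartment carries an L-type-Ca-like
persistent inward current and a delayed-rectifier K current; the Ca gate
m_D is NOT instantaneous but relaxes with a voltage-dependent time constant
tau_mD(V_D) that is slow below half-activation -- the delayed activation
that turns the dendritic saddle-node into a delayed plateau onset.

State vector: [V_S, V_D, n_S, m_D, n_D].  All quantities are in the model's
dimensionless units; rest sits near V_S = -0.5.

The default :class:`ActiveParameters` set was calibrated in-repo (see
``scripts/calibrate_active.py``) to satisfy the qualitative structure above
together with bistable (Type IV) firing of the default passive model under
the standard triangular ramp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .reduction import PassiveParameters

__all__ = [
    "ActiveParameters",
    "DEFAULT_ACTIVE",
    "StimulusProtocol",
    "triangular_protocol",
    "pulse_protocol",
    "step_protocol",
    "switching_protocol",
    "SimulationTrace",
    "derivatives",
    "resting_state",
    "simulate",
]


@dataclass(frozen=True)
class ActiveParameters:
    """Maximum conductances, reversal potentials and gating parameters."""

    # maximum conductances
    g_na: float = 35.0
    g_k_s: float = 45.0
    g_ca: float = 0.30
    g_k_d: float = 0.25
    # reversal potentials (dimensionless voltage)
    e_na: float = 1.0
    e_ca: float = 1.0
    e_k: float = -0.7
    e_leak: float = -0.5
    # somatic gating: instantaneous m_S, first-order n_S
    m_s_half: float = -0.01
    m_s_slope: float = 0.15
    n_s_half: float = 0.0
    n_s_slope: float = 0.15
    n_s_rate: float = 0.5
    # dendritic gating: slow m_D with voltage-dependent time constant, n_D
    m_d_half: float = -0.05
    m_d_slope: float = 0.09
    tau_m_d_max: float = 300.0
    tau_m_d_min: float = 40.0
    tau_m_d_width: float = 0.15
    n_d_half: float = 0.0
    n_d_slope: float = 0.08
    n_d_rate: float = 0.10

    def __post_init__(self):
        for name in ("g_na", "g_k_s", "g_ca", "g_k_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("m_s_slope", "n_s_slope", "m_d_slope", "n_d_slope", "tau_m_d_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_m_d_min <= 0 or self.tau_m_d_max < self.tau_m_d_min:
            raise ValueError("tau_mD bounds must satisfy 0 < min <= max")

    def replace(self, **kw) -> "ActiveParameters":
        return replace(self, **kw)

    # -- gating curves -----------------------------------------------------

    def m_s_inf(self, v):
        return 0.5 * (1.0 + np.tanh((v - self.m_s_half) / self.m_s_slope))

    def n_s_inf(self, v):
        return 0.5 * (1.0 + np.tanh((v - self.n_s_half) / self.n_s_slope))

    def n_s_tau(self, v):
        return 1.0 / (self.n_s_rate * np.cosh((v - self.n_s_half) / (2.0 * self.n_s_slope)))

    def m_d_inf(self, v):
        return 0.5 * (1.0 + np.tanh((v - self.m_d_half) / self.m_d_slope))

    def tau_m_d(self, v):
        """Voltage-dependent activation time constant of the Ca PIC gate.

        Bell-shaped: slowest near half-activation (delayed plateau onset and
        offset), fast far from it (prompt deactivation at hyperpolarized
        potentials, prompt saturation on strong depolarization).
        """
        z = (np.asarray(v, float) - self.m_d_half) / self.tau_m_d_width
        return self.tau_m_d_min + (self.tau_m_d_max - self.tau_m_d_min) * np.exp(-z * z)

    def n_d_inf(self, v):
        return 0.5 * (1.0 + np.tanh((v - self.n_d_half) / self.n_d_slope))

    def n_d_tau(self, v):
        return 1.0 / (self.n_d_rate * np.cosh((v - self.n_d_half) / (2.0 * self.n_d_slope)))


DEFAULT_ACTIVE = ActiveParameters()


# ---------------------------------------------------------------------------
# Stimulus protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Injected-current waveform targeted at one compartment.

    ``kind`` is one of triangular/pulses/step; ``pulses`` are
    (onset, duration, amplitude) triples added on top of ``baseline``.
    """

    kind: str
    t_end: float
    target: str = "soma"
    peak: float = 0.0
    t_peak: float = 0.0
    baseline: float = 0.0
    pulses: tuple = ()

    def current(self, t):
        t = np.asarray(t, float)
        if self.kind == "triangular":
            i = self.peak * (1.0 - np.abs(t - self.t_peak) / self.t_peak)
            out = self.baseline + np.maximum(i, 0.0)
        elif self.kind in ("pulses", "step"):
            out = np.full_like(t, self.baseline, dtype=float)
            for onset, duration, amplitude in self.pulses:
                out = out + amplitude * ((t >= onset) & (t < onset + duration))
        else:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        return out if out.ndim else float(out)


def triangular_protocol(peak: float = 2.5, t_peak: float = 1350.0, baseline: float = 0.0,
                        target: str = "soma") -> StimulusProtocol:
    """Symmetric ramp 0 -> peak -> 0 over [0, 2*t_peak]."""
    if peak <= 0 or t_peak <= 0:
        raise ValueError("peak and t_peak must be positive")
    return StimulusProtocol(kind="triangular", t_end=2.0 * t_peak, peak=peak,
                            t_peak=t_peak, baseline=baseline, target=target)


def pulse_protocol(baseline: float, pulses, t_end: float, target: str = "soma") -> StimulusProtocol:
    """Holding current plus brief (onset, duration, amplitude) pulses."""
    pulses = tuple(tuple(map(float, p)) for p in pulses)
    for onset, duration, _ in pulses:
        if duration <= 0 or onset < 0 or onset + duration > t_end:
            raise ValueError("pulses must lie within [0, t_end] with positive duration")
    return StimulusProtocol(kind="pulses", t_end=t_end, baseline=baseline,
                            pulses=pulses, target=target)


def switching_protocol(hold: float = 0.33, t_end: float = 3200.0) -> StimulusProtocol:
    """Bistability demonstration: holding current with on/off pulses.

    A sub-rheobase holding current keeps the model at rest; a depolarizing
    pulse latches the dendritic plateau and switches the model into
    self-sustained repetitive firing at the same holding current; a later
    strong hyperpolarizing pulse unlatches the plateau and returns it to
    rest.  Defaults calibrated for the default model.
    """
    return pulse_protocol(hold, [(600.0, 300.0, 1.7), (1800.0, 200.0, -3.0)], t_end)


def step_protocol(amplitude: float, t_on: float, t_end: float, target: str = "soma") -> StimulusProtocol:
    return StimulusProtocol(kind="step", t_end=t_end, baseline=0.0,
                            pulses=((t_on, t_end - t_on, amplitude),), target=target)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def derivatives(state, t, passive: PassiveParameters, p: float,
                active: ActiveParameters, i_s: float = 0.0, i_d: float = 0.0):
    """Time derivatives of [V_S, V_D, n_S, m_D, n_D] at one instant."""
    v_s, v_d, n_s, m_d, n_d = state
    a = active
    e_l = a.e_leak

    m_s = 0.5 * (1.0 + math.tanh((v_s - a.m_s_half) / a.m_s_slope))
    i_active_s = a.g_na * m_s * (v_s - a.e_na) + a.g_k_s * n_s * (v_s - a.e_k)
    i_active_d = a.g_ca * m_d * (v_d - a.e_ca) + a.g_k_d * n_d * (v_d - a.e_k)

    dv_s = (
        -passive.g_m_s * (v_s - e_l)
        - i_active_s
        - (passive.g_c / p) * (v_s - v_d)
        + i_s
    ) / passive.c_m_s
    dv_d = (
        -passive.g_m_d * (v_d - e_l)
        - i_active_d
        - (passive.g_c / (1.0 - p)) * (v_d - v_s)
        + i_d
    ) / passive.c_m_d

    n_s_inf = 0.5 * (1.0 + math.tanh((v_s - a.n_s_half) / a.n_s_slope))
    dn_s = a.n_s_rate * math.cosh((v_s - a.n_s_half) / (2.0 * a.n_s_slope)) * (n_s_inf - n_s)

    m_d_inf = 0.5 * (1.0 + math.tanh((v_d - a.m_d_half) / a.m_d_slope))
    z = (v_d - a.m_d_half) / a.tau_m_d_width
    tau_md = a.tau_m_d_min + (a.tau_m_d_max - a.tau_m_d_min) * math.exp(-min(50.0, z * z))
    dm_d = (m_d_inf - m_d) / tau_md

    n_d_inf = 0.5 * (1.0 + math.tanh((v_d - a.n_d_half) / a.n_d_slope))
    dn_d = a.n_d_rate * math.cosh((v_d - a.n_d_half) / (2.0 * a.n_d_slope)) * (n_d_inf - n_d)

    return (dv_s, dv_d, dn_s, dm_d, dn_d)


def steady_gates(active: ActiveParameters, v_s: float, v_d: float):
    return (
        float(active.n_s_inf(v_s)),
        float(active.m_d_inf(v_d)),
        float(active.n_d_inf(v_d)),
    )


def resting_state(passive: PassiveParameters, p: float, active: ActiveParameters,
                  i_s: float = 0.0, i_d: float = 0.0,
                  v_lo: float = -0.75, v_hi: float = -0.2):
    """Lowest equilibrium of the full system at a holding current.

    Gates are set to steady state; the remaining 2-D balance reduces to a
    scalar equation in V_S via the dendritic quasi-steady relation, solved
    by bracketing on the hyperpolarized branch.
    """

    def resid(v_s):
        v_d = _dendrite_steady(passive, p, active, v_s, i_d)
        st = (v_s, v_d) + steady_gates(active, v_s, v_d)
        return derivatives(st, 0.0, passive, p, active, i_s, i_d)[0] * passive.c_m_s

    lo, hi = v_lo, v_hi
    f_lo = resid(lo)
    grid = np.linspace(lo, hi, 200)
    v_root = None
    prev_v, prev_f = lo, f_lo
    for v in grid[1:]:
        f = resid(v)
        if f_lo == 0 or prev_f * f <= 0:
            v_root = brentq(resid, prev_v, v, xtol=1e-12)
            break
        prev_v, prev_f = v, f
    if v_root is None:
        raise RuntimeError("no resting equilibrium found in the hyperpolarized range")
    v_d = _dendrite_steady(passive, p, active, v_root, i_d)
    return np.array((v_root, v_d) + steady_gates(active, v_root, v_d))


def _dendrite_steady(passive, p, active, v_s, i_d):
    """Lowest V_D with dendritic gates at steady state, for a clamped V_S."""

    def resid(v_d):
        st = (v_s, v_d, 0.0) + tuple(steady_gates(active, v_s, v_d)[1:])
        return derivatives(st, 0.0, passive, p, active, 0.0, i_d)[1]

    vv = np.linspace(-0.8, 1.0, 400)
    prev_v, prev_f = vv[0], resid(vv[0])
    for v in vv[1:]:
        f = resid(v)
        if prev_f * f <= 0:
            return brentq(resid, prev_v, v, xtol=1e-12)
        prev_v, prev_f = v, f
    raise RuntimeError("no dendritic steady state found")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Uniform-grid time series of the model state and injected current."""

    t: np.ndarray
    v_s: np.ndarray
    v_d: np.ndarray
    n_s: np.ndarray
    m_d: np.ndarray
    n_d: np.ndarray
    i_s: np.ndarray
    protocol: StimulusProtocol
    passive: PassiveParameters | None = None
    active: ActiveParameters | None = None
    p: float | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "i_s": self.i_s, "v_s": self.v_s, "v_d": self.v_d,
             "n_s": self.n_s, "m_d": self.m_d, "n_d": self.n_d}
        )


def simulate(passive: PassiveParameters, p: float, active: ActiveParameters,
             protocol: StimulusProtocol, *, y0=None, dt_out: float = 0.05,
             rtol: float = 1e-6, atol: float = 1e-8, max_step: float = 0.5,
             method: str = "LSODA") -> SimulationTrace:
    """Integrate the model under a stimulus protocol.

    Deterministic adaptive integration (default LSODA, rtol 1e-6/atol 1e-8,
    max step 0.5) with dense output sampled on a uniform grid of spacing
    ``dt_out``.  The initial condition defaults to the resting state at the
    protocol's baseline current.
    """
    if y0 is None:
        i_s0 = protocol.baseline if protocol.target == "soma" else 0.0
        i_d0 = protocol.baseline if protocol.target == "dendrite" else 0.0
        y0 = resting_state(passive, p, active, i_s0, i_d0)
    soma_target = protocol.target == "soma"

    def rhs(t, y):
        i = protocol.current(t)
        return derivatives(y, t, passive, p, active,
                           i if soma_target else 0.0,
                           0.0 if soma_target else i)

    t_grid = np.arange(0.0, protocol.t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(rhs, (0.0, float(t_grid[-1])), np.asarray(y0, float),
                    method=method, rtol=rtol, atol=atol, max_step=max_step,
                    t_eval=t_grid)
    if not sol.success:
        raise RuntimeError(f"integration failed at t = {sol.t[-1]:.3f}: {sol.message}")
    y = sol.y
    gates = np.clip(y[2:5], 0.0, 1.0)  # numerical safety only
    return SimulationTrace(
        t=sol.t, v_s=y[0], v_d=y[1], n_s=gates[0], m_d=gates[1], n_d=gates[2],
        i_s=np.asarray(protocol.current(sol.t), float),
        protocol=protocol, passive=passive, active=active, p=p,
    )
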