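"""Analytic inverse and forward maps of the two-compartment reduced model.

The passive circuit couples a somatic and a lumped dendritic compartment
through a single conductance G_C, with coupling currents weighted by the
morphological factor p (somatic fraction of total membrane area):

    C_m,S dV_S/dt = -G_m,S (V_S - E_L) - (G_C/p)     (V_S - V_D) + I_S
    C_m,D dV_D/dt = -G_m,D (V_D - E_L) - (G_C/(1-p)) (V_D - V_S) + I_D

Five measurable system properties determine the five passive parameters in
closed form, in a fixed order:

1. r_N, VA_SD^DC, VA_DS^DC  ->  G_m,S, G_m,D, G_C   (steady-state circuit)
2. VA_SD^AC at omega        ->  C_m,D               (AC attenuation magnitude)
3. tau_m                    ->  C_m,S               (slow eigenvalue; last)

C_m,D only exists when the AC signal has attenuated more than DC
(VA_SD^AC < VA_SD^DC); the feasibility machinery classifies violations.

All quantities are in the model's normalized (dimensionless) units; time is
ms-scaled, so a characteristic frequency f_c in Hz enters as
omega = 2*pi*f_c/1000 rad per time unit (250 Hz -> pi/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SystemProperties",
    "PassiveParameters",
    "FeasibilityReport",
    "FeasibilityError",
    "DEFAULT_PROPERTIES",
    "omega_from_hz",
    "solve_dc_conductances",
    "va_sd_ac_magnitude",
    "solve_cmd",
    "solve_cms",
    "solve_uniform_capacitance",
    "solve_passive",
    "system_matrix",
    "time_constants",
    "first_order_response",
    "forward_properties",
    "feasibility",
    "dendritic_input_resistance",
]


def omega_from_hz(f_hz: float) -> float:
    """Angular frequency in rad per ms-scaled time unit for a frequency in Hz."""
    return 2.0 * math.pi * f_hz / 1000.0


class FeasibilityError(ValueError):
    """Raised when the requested property set admits no physical parameter set."""

    def __init__(self, condition: str, message: str):
        super().__init__(message)
        self.condition = condition


@dataclass(frozen=True)
class SystemProperties:
    """The five measurable constraints plus the morphological/measurement context.

    r_N is the somatic-area-normalized input resistance, tau_m the system
    (slowest) time constant, the three va_* the attenuation factors at the
    measurement distance d_path, p the somatic fraction of membrane area and
    f_c the characteristic AC frequency in Hz.
    """

    r_n: float = 0.19
    tau_m: float = 10.4
    va_sd_dc: float = 0.89
    va_ds_dc: float = 0.26
    va_sd_ac: float = 0.49
    p: float = 0.168
    f_c: float = 250.0
    d_path: float = 300.0

    def __post_init__(self):
        for name in ("r_n", "tau_m", "va_sd_dc", "va_ds_dc", "va_sd_ac", "p", "f_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("va_sd_dc", "va_ds_dc", "va_sd_ac"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")
        if self.p >= 1:
            raise ValueError("p must lie in (0, 1)")

    @property
    def omega(self) -> float:
        return omega_from_hz(self.f_c)

    def replace(self, **kw) -> "SystemProperties":
        return replace(self, **kw)


DEFAULT_PROPERTIES = SystemProperties()


@dataclass(frozen=True)
class PassiveParameters:
    """The five solved cable parameters of the two-compartment circuit."""

    g_m_s: float
    g_m_d: float
    g_c: float
    c_m_s: float
    c_m_d: float

    def replace(self, **kw) -> "PassiveParameters":
        return replace(self, **kw)


@dataclass
class FeasibilityReport:
    feasible: bool
    violated_conditions: list = field(default_factory=list)
    parameters: PassiveParameters | None = None

    def __post_init__(self):
        assert self.feasible == (not self.violated_conditions)


# ---------------------------------------------------------------------------
# Inverse maps
# ---------------------------------------------------------------------------

def solve_dc_conductances(props: SystemProperties):
    """Solve (G_m,S, G_m,D, G_C) from r_N and the two DC attenuation factors.

    The steady-state circuit gives
        VA_SD^DC = (G_C/(1-p)) / (G_m,D + G_C/(1-p))
        VA_DS^DC = (G_C/p)     / (G_m,S + G_C/p)
        r_N      = 1 / (G_m,S + (G_C/p) (1 - VA_SD^DC))
    which invert in closed form; G_m,S is analytically independent of p.
    """
    va_sd, va_ds = props.va_sd_dc, props.va_ds_dc
    denom = (1.0 - va_ds) / va_ds + (1.0 - va_sd)
    if denom <= 0:
        raise FeasibilityError("nonpositive_conductance", "DC attenuation factors admit no positive conductances")
    a = (1.0 / props.r_n) / denom  # a = G_C/p
    g_m_s = a * (1.0 - va_ds) / va_ds
    g_c = a * props.p
    b = g_c / (1.0 - props.p)  # G_C/(1-p)
    g_m_d = b * (1.0 - va_sd) / va_sd
    for name, val in (("g_m_s", g_m_s), ("g_m_d", g_m_d), ("g_c", g_c)):
        if val <= 0:
            raise FeasibilityError(
                "nonpositive_conductance", f"solved {name} = {val:.6g} is not positive"
            )
    return g_m_s, g_m_d, g_c


def va_sd_ac_magnitude(g_m_d: float, g_c: float, p: float, c_m_d: float, omega: float) -> float:
    """|V_D/V_S| of the AC transfer from soma to dendrite at angular frequency omega."""
    b = g_c / (1.0 - p)
    return b / math.hypot(g_m_d + b, omega * c_m_d)


def solve_cmd(g_m_d: float, g_c: float, p: float, va_sd_ac: float, omega: float) -> float:
    """Dendritic capacitance from the AC attenuation magnitude.

    Inverts the AC magnitude for C_m,D; a real solution requires the AC
    signal to have attenuated below the DC level at the same distance.
    """
    b = g_c / (1.0 - p)
    va_dc = b / (g_m_d + b)
    if va_sd_ac >= va_dc:
        raise FeasibilityError(
            "ac_exceeds_dc",
            f"VA_SD^AC = {va_sd_ac:.4g} must be below the DC attenuation {va_dc:.4g} "
            "for a real dendritic capacitance to exist",
        )
    c_m_d = math.sqrt((b / va_sd_ac) ** 2 - (g_m_d + b) ** 2) / omega
    return c_m_d


def _alpha_beta_kappa(g_m_s, g_m_d, g_c, p):
    alpha = g_m_s + g_c / p
    beta = g_m_d + g_c / (1.0 - p)
    kappa = g_c**2 / (p * (1.0 - p))
    return alpha, beta, kappa


def solve_cms(g_m_s: float, g_m_d: float, g_c: float, p: float, c_m_d: float, tau_m: float) -> float:
    """Somatic capacitance from the system time constant (must come last).

    -1/tau_m is imposed as a root of the characteristic polynomial
    lambda^2 + (alpha/C_S + beta/C_D) lambda + (alpha*beta - kappa)/(C_S C_D),
    which is linear in C_m,S; the solution is then checked to make -1/tau_m
    the SLOW (dominant) eigenvalue of the assembled system.
    """
    alpha, beta, kappa = _alpha_beta_kappa(g_m_s, g_m_d, g_c, p)
    lam = -1.0 / tau_m
    denom = lam**2 + beta * lam / c_m_d
    numer = -(alpha * lam + (alpha * beta - kappa) / c_m_d)
    if denom == 0:
        raise FeasibilityError("no_valid_somatic_capacitance", "degenerate characteristic equation")
    c_m_s = numer / denom
    if not (c_m_s > 0 and math.isfinite(c_m_s)):
        raise FeasibilityError(
            "no_valid_somatic_capacitance", f"solved C_m,S = {c_m_s:.6g} is not positive"
        )
    # slow-eigenvalue bookkeeping on the assembled matrix
    taus = time_constants(PassiveParameters(g_m_s, g_m_d, g_c, c_m_s, c_m_d), p)
    if not math.isclose(taus[0], tau_m, rel_tol=1e-9):
        raise FeasibilityError(
            "slow_eigenvalue_mismatch",
            f"-1/tau_m is not the slow eigenvalue (slow tau = {taus[0]:.6g}, requested {tau_m:.6g})",
        )
    return c_m_s


def solve_uniform_capacitance(g_m_s: float, g_m_d: float, g_c: float, p: float, tau_m: float) -> float:
    """Single capacitance C_m,S = C_m,D = C of the uniform-capacitance model.

    The characteristic equation becomes quadratic in C; of its two roots the
    one for which -1/tau_m is the slow (not equalizing) eigenvalue is
    returned.
    """
    alpha, beta, kappa = _alpha_beta_kappa(g_m_s, g_m_d, g_c, p)
    disc = (alpha + beta) ** 2 - 4.0 * (alpha * beta - kappa)
    if disc < 0:
        raise FeasibilityError("no_valid_somatic_capacitance", "no real uniform capacitance")
    roots = [tau_m * (alpha + beta - math.sqrt(disc)) / 2.0, tau_m * (alpha + beta + math.sqrt(disc)) / 2.0]
    for c in roots:
        if c <= 0:
            continue
        taus = time_constants(PassiveParameters(g_m_s, g_m_d, g_c, c, c), p)
        if math.isclose(taus[0], tau_m, rel_tol=1e-9):
            return c
    raise FeasibilityError(
        "no_valid_somatic_capacitance",
        "neither quadratic root makes -1/tau_m the slow eigenvalue",
    )


def solve_passive(props: SystemProperties) -> PassiveParameters:
    """Full inverse pipeline: five properties -> five passive parameters."""
    g_m_s, g_m_d, g_c = solve_dc_conductances(props)
    c_m_d = solve_cmd(g_m_d, g_c, props.p, props.va_sd_ac, props.omega)
    c_m_s = solve_cms(g_m_s, g_m_d, g_c, props.p, c_m_d, props.tau_m)
    return PassiveParameters(g_m_s=g_m_s, g_m_d=g_m_d, g_c=g_c, c_m_s=c_m_s, c_m_d=c_m_d)


# ---------------------------------------------------------------------------
# Forward maps
# ---------------------------------------------------------------------------

def system_matrix(params: PassiveParameters, p: float) -> np.ndarray:
    """Passive system matrix A of d[V_S, V_D]/dt = A [V_S, V_D] (+ inputs)."""
    alpha, beta, _ = _alpha_beta_kappa(params.g_m_s, params.g_m_d, params.g_c, p)
    return np.array(
        [
            [-alpha / params.c_m_s, (params.g_c / p) / params.c_m_s],
            [(params.g_c / (1.0 - p)) / params.c_m_d, -beta / params.c_m_d],
        ]
    )


def time_constants(params: PassiveParameters, p: float):
    """(tau_slow, tau_fast): negative reciprocals of the system eigenvalues."""
    ev = np.linalg.eigvals(system_matrix(params, p))
    ev = np.sort(np.real(ev))  # both real and negative for a passive circuit
    return (-1.0 / ev[1], -1.0 / ev[0])


def forward_properties(params: PassiveParameters, p: float, f_c: float = 250.0, d_path: float = 300.0) -> SystemProperties:
    """Recompute the five system properties from a passive parameter set.

    The steady-state quantities come from direct circuit solves (unit current
    at the soma or dendrite), tau_m from the eigenvalues, and VA_SD^AC from
    the AC magnitude at f_c; composing with :func:`solve_passive` is the
    identity on feasible property sets.
    """
    a = params.g_c / p
    b = params.g_c / (1.0 - p)
    va_sd_dc = b / (params.g_m_d + b)
    va_ds_dc = a / (params.g_m_s + a)
    # unit somatic current steady state
    r_n = 1.0 / (params.g_m_s + a * (1.0 - va_sd_dc))
    tau_m = time_constants(params, p)[0]
    va_sd_ac = va_sd_ac_magnitude(params.g_m_d, params.g_c, p, params.c_m_d, omega_from_hz(f_c))
    return SystemProperties(
        r_n=r_n,
        tau_m=tau_m,
        va_sd_dc=va_sd_dc,
        va_ds_dc=va_ds_dc,
        va_sd_ac=va_sd_ac,
        p=p,
        f_c=f_c,
        d_path=d_path,
    )


def dendritic_input_resistance(params: PassiveParameters, p: float) -> float:
    """Steady-state V_D per unit dendritic current (soma unstimulated)."""
    a = params.g_c / p
    b = params.g_c / (1.0 - p)
    va_ds = a / (params.g_m_s + a)
    return 1.0 / (params.g_m_d + b * (1.0 - va_ds))


def first_order_response(params: PassiveParameters, p: float, omega) -> tuple:
    """(VA, phase) of the soma-to-dendrite transfer in first-order form.

    VA = K/sqrt(1+(omega*tau)^2), phase = -atan(omega*tau) with gain
    K = VA_SD^DC and tau = C_m,D/(G_m,D + G_C/(1-p)); identical in magnitude
    to :func:`va_sd_ac_magnitude` for every omega.
    """
    b = params.g_c / (1.0 - p)
    k = b / (params.g_m_d + b)
    tau = params.c_m_d / (params.g_m_d + b)
    omega = np.asarray(omega, float)
    va = k / np.sqrt(1.0 + (omega * tau) ** 2)
    phase = -np.arctan(omega * tau)
    return va, phase


def feasibility(props: SystemProperties) -> FeasibilityReport:
    """Run the guarded inverse pipeline and classify any failure."""
    try:
        params = solve_passive(props)
    except FeasibilityError as exc:
        return FeasibilityReport(feasible=False, violated_conditions=[exc.condition])
    return FeasibilityReport(feasible=True, parameters=params)
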