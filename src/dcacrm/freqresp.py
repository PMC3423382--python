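"""Frequency response of passive dendritic trees.

For a passive tree the complex nodal system ``(G + j*omega*C) V = I`` is
solved for a unit sinusoidal point current; amplitude ratios and phase lags
between the source and every node give the spatial frequency response as a
function of path distance from the soma.  Summary fits (single-exponential
amplitude decay with constant eta; cubic-through-origin phase) condense a
profile into the attenuation factors consumed by the two-compartment
reduction.

Frequencies are user-facing Hz; internally omega = 2*pi*f rad/s against the
tree's electrical constants in CGS units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from .morphology import UM_TO_CM, CompartmentTree

__all__ = [
    "FrequencyResponseProfile",
    "DecayFit",
    "PhaseFit",
    "transfer_response",
    "transfer_matrix_factor",
    "attenuation_profile",
    "fit_exponential_decay",
    "fit_phase_cubic",
    "nyquist_coords",
]

SOMA_TO_DENDRITE = "soma_to_dendrite"
DENDRITE_TO_SOMA = "dendrite_to_soma"


@dataclass
class FrequencyResponseProfile:
    """Per-node amplitude ratio and phase lag at one frequency and direction."""

    direction: str
    frequency: float  # Hz
    node_ids: np.ndarray
    d_path: np.ndarray  # um from soma
    va: np.ndarray  # amplitude ratio in (0, 1]
    phase: np.ndarray  # radians, unwrapped, <= 0


@dataclass
class DecayFit:
    """Single-exponential amplitude decay VA = exp(-D_path/eta)."""

    eta: float  # um
    residual: float

    def __call__(self, d_path):
        return np.exp(-np.asarray(d_path, float) / self.eta)


@dataclass
class PhaseFit:
    """Cubic through the origin: phase = a3*D^3 + a2*D^2 + a1*D."""

    coefficients: tuple  # (a3, a2, a1)
    residual: float

    def __call__(self, d_path):
        d = np.asarray(d_path, float)
        a3, a2, a1 = self.coefficients
        return a3 * d**3 + a2 * d**2 + a1 * d


# ---------------------------------------------------------------------------
# Complex nodal solve
# ---------------------------------------------------------------------------

def _nodal_system(tree: CompartmentTree, frequency: float):
    """Sparse complex admittance matrix (G + j*omega*C) in Siemens."""
    n = tree.n_nodes
    areas_cm2 = tree.membrane_areas() * UM_TO_CM**2
    omega = 2.0 * np.pi * frequency  # rad/s
    y_mem = areas_cm2 * (1.0 / tree.r_m + 1j * omega * tree.c_m * 1e-6)
    g_ax = tree.axial_conductances()
    pidx = tree.parent_index()

    rows, cols, vals = [], [], []
    for k in range(n):
        diag = y_mem[k]
        if pidx[k] >= 0:
            diag += g_ax[k]
            rows += [k, pidx[k]]
            cols += [pidx[k], k]
            vals += [-g_ax[k], -g_ax[k]]
        for c in np.flatnonzero(pidx == k):
            diag += g_ax[c]
        rows.append(k)
        cols.append(k)
        vals.append(diag)
    return csc_matrix((np.array(vals, complex), (rows, cols)), shape=(n, n))


def transfer_matrix_factor(tree: CompartmentTree, frequency: float):
    """LU factorization of the nodal admittance matrix (reused across solves)."""
    if frequency < 0:
        raise ValueError("frequency must be non-negative")
    Y = _nodal_system(tree, frequency)
    if not np.isfinite(Y.data).all() or abs(Y.diagonal()).min() == 0.0:
        raise np.linalg.LinAlgError("singular nodal system")
    return splu(Y)


def transfer_response(tree: CompartmentTree, source_node: int, frequency: float) -> np.ndarray:
    """Complex voltage ratio V(node)/V(source) for unit current at ``source_node``.

    At frequency 0 this is the steady-state (DC) attenuation.  Returns one
    complex ratio per node in tree order.
    """
    lu = transfer_matrix_factor(tree, frequency)
    k = tree.index_of(source_node)
    rhs = np.zeros(tree.n_nodes, complex)
    rhs[k] = 1.0
    v = lu.solve(rhs)
    return v / v[k]


def _unwrap_along_tree(tree: CompartmentTree, raw_phase: np.ndarray, source_index: int) -> np.ndarray:
    """Accumulate phase continuously along root-to-tip paths from the source."""
    pidx = tree.parent_index()
    out = np.array(raw_phase, float)
    # process in tree order (parents precede children); source anchored at its raw value
    for k in range(tree.n_nodes):
        p = pidx[k]
        if p < 0 or k == source_index:
            continue
        delta = raw_phase[k] - raw_phase[p]
        delta = (delta + np.pi) % (2 * np.pi) - np.pi
        out[k] = out[p] + delta
    return out


def attenuation_profile(tree: CompartmentTree, direction: str, frequency: float) -> FrequencyResponseProfile:
    """Amplitude/phase profile over all nodes versus path distance from the soma.

    ``soma_to_dendrite``: a single solve with the current source at the soma.
    ``dendrite_to_soma``: each node acts in turn as a point source; the
    reported ratio is V(soma)/V(node).  Both reuse one LU factorization.
    """
    if direction not in (SOMA_TO_DENDRITE, DENDRITE_TO_SOMA):
        raise ValueError(f"unknown direction: {direction!r}")
    soma = tree.soma_node
    s = tree.index_of(soma)
    d_path = tree.path_distance()

    if direction == SOMA_TO_DENDRITE:
        ratio = transfer_response(tree, soma, frequency)
        raw = np.angle(ratio)
        phase = _unwrap_along_tree(tree, raw, s)
        phase -= phase[s]
    else:
        lu = transfer_matrix_factor(tree, frequency)
        n = tree.n_nodes
        ratio = np.empty(n, complex)
        for k in range(n):
            rhs = np.zeros(n, complex)
            rhs[k] = 1.0
            v = lu.solve(rhs)
            ratio[k] = v[s] / v[k]
        raw = np.angle(ratio)
        phase = _unwrap_along_tree(tree, raw, s)
        phase -= phase[s]
    return FrequencyResponseProfile(
        direction=direction,
        frequency=frequency,
        node_ids=tree.ids.copy(),
        d_path=d_path,
        va=np.abs(ratio),
        phase=phase,
    )


# ---------------------------------------------------------------------------
# Summary fits
# ---------------------------------------------------------------------------

def fit_exponential_decay(profile: FrequencyResponseProfile | None = None, *, d_path=None, va=None) -> DecayFit:
    """Least-squares fit VA = exp(-D_path/eta) on the linear amplitude scale."""
    if profile is not None:
        d_path, va = profile.d_path, profile.va
    d = np.asarray(d_path, float)
    v = np.asarray(va, float)
    if len(d) < 3:
        raise ValueError("need at least 3 points to fit a decay constant")
    # log-linear start value; guards against va underflow
    pos = v > 0
    slope = np.polyfit(d[pos], np.log(v[pos]), 1)[0]
    eta0 = -1.0 / slope if slope < 0 else max(d.max(), 1.0)
    try:
        popt, _ = optimize.curve_fit(lambda x, eta: np.exp(-x / eta), d, v, p0=[eta0], maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential decay fit did not converge: {exc}") from exc
    eta = float(popt[0])
    if eta <= 0:
        raise RuntimeError(f"exponential decay fit returned non-positive eta = {eta}")
    resid = float(np.sum((np.exp(-d / eta) - v) ** 2))
    return DecayFit(eta=eta, residual=resid)


def fit_phase_cubic(profile: FrequencyResponseProfile | None = None, *, d_path=None, phase=None) -> PhaseFit:
    """Least-squares cubic through the origin for the phase profile."""
    if profile is not None:
        d_path, phase = profile.d_path, profile.phase
    d = np.asarray(d_path, float)
    ph = np.asarray(phase, float)
    if len(d) < 4:
        raise ValueError("need at least 4 points to fit a cubic")
    basis = np.column_stack([d**3, d**2, d])
    coef, res, *_ = np.linalg.lstsq(basis, ph, rcond=None)
    resid = float(res[0]) if len(res) else float(np.sum((basis @ coef - ph) ** 2))
    return PhaseFit(coefficients=tuple(float(c) for c in coef), residual=resid)


def nyquist_coords(va, phase):
    """Cartesian (x, y) of the frequency-response vector VA*exp(j*phase)."""
    va = np.asarray(va, float)
    if np.any(va < 0):
        raise ValueError("VA must be non-negative")
    phase = np.asarray(phase, float)
    return va * np.cos(phase), va * np.sin(phase)
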