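"""Spike/plateau extraction, characteristic indexes and firing-type labels.

During a symmetric triangular current ramp the three characteristic indexes
quantify bistable behaviour:

TTP  (time to plateau)   = dendritic plateau onset - first somatic spike;
TES  (end of spiking)    = last spike - time at which the descending ramp
                           re-crosses the ascending rheobase current;
DSF  (frequency diff.)   = descending - ascending instantaneous firing rate,
                           both interpolated at the rheobase current.

All three positive defines fully-bistable (Type IV, counter-clockwise F-I
hysteresis with sustained firing); the remaining labels follow the standard
F-I taxonomy for motor neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SimulationTrace, StimulusProtocol

__all__ = [
    "FiringMetrics",
    "detect_spikes",
    "detect_plateau_onset",
    "detect_plateau_offset",
    "fi_curves",
    "characteristic_indexes",
    "classify_firing",
    "analyze",
]

SPIKE_THRESHOLD = 0.0
REFRACTORY = 2.0
PLATEAU_HOLD = 10.0
TTP_DEADBAND = 5.0
DSF_DEADBAND = 0.002


@dataclass
class FiringMetrics:
    """Everything extracted from one triangular-ramp run."""

    spike_times: np.ndarray
    rheobase_current: float | None = None
    plateau_onset_time: float | None = None
    plateau_offset_time: float | None = None
    plateau_offset_current: float | None = None
    last_spike_time: float | None = None
    ttp: float | None = None
    tes: float | None = None
    dsf: float | None = None
    fi_ascending: tuple | None = None  # (I, f) arrays
    fi_descending: tuple | None = None
    label: str = "quiescent"


def detect_spikes(trace: SimulationTrace, threshold: float = SPIKE_THRESHOLD,
                  refractory: float = REFRACTORY) -> np.ndarray:
    """Times of upward V_S threshold crossings separated by >= refractory."""
    v = trace.v_s
    t = trace.t
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    times = []
    # linear interpolation of the crossing instant
    for k in up:
        frac = (threshold - v[k]) / (v[k + 1] - v[k])
        tc = t[k] + frac * (t[k + 1] - t[k])
        if not times or tc - times[-1] >= refractory:
            times.append(tc)
    return np.asarray(times)


ENVELOPE_WINDOW = 60.0


def _lower_envelope(trace: SimulationTrace, window: float = ENVELOPE_WINDOW) -> np.ndarray:
    """Rolling minimum of V_D over a centered window longer than one ISI.

    Back-propagated spikes ride on the dendritic potential as brief
    depolarizing transients; the lower envelope (the inter-spike troughs)
    tracks the underlying plateau state and is immune to that ripple.
    """
    import scipy.ndimage as ndi

    n_win = max(1, int(round(window / trace.dt)))
    return ndi.minimum_filter1d(trace.v_d, size=n_win, mode="nearest")


def _plateau_levels(env: np.ndarray):
    """(baseline, high) levels of the dendritic lower envelope."""
    return float(env[0]), float(np.max(env))


def detect_plateau_onset(trace: SimulationTrace, hold: float = PLATEAU_HOLD,
                         min_amplitude: float = 0.15,
                         window: float = ENVELOPE_WINDOW) -> float | None:
    """First sustained elevation of the dendritic lower envelope.

    The envelope must cross the midpoint between its pre-stimulus baseline
    and its plateau-branch high with positive slope, and stay above it for
    ``hold`` time units.  Returns None when the envelope never lifts by at
    least ``min_amplitude`` (no plateau).
    """
    env = _lower_envelope(trace, window)
    baseline, high = _plateau_levels(env)
    if high - baseline < min_amplitude:
        return None
    mid = 0.5 * (baseline + high)
    above = env >= mid
    n_hold = max(1, int(round(hold / trace.dt)))
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        idx = np.r_[0, idx]
    for k in idx:
        if bool(np.all(above[k:k + n_hold])):
            return float(trace.t[k])
    return None


def detect_plateau_offset(trace: SimulationTrace, onset: float,
                          hold: float = PLATEAU_HOLD,
                          window: float = ENVELOPE_WINDOW) -> float | None:
    """First sustained drop of the envelope back below the midpoint."""
    env = _lower_envelope(trace, window)
    baseline, high = _plateau_levels(env)
    mid = 0.5 * (baseline + high)
    below = env < mid
    start = int(np.searchsorted(trace.t, onset))
    n_hold = max(1, int(round(hold / trace.dt)))
    idx = np.flatnonzero(~below[start:-1] & below[start + 1:]) + start + 1
    for k in idx:
        if bool(np.all(below[k:k + n_hold])):
            return float(trace.t[k])
    return None


def fi_curves(spike_times: np.ndarray, protocol: StimulusProtocol):
    """Ascending and descending (I, f) branches from a triangular run.

    The instantaneous frequency 1/ISI is assigned to the second spike of
    each pair and mapped to the injected current at that instant; pairs
    straddling the ramp apex are assigned by the second spike's phase.
    """
    if protocol.kind != "triangular":
        raise ValueError("F-I analysis requires a triangular protocol")
    st = np.asarray(spike_times)
    if len(st) < 2:
        empty = (np.array([]), np.array([]))
        return empty, empty
    t2 = st[1:]
    f = 1.0 / np.diff(st)
    i2 = np.asarray(protocol.current(t2), float)
    asc = t2 <= protocol.t_peak
    return (i2[asc], f[asc]), (i2[~asc], f[~asc])


def _interp_branch(branch, i_query: float) -> float | None:
    i, f = branch
    if len(i) == 0:
        return None
    order = np.argsort(i)
    i, f = i[order], f[order]
    if len(i) == 1:
        return float(f[0])
    return float(np.interp(i_query, i, f))


def characteristic_indexes(trace: SimulationTrace, protocol: StimulusProtocol | None = None,
                           **detector_kwargs) -> FiringMetrics:
    """Compute spikes, plateau timing, F-I branches and the three indexes."""
    protocol = protocol or trace.protocol
    spikes = detect_spikes(trace, **detector_kwargs)
    m = FiringMetrics(spike_times=spikes)
    if len(spikes) == 0:
        return m
    first, last = float(spikes[0]), float(spikes[-1])
    m.last_spike_time = last
    m.rheobase_current = float(protocol.current(first))

    onset = detect_plateau_onset(trace)
    m.plateau_onset_time = onset
    if onset is not None:
        m.ttp = onset - first
        offset = detect_plateau_offset(trace, onset)
        m.plateau_offset_time = offset
        if offset is not None:
            m.plateau_offset_current = float(protocol.current(offset))

    # TES: persistence past the descending re-crossing of ascending rheobase
    t_recross = 2.0 * protocol.t_peak - first
    m.tes = last - t_recross

    m.fi_ascending, m.fi_descending = fi_curves(spikes, protocol)
    f_asc = _interp_branch(m.fi_ascending, m.rheobase_current)
    f_desc = _interp_branch(m.fi_descending, m.rheobase_current)
    if f_asc is not None and f_desc is not None:
        m.dsf = f_desc - f_asc
    return m


def classify_firing(metrics: FiringMetrics, ttp_deadband: float = TTP_DEADBAND,
                    dsf_deadband: float = DSF_DEADBAND,
                    plateau_possible: bool | None = None,
                    plateau_sustain_current: float | None = None) -> str:
    """Map characteristic indexes to a firing-type label.

    IV_bistable      : TTP, TES and DSF all positive (counter-clockwise
                       hysteresis with sustained firing).
    partial_bistable : plateau present but deactivated on descent at a
                       current above the ascending rheobase; also
                       tightly-coupled (synchronized) cells whose dendrite
                       has no saddle-node fold yet shows hysteresis from
                       slow-gate lag.
    III              : plateau co-activated with spiking (TTP ~ 0),
                       sustained firing, no hysteresis (DSF ~ 0).
    II               : no plateau, clockwise hysteresis (DSF < 0).
    I                : no plateau, overlapping F-I, no sustained firing.
    quiescent        : no spikes.

    ``plateau_possible`` is the structural prerequisite (an S-shaped
    dendritic fixed-point branch, see
    :func:`dcacrm.bifurcation.dendritic_fold_exists`); when False the
    trace-level plateau detection is overridden: a smooth dendritic
    depolarization cannot be a regenerative plateau.
    ``plateau_sustain_current`` is the deactivation (lower saddle-node)
    current of that branch; a plateau that cannot survive below the
    ascending rheobase deactivates on the descending ramp above rheobase,
    which is partial, not full, bistability.
    """
    if len(metrics.spike_times) == 0:
        return "quiescent"
    plateau = metrics.plateau_onset_time is not None
    if plateau_possible is False:
        plateau = False
    if (
        plateau
        and plateau_sustain_current is not None
        and metrics.rheobase_current is not None
        and plateau_sustain_current > metrics.rheobase_current
    ):
        return "partial_bistable"
    ttp = metrics.ttp if metrics.ttp is not None else 0.0
    tes = metrics.tes if metrics.tes is not None else 0.0
    dsf = metrics.dsf if metrics.dsf is not None else 0.0

    if plateau:
        deactivated_early = (
            metrics.plateau_offset_current is not None
            and metrics.rheobase_current is not None
            and metrics.plateau_offset_current > metrics.rheobase_current
        )
        if deactivated_early:
            return "partial_bistable"
        if ttp > ttp_deadband and tes > 0 and dsf > dsf_deadband:
            return "IV_bistable"
        if tes > 0 and abs(dsf) <= dsf_deadband and abs(ttp) <= ttp_deadband:
            return "III"
        # plateau with some hysteresis but not all indexes positive
        if ttp <= ttp_deadband and tes > 0:
            return "III"
        return "partial_bistable"
    if dsf > dsf_deadband and tes > 0:
        # counter-clockwise hysteresis without a plateau mechanism:
        # slow-gate lag in a tightly coupled (synchronized) cell
        return "partial_bistable"
    if dsf < -dsf_deadband:
        return "II"
    return "I"


def analyze(trace: SimulationTrace, protocol: StimulusProtocol | None = None,
            plateau_possible: bool | None = None,
            plateau_sustain_current: float | None = None) -> FiringMetrics:
    """Full pipeline: indexes plus label, stored on the returned metrics.

    When the trace carries its model parameters, the structural plateau
    prerequisites (S-shaped blocked dendritic branch reachable within the
    stimulus, deactivation fold location) are derived automatically unless
    given explicitly.
    """
    m = characteristic_indexes(trace, protocol)
    if plateau_possible is None and trace.passive is not None and trace.active is not None:
        from .bifurcation import dendritic_fold_currents

        folds = dendritic_fold_currents(
            trace.passive, trace.p, trace.active.replace(g_na=0.0, g_k_s=0.0)
        )
        plateau_possible = folds is not None and folds[0] <= float(np.max(trace.i_s))
        if plateau_sustain_current is None and folds is not None:
            plateau_sustain_current = folds[1]
    m.label = classify_firing(m, plateau_possible=plateau_possible,
                              plateau_sustain_current=plateau_sustain_current)
    return m
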