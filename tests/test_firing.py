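"""Spike/plateau extraction, characteristic indexes and firing classification."""

import numpy as np
import pytest

from dcacrm import firing as FA
from dcacrm.dynamics import SimulationTrace, simulate, step_protocol, triangular_protocol


def synthetic_trace(t_end=1000.0, dt=0.1, spike_times=(), v_d=None, protocol=None):
    t = np.arange(0.0, t_end + dt / 2, dt)
    v_s = np.full_like(t, -0.5)
    for ts in spike_times:
        v_s += 0.6 * np.exp(-((t - ts) / 1.0) ** 2)  # 0.1-peak gaussian spikes
    if v_d is None:
        v_d = np.full_like(t, -0.5)
    proto = protocol or triangular_protocol(peak=2.5, t_peak=t_end / 2)
    return SimulationTrace(t=t, v_s=v_s, v_d=np.asarray(v_d), n_s=np.zeros_like(t),
                           m_d=np.zeros_like(t), n_d=np.zeros_like(t),
                           i_s=np.asarray(proto.current(t), float), protocol=proto)


def test_no_spikes_on_subthreshold_trace():
    trace = synthetic_trace()
    assert len(FA.detect_spikes(trace)) == 0
    assert FA.analyze(trace).label == "quiescent"


def test_detects_injected_spikes_at_known_times():
    times = np.linspace(100, 900, 10)
    trace = synthetic_trace(spike_times=times)
    detected = FA.detect_spikes(trace)
    assert len(detected) == 10
    np.testing.assert_allclose(detected, times, atol=1.5)


def test_refractory_merges_double_crossings():
    trace = synthetic_trace(spike_times=(100.0, 100.8, 300.0))
    assert len(FA.detect_spikes(trace)) == 2


def test_plateau_absent_on_flat_dendrite():
    trace = synthetic_trace(spike_times=(400.0,))
    assert FA.detect_plateau_onset(trace) is None


def test_plateau_onset_on_step_like_dendrite():
    t = np.arange(0.0, 1000.1, 0.1)
    v_d = np.where(t < 600.0, -0.5, 0.0)
    trace = synthetic_trace(v_d=v_d)
    onset = FA.detect_plateau_onset(trace)
    assert onset == pytest.approx(600.0, abs=FA.ENVELOPE_WINDOW)
    off = FA.detect_plateau_offset(trace, onset)
    assert off is None


def test_plateau_detector_ignores_spike_ripple():
    """Brief dendritic transients riding on a resting baseline are not a
    plateau even when their peaks cross the midpoint."""
    t = np.arange(0.0, 1000.1, 0.1)
    v_d = np.full_like(t, -0.5)
    for ts in np.arange(100.0, 900.0, 50.0):
        v_d += 0.45 * np.exp(-((t - ts) / 3.0) ** 2)
    trace = synthetic_trace(v_d=v_d)
    assert FA.detect_plateau_onset(trace) is None


def test_default_run_characteristic_indexes(default_trace):
    m = FA.analyze(default_trace)
    assert len(m.spike_times) > 20
    assert m.label == "IV_bistable"
    assert m.ttp > 0 and m.tes > 0 and m.dsf > 0
    # plateau onset strictly after the first somatic spike
    assert m.plateau_onset_time > m.spike_times[0]
    # first spike during the ascending ramp
    assert m.spike_times[0] < default_trace.protocol.t_peak


def test_rheobase_consistent_with_ascending_ramp(default_trace):
    m = FA.analyze(default_trace)
    proto = default_trace.protocol
    assert m.rheobase_current == pytest.approx(
        float(proto.current(m.spike_times[0])), abs=1e-12
    )
    # near rest the ascending V_S-I_S slope tracks the input resistance;
    # the Na window conductance of the active set steepens it by ~10%
    i = default_trace.i_s
    near_rest = (default_trace.t < default_trace.protocol.t_peak) & (i > 0.02) & (i < 0.10)
    slope = np.polyfit(i[near_rest], default_trace.v_s[near_rest], 1)[0]
    assert slope == pytest.approx(0.19, rel=0.15)


def test_subthreshold_slope_equals_input_resistance_for_passive_model(
    passive, props, active
):
    """With active conductances blocked the ramp V_S-I_S slope recovers the
    whole-cell input resistance to within 2% (window-conductance tails of
    the active set account for the larger deviation of the full model)."""
    from dcacrm.dynamics import simulate

    proto = triangular_protocol(peak=1.0, t_peak=400.0)
    blocked = active.replace(g_na=0.0, g_k_s=0.0, g_ca=0.0, g_k_d=0.0)
    trace = simulate(passive, props.p, blocked, proto, dt_out=0.1)
    i = trace.i_s
    sel = (trace.t < proto.t_peak) & (i > 0.05) & (i < 0.4)
    slope = np.polyfit(i[sel], trace.v_s[sel], 1)[0]
    assert slope == pytest.approx(0.19, rel=0.02)


def test_counterclockwise_hysteresis_in_fi_curves(default_trace):
    m = FA.analyze(default_trace)
    (i_asc, f_asc), (i_desc, f_desc) = m.fi_ascending, m.fi_descending
    assert len(i_asc) > 5 and len(i_desc) > 5
    # descending branch lies above ascending at the rheobase current
    assert m.dsf > 0


def test_plateau_ablation_removes_bistable_firing(passive, props, active, default_trace):
    """Without the dendritic Ca PIC there is no plateau mechanism: the label
    collapses to Type I/II, the F-I hysteresis vanishes, and the residual
    post-rheobase firing (delayed spiking onset from slow passage through
    the Hopf point under a ramp) is small next to the plateau-sustained
    firing of the intact model."""
    no_pic = active.replace(g_ca=0.0)
    proto = triangular_protocol()
    trace = simulate(passive, props.p, no_pic, proto, dt_out=0.1)
    m = FA.analyze(trace)
    assert m.label in ("I", "II")
    assert m.dsf is None or m.dsf <= FA.DSF_DEADBAND
    m_full = FA.analyze(default_trace)
    assert m.tes < 0.3 * m_full.tes


def test_classification_rules_on_synthetic_metrics():
    def metrics(**kw):
        m = FA.FiringMetrics(spike_times=np.array([1.0, 2.0]))
        m.rheobase_current = 0.6
        for k, v in kw.items():
            setattr(m, k, v)
        return m

    assert FA.classify_firing(FA.FiringMetrics(spike_times=np.array([]))) == "quiescent"
    assert FA.classify_firing(
        metrics(plateau_onset_time=500.0, ttp=100.0, tes=200.0, dsf=0.01)
    ) == "IV_bistable"
    assert FA.classify_firing(
        metrics(plateau_onset_time=500.0, ttp=1.0, tes=200.0, dsf=0.001)
    ) == "III"
    assert FA.classify_firing(
        metrics(plateau_onset_time=500.0, ttp=100.0, tes=200.0, dsf=0.01,
                plateau_offset_current=1.5)
    ) == "partial_bistable"
    assert FA.classify_firing(metrics(tes=-50.0, dsf=-0.01)) == "II"
    assert FA.classify_firing(metrics(tes=-50.0, dsf=0.0)) == "I"
    # structural override: no dendritic fold means no plateau label
    assert FA.classify_firing(
        metrics(plateau_onset_time=500.0, ttp=100.0, tes=200.0, dsf=0.01),
        plateau_possible=False,
    ) == "partial_bistable"
    assert FA.classify_firing(
        metrics(plateau_onset_time=500.0, ttp=100.0, tes=-10.0, dsf=0.0),
        plateau_possible=False,
    ) == "I"
    # a plateau that cannot survive below rheobase is partial
    assert FA.classify_firing(
        metrics(plateau_onset_time=500.0, ttp=100.0, tes=200.0, dsf=0.01),
        plateau_sustain_current=1.0,
    ) == "partial_bistable"


def test_classification_stable_under_grid_refinement(passive, props, active):
    proto = triangular_protocol()
    labels = set()
    for dt_out in (0.2, 0.1):
        trace = simulate(passive, props.p, active, proto, dt_out=dt_out)
        labels.add(FA.analyze(trace).label)
    assert labels == {"IV_bistable"}


def test_classification_refinement_stable_on_random_cells(props, active):
    """Halving the output grid leaves the firing-type label unchanged on
    randomly drawn feasible attenuation triples."""
    from dcacrm.reduction import feasibility

    rng = np.random.default_rng(11)
    proto = triangular_protocol()
    checked = 0
    while checked < 4:
        va_sd = rng.uniform(0.4, 0.95)
        cell = props.replace(va_sd_dc=va_sd, va_ds_dc=rng.uniform(0.1, 0.9),
                             va_sd_ac=rng.uniform(0.1, 0.95) * va_sd)
        rep = feasibility(cell)
        if not rep.feasible:
            continue
        labels = {
            FA.analyze(simulate(rep.parameters, props.p, active, proto, dt_out=dt)).label
            for dt in (0.2, 0.1)
        }
        assert len(labels) == 1, cell
        checked += 1
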