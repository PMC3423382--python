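"""Analytic inverse/forward maps: published regression values and identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcacrm import reduction as R


def test_dc_conductances_from_default_properties(props):
    g_m_s, g_m_d, g_c = R.solve_dc_conductances(props)
    assert round(g_m_s, 3) == 5.067
    assert g_m_d == pytest.approx(0.044, rel=0.01)
    assert g_c == pytest.approx(0.299, rel=0.01)


def test_somatic_conductance_independent_of_p(props):
    base = R.solve_dc_conductances(props)[0]
    for p in (0.05, 0.168, 0.4, 0.8):
        assert R.solve_dc_conductances(props.replace(p=p))[0] == pytest.approx(base, rel=1e-12)


def test_perfect_dendrite_to_soma_transfer_is_infeasible(props):
    with pytest.raises(R.FeasibilityError):
        R.solve_dc_conductances(props.replace(va_ds_dc=1.0))


@pytest.mark.parametrize(
    "va_ac, expected_cmd",
    [(0.49, 0.39), (0.08, 2.851), (0.88, 0.039)],
)
def test_dendritic_capacitance_matches_published_values(props, va_ac, expected_cmd):
    g_m_s, g_m_d, g_c = R.solve_dc_conductances(props)
    c_m_d = R.solve_cmd(g_m_d, g_c, props.p, va_ac, props.omega)
    assert c_m_d == pytest.approx(expected_cmd, rel=0.01)


def test_ac_magnitude_round_trip_and_dc_limit(props, passive):
    va0 = R.va_sd_ac_magnitude(passive.g_m_d, passive.g_c, props.p, passive.c_m_d, 0.0)
    assert va0 == pytest.approx(props.va_sd_dc, abs=1e-12)
    va = R.va_sd_ac_magnitude(passive.g_m_d, passive.g_c, props.p, passive.c_m_d, props.omega)
    assert va == pytest.approx(props.va_sd_ac, abs=1e-12)
    assert round(va, 2) == 0.49


def test_ac_magnitude_strictly_decreasing_in_frequency():
    rng = np.random.default_rng(7)
    for _ in range(20):
        g_m_d, g_c, c = rng.uniform(0.01, 2, 3)
        p = rng.uniform(0.05, 0.9)
        omegas = np.linspace(0, 10, 50)
        vals = [R.va_sd_ac_magnitude(g_m_d, g_c, p, c, w) for w in omegas]
        assert np.all(np.diff(vals) < 0)


def test_cmd_vanishes_at_the_existence_boundary(props):
    g_m_s, g_m_d, g_c = R.solve_dc_conductances(props)
    for eps in (1e-4, 1e-6, 1e-8):
        c = R.solve_cmd(g_m_d, g_c, props.p, props.va_sd_dc - eps, props.omega)
        assert 0 < c < 10 * math.sqrt(eps)
    with pytest.raises(R.FeasibilityError):
        R.solve_cmd(g_m_d, g_c, props.p, props.va_sd_dc, props.omega)


def test_somatic_capacitance_and_slow_time_constant(props, passive):
    assert passive.c_m_s == pytest.approx(53.103, rel=0.01)
    tau_slow, tau_fast = R.time_constants(passive, props.p)
    assert round(tau_slow, 1) == 10.4
    assert tau_fast < tau_slow


def test_decoupled_limit_somatic_slow_mode():
    # kappa = 0: compartments independent; soma holds the slow mode
    g_m_s, g_m_d, p, tau = 0.5, 5.0, 0.3, 8.0
    c_m_d = 0.1  # dendritic tau = 0.02 << 8
    c_m_s = R.solve_cms(g_m_s, g_m_d, 1e-12, p, c_m_d, tau)
    assert c_m_s == pytest.approx(tau * g_m_s, rel=1e-6)


def test_uniform_capacitance_contrast(props):
    g_m_s, g_m_d, g_c = R.solve_dc_conductances(props)
    c = R.solve_uniform_capacitance(g_m_s, g_m_d, g_c, props.p, props.tau_m)
    assert c == pytest.approx(3.18, rel=0.01)
    va = R.va_sd_ac_magnitude(g_m_d, g_c, props.p, c, props.omega)
    assert round(va, 2) == 0.07
    # the rejected (larger) root would make -1/tau_m the fast equalizing mode
    uni = R.PassiveParameters(g_m_s, g_m_d, g_c, c, c)
    assert R.time_constants(uni, props.p)[0] == pytest.approx(props.tau_m, rel=1e-9)


def test_symmetric_uniform_model_eigenstructure():
    """With p = 0.5, equal membrane conductances and uniform capacitance the
    circuit is mirror-symmetric: eigenvectors are the in-phase (slow) and
    anti-phase (equalizing) modes."""
    g, g_c, tau = 1.0, 0.5, 2.0
    c = R.solve_uniform_capacitance(g, g, g_c, 0.5, tau)
    A = R.system_matrix(R.PassiveParameters(g, g, g_c, c, c), 0.5)
    lam, V = np.linalg.eig(A)
    order = np.argsort(lam)[::-1]  # slow first
    slow, fast = V[:, order[0]], V[:, order[1]]
    assert slow[0] == pytest.approx(slow[1], rel=1e-9)
    assert fast[0] == pytest.approx(-fast[1], rel=1e-9)


def test_forward_properties_recover_default_inputs(props, passive):
    fwd = R.forward_properties(passive, props.p, props.f_c)
    assert round(fwd.r_n, 2) == 0.19
    assert round(fwd.va_sd_dc, 2) == 0.89
    assert round(fwd.va_ds_dc, 2) == 0.26
    assert round(fwd.tau_m, 1) == 10.4


def _random_feasible_props(rng):
    while True:
        va_sd = rng.uniform(0.2, 0.98)
        va_ds = rng.uniform(0.05, 0.95)
        va_ac = rng.uniform(0.02, va_sd * 0.98)
        try:
            return R.SystemProperties(
                r_n=rng.uniform(0.05, 1.0),
                tau_m=rng.uniform(2.0, 30.0),
                va_sd_dc=va_sd,
                va_ds_dc=va_ds,
                va_sd_ac=va_ac,
                p=rng.uniform(0.05, 0.6),
            )
        except ValueError:
            continue


def test_inverse_forward_round_trip_on_random_properties():
    rng = np.random.default_rng(2024)
    n_ok = 0
    for _ in range(1000):
        props = _random_feasible_props(rng)
        try:
            params = R.solve_passive(props)
        except R.FeasibilityError:
            continue
        fwd = R.forward_properties(params, props.p, props.f_c)
        for name in ("r_n", "tau_m", "va_sd_dc", "va_ds_dc", "va_sd_ac"):
            assert abs(getattr(fwd, name) - getattr(props, name)) < 1e-9, name
        n_ok += 1
    assert n_ok > 500  # most random draws are feasible


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    r_n=st.floats(0.05, 1.0),
    tau_m=st.floats(2.0, 30.0),
    va_sd=st.floats(0.2, 0.98),
    va_ds=st.floats(0.05, 0.95),
    ac_frac=st.floats(0.05, 0.95),
    p=st.floats(0.05, 0.6),
)
def test_round_trip_property(r_n, tau_m, va_sd, va_ds, ac_frac, p):
    props = R.SystemProperties(
        r_n=r_n, tau_m=tau_m, va_sd_dc=va_sd, va_ds_dc=va_ds,
        va_sd_ac=ac_frac * va_sd, p=p,
    )
    try:
        params = R.solve_passive(props)
    except R.FeasibilityError:
        return
    fwd = R.forward_properties(params, p, props.f_c)
    assert abs(fwd.r_n - r_n) < 1e-9
    assert abs(fwd.tau_m - tau_m) < 1e-9
    assert abs(fwd.va_sd_ac - props.va_sd_ac) < 1e-9


def test_first_order_form_identical_to_ac_magnitude(props, passive):
    omega = np.linspace(0, 50, 300)
    va, phase = R.first_order_response(passive, props.p, omega)
    direct = np.array([
        R.va_sd_ac_magnitude(passive.g_m_d, passive.g_c, props.p, passive.c_m_d, w)
        for w in omega
    ])
    np.testing.assert_allclose(va, direct, atol=1e-12)
    assert phase[0] == 0.0
    assert va[0] == pytest.approx(props.va_sd_dc, abs=1e-12)
    # high-frequency limit: full quarter-turn phase lag
    va_inf, ph_inf = R.first_order_response(passive, props.p, 1e9)
    assert va_inf < 1e-6
    assert ph_inf == pytest.approx(-np.pi / 2, abs=1e-6)


def test_dendritic_input_resistance_relation(props, passive):
    # R_N,D = R_N,S * VA_SD/VA_DS after carrying the per-area normalization
    r_nd = R.dendritic_input_resistance(passive, props.p)
    expected = props.r_n * ((1 - props.p) / props.p) * props.va_sd_dc / props.va_ds_dc
    assert r_nd == pytest.approx(expected, abs=1e-9)


def test_feasibility_classification(props):
    assert R.feasibility(props).feasible
    bad_ac = R.feasibility(props.replace(va_sd_ac=0.95))
    assert not bad_ac.feasible
    assert bad_ac.violated_conditions == ["ac_exceeds_dc"]
    # lower-right corner of the attenuation plane at the default AC level:
    # VA_SD^DC below VA_SD^AC leaves no real dendritic capacitance
    corner = R.feasibility(props.replace(va_sd_dc=0.3, va_ds_dc=0.9))
    assert not corner.feasible
    assert corner.violated_conditions == ["ac_exceeds_dc"]


def test_property_validation():
    with pytest.raises(ValueError):
        R.SystemProperties(r_n=-0.1)
    with pytest.raises(ValueError):
        R.SystemProperties(p=1.0)
    with pytest.raises(ValueError):
        R.SystemProperties(va_sd_dc=1.2)
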