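"""Tree frequency response against closed-form cable theory and passivity."""

import numpy as np
import pytest

from dcacrm import freqresp as F
from dcacrm.morphology import UM_TO_CM, CompartmentTree, discretize, generate_synthetic_tree


def cylinder_tree(length=1000.0, radius=2.0, step=5.0):
    """Unbranched cylinder with a dendritic (non-spherical) root."""
    n = int(length / step)
    ids = np.arange(1, n + 2)
    return CompartmentTree(
        ids=ids,
        parent_ids=np.r_[-1, ids[:-1]],
        type_codes=np.full(n + 1, 3),
        xyz=np.c_[np.linspace(0, length, n + 1), np.zeros(n + 1), np.zeros(n + 1)],
        radius=np.full(n + 1, radius),
    )


def sealed_cable_ratio(tree, frequency):
    """cosh((L-x)/lambda_c)/cosh(L/lambda_c) for the cylinder fixture."""
    x = tree.xyz[:, 0] * UM_TO_CM
    L = x.max()
    r_cm = tree.radius[0] * UM_TO_CM
    lam = np.sqrt((r_cm / 2.0) * tree.r_m / tree.r_a)
    tau = tree.r_m * tree.c_m * 1e-6  # seconds
    lam_c = lam / np.sqrt(1.0 + 1j * 2.0 * np.pi * frequency * tau)
    return np.cosh((L - x) / lam_c) / np.cosh(L / lam_c)


@pytest.mark.parametrize("frequency", [0.0, 250.0, 500.0])
def test_transfer_matches_sealed_cable_closed_form(frequency):
    tree = cylinder_tree()
    ratio = F.transfer_response(tree, 1, frequency)
    closed = sealed_cable_ratio(tree, frequency)
    rel = np.max(np.abs(ratio - closed) / np.abs(closed))
    assert rel < 1e-3


def test_zero_frequency_equals_real_dc_solve():
    tree = generate_synthetic_tree("symmetric_binary", seed=0)
    ac0 = F.transfer_response(tree, tree.soma_node, 0.0)
    assert np.max(np.abs(ac0.imag)) < 1e-10
    # independent real-valued check through the profile path
    prof = F.attenuation_profile(tree, F.SOMA_TO_DENDRITE, 0.0)
    np.testing.assert_allclose(prof.va, np.abs(ac0), atol=1e-10)
    np.testing.assert_allclose(prof.phase, 0.0, atol=1e-10)


def test_source_node_ratio_is_unity():
    tree = generate_synthetic_tree("random_taper", seed=1)
    ratio = F.transfer_response(tree, tree.soma_node, 250.0)
    k = tree.index_of(tree.soma_node)
    assert ratio[k] == pytest.approx(1.0 + 0.0j)


def test_transfer_impedance_reciprocity():
    tree = generate_synthetic_tree("random_taper", seed=3)
    lu = F.transfer_matrix_factor(tree, 250.0)
    n = tree.n_nodes
    Z = np.empty((n, n), complex)
    for k in range(n):
        e = np.zeros(n, complex)
        e[k] = 1.0
        Z[:, k] = lu.solve(e)
    assert np.max(np.abs(Z - Z.T)) / np.max(np.abs(Z)) < 1e-9


def test_low_pass_monotonicity_in_frequency_and_distance():
    tree = generate_synthetic_tree("ball_and_stick", {"length": 800.0}, seed=0)
    prof250 = F.attenuation_profile(tree, F.SOMA_TO_DENDRITE, 250.0)
    prof500 = F.attenuation_profile(tree, F.SOMA_TO_DENDRITE, 500.0)
    assert np.all(prof250.va >= prof500.va - 1e-12)
    order = np.argsort(prof250.d_path)
    assert np.all(np.diff(prof250.va[order]) <= 1e-12)


def test_phase_nonpositive_and_continuous():
    tree = generate_synthetic_tree("ball_and_stick", {"length": 1854.0}, seed=0)
    prof = F.attenuation_profile(tree, F.SOMA_TO_DENDRITE, 250.0)
    assert prof.phase.max() <= 1e-9
    order = np.argsort(prof.d_path)
    assert np.all(np.diff(prof.phase[order]) <= 1e-9)  # no unwrapping jumps


def test_direction_asymmetry_on_fixtures():
    """Soma-to-dendrite attenuation is milder than the reverse direction.

    Holds when the somatic input impedance is small relative to dendritic
    point impedances, as in motor neurons whose soma anchors many large
    dendrites -- emulated here by a large equivalent soma.  Exact at DC at
    every node; at 250 Hz the proximal ~100 um is excluded, where
    complex-impedance phase can invert the pointwise comparison.
    """
    tree = generate_synthetic_tree(
        "ball_and_stick", {"length": 1854.0, "soma_radius": 50.0}, seed=0
    )
    sd0 = F.attenuation_profile(tree, F.SOMA_TO_DENDRITE, 0.0)
    ds0 = F.attenuation_profile(tree, F.DENDRITE_TO_SOMA, 0.0)
    assert np.all(sd0.va >= ds0.va - 1e-12)
    sd = F.attenuation_profile(tree, F.SOMA_TO_DENDRITE, 250.0)
    ds = F.attenuation_profile(tree, F.DENDRITE_TO_SOMA, 250.0)
    distal = sd.d_path > 100.0
    assert np.all(sd.va[distal] >= ds.va[distal] - 1e-12)
    assert np.median(sd.va - ds.va) >= 0.0


def test_exponential_decay_fit_self_consistency():
    d = np.linspace(0, 1500, 40)
    fit = F.fit_exponential_decay(d_path=d, va=np.exp(-d / 420.1))
    assert fit.eta == pytest.approx(420.1, abs=1e-6)


@pytest.mark.parametrize(
    "eta, expected",
    [(420.1, 0.49), (225.0, 0.26)],  # AC soma->dendrite and DC dendrite->soma decay
)
def test_fitted_curve_evaluation_at_pic_distance(eta, expected):
    fit = F.DecayFit(eta=eta, residual=0.0)
    assert round(float(fit(300.0)), 2) == expected


def test_random_taper_profiles_admit_decay_fit():
    for seed in range(4):
        tree = generate_synthetic_tree("random_taper", seed=seed)
        prof = F.attenuation_profile(tree, F.SOMA_TO_DENDRITE, 250.0)
        fit = F.fit_exponential_decay(prof)
        assert fit.eta > 0


def test_phase_cubic_recovery_and_origin():
    coeffs = (6.8e-11, -9.2e-7, -0.0018)
    d = np.linspace(0, 1854, 60)
    phase = coeffs[0] * d**3 + coeffs[1] * d**2 + coeffs[2] * d
    fit = F.fit_phase_cubic(d_path=d, phase=phase)
    np.testing.assert_allclose(fit.coefficients, coeffs, rtol=1e-9, atol=1e-15)
    assert fit(0.0) == 0.0


def test_discretization_convergence_of_tip_attenuation():
    coarse = F.attenuation_profile(
        discretize(cylinder_tree(step=20.0), 20.0), F.SOMA_TO_DENDRITE, 250.0
    )
    fine = F.attenuation_profile(
        discretize(cylinder_tree(step=20.0), 1.0), F.SOMA_TO_DENDRITE, 250.0
    )
    tip_coarse = coarse.va[np.argmax(coarse.d_path)]
    tip_fine = fine.va[np.argmax(fine.d_path)]
    assert abs(tip_coarse - tip_fine) / tip_fine < 0.005


def test_nyquist_coordinates():
    x, y = F.nyquist_coords(1.0, 0.0)
    assert (x, y) == (1.0, 0.0)
    x, y = F.nyquist_coords(0.5, -np.pi / 2)
    assert x == pytest.approx(0.0, abs=1e-12)
    assert y == pytest.approx(-0.5)
    rng = np.random.default_rng(0)
    va, ph = rng.uniform(0, 1, 50), rng.uniform(-2 * np.pi, 0, 50)
    x, y = F.nyquist_coords(va, ph)
    np.testing.assert_allclose(x**2 + y**2, va**2, atol=1e-12)
    with pytest.raises(ValueError):
        F.nyquist_coords(-0.1, 0.0)
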