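"""Langmuir binding with Pol II tethering: identities, limits, simulations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from loopcontact import (
    BindingParameters,
    DomainError,
    EffectiveKinetics,
    PolIIKinetics,
    boltzmann_tether_factor,
    contact_scan_vs_linker,
    contact_scan_vs_rho,
    p_ini_steady,
    sigma_steady,
    sigma_timecourse,
    simulate_binding,
)

rate = st.floats(min_value=1e-2, max_value=1e2)
conc = st.floats(min_value=0.0, max_value=1e2)
energy = st.floats(min_value=0.0, max_value=10.0)


def test_p_ini_limits_and_value():
    assert p_ini_steady(PolIIKinetics(0.0, 1.0, 1.0, 1.0, 1.0)) == 0.0
    assert p_ini_steady(PolIIKinetics(2.0, 1.0, 1.0, 0.0, 1.0)) == 1.0
    # rho = 2 K_ini, lambda_ini = lambda_elo  ->  P_ini = 2/5
    kin = PolIIKinetics(rho=2.0, K_ini=1.0, lambda_ini=0.7, lambda_elo=0.7, epsilon=1.0)
    assert p_ini_steady(kin) == pytest.approx(2 / 5)


def test_p_ini_against_two_state_markov_simulation(rng):
    """Long-run initiation-state fraction of the jump process matches Eq-style
    steady state."""
    kin = PolIIKinetics(rho=2.0, K_ini=1.0, lambda_ini=0.9, lambda_elo=0.6, epsilon=1.0)
    on = kin.lambda_ini * kin.rho / (kin.rho + kin.K_ini)
    off = kin.lambda_elo
    t, state, t_in = 0.0, 0, 0.0
    t_end = 20000.0
    while t < t_end:
        dwell = rng.exponential(1.0 / (on if state == 0 else off))
        if state == 1:
            t_in += min(dwell, t_end - t)
        t += dwell
        state = 1 - state
    assert t_in / t_end == pytest.approx(p_ini_steady(kin), abs=0.01)


def test_tether_factor_limits():
    # lambda_elo -> 0: promoter almost always paused, factor -> e^-eps
    slow = PolIIKinetics(rho=3.0, K_ini=1.0, lambda_ini=1.0, lambda_elo=1e-9, epsilon=2.0)
    assert boltzmann_tether_factor(slow) == pytest.approx(math.exp(-2.0), rel=1e-6)
    # lambda_elo -> inf: initiation state never occupied, factor -> 1
    fast = PolIIKinetics(rho=3.0, K_ini=1.0, lambda_ini=1.0, lambda_elo=1e9, epsilon=2.0)
    assert boltzmann_tether_factor(fast) == pytest.approx(1.0, rel=1e-6)
    # eps = 0: no tethering energy
    free = PolIIKinetics(rho=3.0, K_ini=1.0, lambda_ini=1.0, lambda_elo=1.0, epsilon=0.0)
    assert boltzmann_tether_factor(free) == pytest.approx(1.0, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(rho=conc, K_ini=rate, lam_i=rate, lam_e=rate, eps=energy)
def test_tether_factor_identity(rho, K_ini, lam_i, lam_e, eps):
    """(alpha rho + K_elo)/(rho + K_elo) == 1 - P_ini (1 - e^-eps) identically."""
    kin = PolIIKinetics(rho, K_ini, lam_i, lam_e, eps)
    g = boltzmann_tether_factor(kin)
    assert g == pytest.approx(1.0 - p_ini_steady(kin) * (1.0 - math.exp(-eps)), abs=1e-12)
    assert math.exp(-eps) - 1e-12 <= kin.alpha_elo <= 1.0 + 1e-12


@settings(derandomize=True, max_examples=200)
@given(psi_a=st.floats(min_value=0.0, max_value=1.0), rho=conc, K_ini=rate,
       lam_i=rate, lam_e=rate, eps=energy)
def test_sigma_identity_and_bounds(psi_a, rho, K_ini, lam_i, lam_e, eps):
    kin = PolIIKinetics(rho, K_ini, lam_i, lam_e, eps)
    s = sigma_steady(psi_a, kin)
    assert 0.0 <= s <= 1.0
    if psi_a > 0:
        assert s == pytest.approx(psi_a / (psi_a + boltzmann_tether_factor(kin)), rel=1e-12)


def test_sigma_asymptotes():
    psi_a = 0.42
    big = EffectiveKinetics(alpha_elo=0.3, rho_over_K_elo=1e10)
    assert sigma_steady(psi_a, big) == pytest.approx(psi_a / (psi_a + 0.3), rel=1e-8)
    zero = EffectiveKinetics(alpha_elo=0.3, rho_over_K_elo=0.0)
    assert sigma_steady(psi_a, zero) == pytest.approx(psi_a / (1 + psi_a), rel=1e-12)
    assert sigma_steady(0.0, big) == 0.0


def test_sigma_unity_only_in_joint_limit():
    nearly = PolIIKinetics(rho=1e8, K_ini=1.0, lambda_ini=1.0, lambda_elo=1e-8, epsilon=30.0)
    assert sigma_steady(1.0, nearly) == pytest.approx(1.0, abs=1e-6)
    partial = PolIIKinetics(rho=1e8, K_ini=1.0, lambda_ini=1.0, lambda_elo=1.0, epsilon=30.0)
    assert sigma_steady(1.0, partial) < 0.9


def test_timecourse_endpoints_and_k0_independence():
    kin = EffectiveKinetics(alpha_elo=0.4, rho_over_K_elo=2.0)
    limits = []
    for k0 in (0.1, 1.0, 10.0):
        binding = BindingParameters(k0=k0, psi_a=0.25)
        assert sigma_timecourse(binding, kin, 0.0, sigma0=0.1) == pytest.approx(0.1)
        limits.append(sigma_timecourse(binding, kin, 1e6, sigma0=0.1))
    assert max(limits) - min(limits) < 1e-10
    assert limits[0] == pytest.approx(sigma_steady(0.25, kin), rel=1e-10)


def test_timecourse_matches_ode_integration():
    kin = EffectiveKinetics(alpha_elo=0.3, rho_over_K_elo=2.2)
    binding = BindingParameters(k0=0.8, psi_a=0.37)
    g = boltzmann_tether_factor(kin)
    t = np.linspace(0, 6.0, 40)
    sol = integrate.solve_ivp(
        lambda _, s: [binding.k0 * (1 - s[0]) * binding.psi_a - binding.k0 * g * s[0]],
        (0, t[-1]), [0.05], t_eval=t, rtol=1e-10, atol=1e-12,
    )
    np.testing.assert_allclose(sigma_timecourse(binding, kin, t, sigma0=0.05),
                               sol.y[0], rtol=1e-7, atol=1e-9)


def test_two_state_binding_simulation_consistent():
    kin = EffectiveKinetics(alpha_elo=0.3, rho_over_K_elo=2.2)
    binding = BindingParameters(k0=1.0, psi_a=0.3)
    est = simulate_binding(binding, kin, t_end=40000.0, seed=12)
    expected = sigma_steady(binding.psi_a, kin)
    # SE of a two-state time average ~ sqrt(2 p(1-p) tau_corr / T)
    g = boltzmann_tether_factor(kin)
    tau_corr = 1.0 / (binding.k0 * (binding.psi_a + g))
    se = math.sqrt(2 * expected * (1 - expected) * tau_corr / (0.8 * 40000.0))
    assert abs(est - expected) < 3 * se


def test_domain_errors():
    with pytest.raises(DomainError):
        sigma_steady(1.5, EffectiveKinetics(0.3, 1.0))
    with pytest.raises(DomainError):
        BindingParameters(k0=0.0, psi_a=0.5)
    with pytest.raises(DomainError):
        PolIIKinetics(rho=-1.0, K_ini=1.0, lambda_ini=1.0, lambda_elo=1.0, epsilon=0.0)
    with pytest.raises(DomainError):
        PolIIKinetics(rho=1.0, K_ini=1.0, lambda_ini=0.0, lambda_elo=0.0, epsilon=0.0).K_elo


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_linker_scan_columns_and_qualitative_shape():
    df = contact_scan_vs_linker(np.geomspace(0.3, 30, 7))
    assert list(df.columns) == [
        "ratio", "psi_a_active", "psi_a_equilibrium", "sigma_active", "sigma_equilibrium",
    ]
    se = df["sigma_equilibrium"].to_numpy()
    sa = df["sigma_active"].to_numpy()
    assert np.all(np.diff(se) < 0)
    assert sa[-1] > sa.min()
    assert np.all((0 <= sa) & (sa <= 1))


def test_rho_scan_monotone_and_flat_cases():
    rho = np.linspace(0.0, 8.0, 9)
    df = contact_scan_vs_rho(rho, ratios=(1.0,), t0_coefficient=20.0)
    s = df["sigma"].to_numpy()
    assert np.all(np.diff(s) > 0)  # alpha_elo < 1: sigma grows with Pol II level
    psi_a = df["psi_a"].iloc[0]
    assert s[-1] < psi_a / (psi_a + 0.3)  # below the large-rho plateau
    flat = contact_scan_vs_rho(rho, ratios=(1.0,), alpha_elo=1.0, t0_coefficient=20.0)
    fs = flat["sigma"].to_numpy()
    np.testing.assert_allclose(fs, fs[0], rtol=1e-12)  # eps = 0: no rho dependence
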