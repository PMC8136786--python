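"""Moment-closure dynamics of r(t) and the cycle-averaged zone probability."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from loopcontact import (
    ChainParameters,
    DomainError,
    ExtrusionSchedule,
    equilibrium_reaction_zone_probability,
    mean_square_distance,
    reaction_zone_probability,
    relaxation_factor_ode,
)


def test_early_time_slope(make_schedule):
    """r(t) ~ t / (tau_N0 + tau_ex) as t -> 0+."""
    sched = make_schedule(0.1)
    dist = relaxation_factor_ode(sched)
    t = 1e-4 * min(sched.tau_ex, sched.chain.tau_N0)
    assert dist.r_of(t) == pytest.approx(t / (sched.chain.tau_N0 + sched.tau_ex), rel=1e-2)
    assert dist.r_of(0.0) == 0.0


def test_pure_relaxation_recovers_equilibrium(chain32):
    """With t0 -> infinity the factor r climbs monotonically to 1."""
    sched = ExtrusionSchedule(chain=chain32, tau_m=0.1 * chain32.tau_N0 / chain32.N0, t0=math.inf)
    t_end = 100.0 * chain32.tau_N0
    dist = relaxation_factor_ode(sched, t_end=t_end)
    t = np.geomspace(1e-5 * chain32.tau_N0, t_end, 400)
    r = dist.r_of(t)
    assert np.all(np.diff(r) >= -1e-10)
    assert r[-1] == pytest.approx(1.0, abs=1e-2)


def test_quasi_static_limit(chain32):
    """For tau_N0 << t the factor tracks l^2(t)/l_eq^2 = (t/tau_ex)/(1+t/tau_ex)."""
    sched = ExtrusionSchedule(chain=chain32, tau_m=100.0 * chain32.tau_N0 / chain32.N0,
                              t0=300.0 * chain32.tau_N0)
    dist = relaxation_factor_ode(sched, t_end=sched.t0)
    for frac in (0.1, 0.5, 0.9):
        t = frac * sched.t0
        expected = (t / sched.tau_ex) / (1 + t / sched.tau_ex)
        assert dist.r_of(t) == pytest.approx(expected, rel=1e-2)


def test_cycle_end_returns_near_surface():
    """Fast extrusion (tau_ex >= tau_N0) drags the promoter back to z ~ 0."""
    chain = ChainParameters(N0=100.0)
    sched = ExtrusionSchedule(chain=chain, tau_m=2.0 * chain.tau_N0 / chain.N0,
                              t0=4.0 * chain.tau_N0)
    dist = relaxation_factor_ode(sched)
    assert dist.r_of(sched.period) < 0.05


def test_r_continuous_across_handoff(make_schedule):
    sched = make_schedule(0.3)
    dist = relaxation_factor_ode(sched)
    eps = 1e-8 * sched.tau_ex
    assert abs(dist.r_of(sched.t0 - eps) - dist.r_of(sched.t0 + eps)) < 1e-6


def test_psi_normalized_at_random_cycle_times(make_schedule, rng):
    sched = make_schedule(0.1)
    dist = relaxation_factor_ode(sched)
    l_eq = sched.chain.l_eq
    for t in rng.uniform(0.01, 1.0, 20) * sched.period:
        norm, _ = integrate.quad(lambda z: dist.psi(z, t), 0, 12 * l_eq, limit=200)
        assert norm == pytest.approx(1.0, abs=1e-8)


def test_msd_endpoints_and_plateau(chain32, make_schedule):
    sched = make_schedule(0.01, t0_over_tau_N0=8.0)
    dist = relaxation_factor_ode(sched)
    assert mean_square_distance(dist, 0.0) == 0.0
    # long relaxation plateau near N0 b^2
    plateau = mean_square_distance(dist, sched.t0)
    assert plateau == pytest.approx(chain32.N0 * chain32.b**2, rel=0.02)
    with pytest.raises(DomainError):
        mean_square_distance(dist, 10 * sched.period)


def test_slow_extrusion_leaves_promoter_untouched_then_drops(make_schedule):
    """tau_ex/tau_N0 = 0.01: <z^2> barely moves for most of the extrusion."""
    sched = make_schedule(0.01, t0_over_tau_N0=8.0)
    dist = relaxation_factor_ode(sched)
    r_start = dist.r_of(sched.t0)
    r_mid = dist.r_of(sched.t0 + 0.9 * sched.tau_ex)
    assert r_mid > 0.93 * r_start
    # contrast: fast extrusion declines roughly linearly from the start
    fast = make_schedule(10.0, t0_over_tau_N0=12.0)
    dfast = relaxation_factor_ode(fast)
    drop_half = dfast.r_of(fast.t0 + 0.5 * fast.tau_ex) / dfast.r_of(fast.t0)
    assert drop_half < 0.85


@pytest.mark.parametrize("ratio, exponent", [(0.1, 0.1), (4.0, 1.0)])
def test_terminal_collapse_exponent(ratio, exponent):
    """Near full extrusion <z^2> ~ (tau_ex - t')^min(1, tau_ex/tau_N0)."""
    chain = ChainParameters(N0=200.0)
    sched = ExtrusionSchedule(chain=chain, tau_m=ratio * chain.tau_N0 / chain.N0,
                              t0=max(2.0, 2.0 * ratio) * chain.tau_N0)
    dist = relaxation_factor_ode(sched)
    u = np.geomspace(6e-3, 2e-2, 12) * sched.tau_ex
    r = dist.r_of(sched.period - u)
    slope = stats.linregress(np.log(u), np.log(r)).slope
    assert slope == pytest.approx(exponent, rel=0.10)


def test_active_extrusion_concentrates_mass_near_surface(make_schedule):
    """r(t) < 1 throughout the cycle implies Psi_a(active) >= Psi_a(equilibrium)."""
    sched = make_schedule(0.1, t0_over_tau_N0=0.2)
    dist = relaxation_factor_ode(sched)
    a = 0.4 * sched.chain.l_eq
    active = reaction_zone_probability(dist, a)
    equil = equilibrium_reaction_zone_probability(a, sched.chain.l_eq)
    assert active >= equil
    # full-support limit
    assert reaction_zone_probability(dist, 100 * sched.chain.l_eq) == pytest.approx(1.0, abs=1e-6)


def test_zone_probability_domain_checks(make_schedule):
    dist = relaxation_factor_ode(make_schedule(0.1))
    with pytest.raises(DomainError):
        reaction_zone_probability(dist, -1.0)
    with pytest.raises(DomainError):
        equilibrium_reaction_zone_probability(1.0, 0.0)


def test_grid_validation(make_schedule):
    sched = make_schedule(0.1)
    with pytest.raises(DomainError):
        relaxation_factor_ode(sched, grid=np.array([0.5, 0.1]))
    with pytest.raises(DomainError):
        relaxation_factor_ode(sched, grid=np.array([0.0, 2.0 * sched.period]))
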