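"""Moment-closure dynamics of the promoter height over one extrusion cycle.

The Smoluchowski equation for the promoter height with the time-dependent
local-equilibrium potential is the radial Fokker-Planck equation of a 3-D
isotropic Ornstein-Uhlenbeck process with stiffness ``kB T / l^2(t)`` and
diffusivity ``D = kB T / (N0 zeta0)``.  That process preserves the
radial-Gaussian family, so the full density is carried by a single scalar, the
relaxation factor ``r(t) = <z^2> / (3 l_eq^2)``, which obeys the exact
first-moment equation

    dr/dt = (1 / tau_N0) * (1 - r * l_eq^2 / l^2(t)),      r(0) = 0,

with ``tau_N0 = N0^2 tau1`` the Rouse relaxation time.  The closure is exact
for this family; it is validated numerically against the finite-difference
solver (:mod:`loopcontact.fp`) and the Brownian-dynamics ensemble
(:mod:`loopcontact.bd`).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

from .distribution import PromoterDistribution, radial_gaussian_cdf
from .exceptions import DomainError, NumericsError
from .schedule import ExtrusionSchedule, cycle_time_grid

__all__ = [
    "relaxation_factor_ode",
    "mean_square_distance",
    "reaction_zone_probability",
    "equilibrium_reaction_zone_probability",
]


def relaxation_factor_ode(
    schedule: ExtrusionSchedule,
    *,
    t_end: float | None = None,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> PromoterDistribution:
    """Integrate the moment ODE for ``r(t)`` over one cycle.

    The coefficient ``l_eq^2 / l^2(t)`` diverges like ``tau_ex / t`` at the
    singular start, where the exact leading-order solution is
    ``r(t) = t / (tau_N0 + tau_ex)``; integration starts from that series at
    ``t_min = 1e-6 min(tau_ex, tau_N0)`` and the returned ``r`` is extended
    linearly below ``t_min``.  The stiff endpoint (``l^2 -> 0`` as
    ``t' -> tau_ex``) is handled by the schedule's arm-count floor and LSODA's
    automatic stiff switching.
    """
    chain = schedule.chain
    tau_N0 = chain.tau_N0
    tau_ex = schedule.tau_ex
    l_eq_sq = chain.l_eq_sq
    if t_end is None:
        if not math.isfinite(schedule.period):
            raise DomainError("t_end required for an infinite-period schedule")
        t_end = schedule.period
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise DomainError("grid must be strictly increasing with >= 2 points")
        if grid[0] < 0 or grid[-1] > t_end * (1 + 1e-12):
            raise DomainError("grid must lie within [0, t_end]")

    t_min = 1e-6 * min(tau_ex, tau_N0, t_end)
    r0 = t_min / (tau_N0 + tau_ex)

    def rhs(t, r):
        l2 = float(schedule.l2_of_t(min(t, t_end)))
        return [(1.0 - r[0] * l_eq_sq / l2) / tau_N0]

    sol = integrate.solve_ivp(
        rhs,
        (t_min, t_end),
        [r0],
        method="LSODA",
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericsError(f"moment ODE integration failed: {sol.message}")

    def r_of_t(t):
        t = np.asarray(t, dtype=float)
        early = t / (tau_N0 + tau_ex)
        late = sol.sol(np.clip(t, t_min, t_end))[0]
        return np.where(t < t_min, early, np.clip(late, 0.0, None))

    if grid is None:
        grid = cycle_time_grid(schedule, t_end=t_end) if math.isfinite(t_end) else np.array([t_min, t_end])
    return PromoterDistribution(l_eq_sq=l_eq_sq, r=r_of_t, grid=grid, schedule=schedule)


def mean_square_distance(dist: PromoterDistribution, t):
    """Mean-square promoter-surface distance ``<z^2>(t) = 3 l_eq^2 r(t)``."""
    t = np.asarray(t, dtype=float)
    if dist.grid.size and (np.any(t < 0) or np.any(t > dist.grid[-1] * (1 + 1e-12))):
        raise DomainError("t outside the evaluated range")
    return dist.msd(t)


def reaction_zone_probability(dist: PromoterDistribution, a: float) -> float:
    """Cycle-averaged probability ``Psi_a`` that the promoter is within ``z < a``.

    Because the cycle resets to ``psi = delta(z)`` each period, the long-time
    average reduces to a single-period average of the closed-form zone mass
    ``F(a; r(t))``, evaluated here by adaptive quadrature in time (no nested
    z-integration).
    """
    if not a > 0:
        raise DomainError("a must be positive")
    if dist.schedule is None or not math.isfinite(dist.schedule.period):
        raise DomainError("reaction_zone_probability needs a finite-period schedule")
    period = dist.schedule.period
    t0 = dist.schedule.t0

    def f(t):
        return radial_gaussian_cdf(a, dist.l_eq_sq * dist.r_of(t))

    points = [t for t in (t0,) if 0.0 < t < period]
    val, err = integrate.quad(f, 0.0, period, points=points or None, limit=400)
    if err / period > 1e-7 + 1e-6 * (val / period):
        raise NumericsError(f"cycle-average quadrature error {err:.2e} too large")
    return val / period


def equilibrium_reaction_zone_probability(a: float, l_eq: float) -> float:
    """Zone probability with extrusion inhibited: ``F(a; r = 1)`` in closed form."""
    if not a > 0:
        raise DomainError("a must be positive")
    if not l_eq > 0:
        raise DomainError("l_eq must be positive")
    return float(radial_gaussian_cdf(a, l_eq * l_eq))
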