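"""Promoter-condensate binding kinetics with Pol II initiation-state tethering.

The bound fraction sigma(t) of promoters obeys a Langmuir-type rate equation

    d sigma/dt = k0 (1 - sigma) Psi_a - k0 <e^{-n eps}>_n sigma,

where ``Psi_a`` is the cycle-averaged probability that the promoter sits in
the reaction zone and the Boltzmann factor ``<e^{-n eps}>_n`` (n in {0, 1}:
at most one Pol II per promoter) lowers the unbinding rate when a paused
(initiation-state) Pol II tethers the promoter to the condensate.  The
initiation-state occupancy follows a two-state kinetic scheme with Pol II
binding equilibrium ``K_ini``, entry rate ``lambda_ini`` and escape-to-
elongation rate ``lambda_elo``; its steady state yields

    <e^{-n eps}>_n = (alpha_elo rho + K_elo) / (rho + K_elo)
                   = 1 - P_ini (1 - e^{-eps}),

with ``K_elo = lambda_elo K_ini / (lambda_elo + lambda_ini)`` and
``alpha_elo = (lambda_elo + lambda_ini e^{-eps}) / (lambda_elo + lambda_ini)``.
The steady-state contact probability is then independent of k0:

    sigma = Psi_a (rho + K_elo) / ((Psi_a + alpha_elo) rho + (1 + Psi_a) K_elo)
          = Psi_a / (Psi_a + <e^{-n eps}>_n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import (
    equilibrium_reaction_zone_probability,
    reaction_zone_probability,
    relaxation_factor_ode,
)
from .exceptions import DomainError, NumericsError
from .params import ChainParameters, reaction_zone_from_dimensionless
from .schedule import ExtrusionSchedule

__all__ = [
    "PolIIKinetics",
    "EffectiveKinetics",
    "BindingParameters",
    "p_ini_steady",
    "boltzmann_tether_factor",
    "sigma_steady",
    "sigma_timecourse",
    "simulate_binding",
    "contact_scan_vs_linker",
    "contact_scan_vs_rho",
]


@dataclass(frozen=True)
class PolIIKinetics:
    """Microscopic Pol II parameters.

    rho: Pol II concentration in the condensate (in units of K_ini / K_elo;
    only ratios enter the theory).  K_ini: promoter binding equilibrium
    constant.  lambda_ini / lambda_elo: rates into the initiation and
    elongation states (1/s).  epsilon: Pol II-condensate binding energy in
    kB T units.
    """

    rho: float
    K_ini: float
    lambda_ini: float
    lambda_elo: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in ("rho", "K_ini", "lambda_ini", "lambda_elo"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def K_elo(self) -> float:
        lam = self.lambda_elo + self.lambda_ini
        if lam == 0:
            raise DomainError("lambda_elo + lambda_ini must be positive")
        return self.lambda_elo * self.K_ini / lam

    @property
    def alpha_elo(self) -> float:
        lam = self.lambda_elo + self.lambda_ini
        if lam == 0:
            raise DomainError("lambda_elo + lambda_ini must be positive")
        return (self.lambda_elo + self.lambda_ini * math.exp(-self.epsilon)) / lam


@dataclass(frozen=True)
class EffectiveKinetics:
    """Effective parameterization used by the figure-style scans.

    Only ``alpha_elo`` and the ratio ``rho / K_elo`` enter the steady-state
    contact probability; the microscopic triple realizing a given
    ``alpha_elo`` is underdetermined, so scans accept it directly.
    """

    alpha_elo: float
    rho_over_K_elo: float

    def __post_init__(self) -> None:
        if self.rho_over_K_elo < 0:
            raise DomainError("rho_over_K_elo must be non-negative")
        if not 0 <= self.alpha_elo <= 1:
            raise DomainError("alpha_elo must lie in [0, 1]")

    @property
    def rho(self) -> float:
        return self.rho_over_K_elo

    @property
    def K_elo(self) -> float:
        return 1.0


@dataclass(frozen=True)
class BindingParameters:
    """Rate constant and zone probability entering the Langmuir equation."""

    k0: float
    psi_a: float

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise DomainError("k0 must be positive")
        if not 0.0 <= self.psi_a <= 1.0:
            raise DomainError("psi_a must lie in [0, 1]")


def p_ini_steady(kin: PolIIKinetics) -> float:
    """Steady-state probability the promoter holds an initiation-state Pol II."""
    on = kin.lambda_ini * kin.rho / (kin.rho + kin.K_ini) if kin.rho > 0 else 0.0
    if kin.rho > 0 and kin.rho + kin.K_ini == 0:
        raise DomainError("rho + K_ini must be positive")
    denom = on + kin.lambda_elo
    if denom == 0:
        if on == 0 and kin.rho == 0:
            return 0.0
        raise DomainError("degenerate kinetics: no exit from the initiation state")
    return on / denom


def boltzmann_tether_factor(kin) -> float:
    """Tethering factor ``<e^{-n eps}>_n = (alpha_elo rho + K_elo)/(rho + K_elo)``.

    For a microscopic :class:`PolIIKinetics` the identity
    ``1 - P_ini (1 - e^{-eps})`` is verified internally to machine precision.
    """
    denom = kin.rho + kin.K_elo
    if denom == 0:
        raise DomainError("rho + K_elo must be positive")
    g = (kin.alpha_elo * kin.rho + kin.K_elo) / denom
    if isinstance(kin, PolIIKinetics):
        via_p_ini = 1.0 - p_ini_steady(kin) * (1.0 - math.exp(-kin.epsilon))
        if not math.isclose(g, via_p_ini, rel_tol=1e-12, abs_tol=1e-12):
            raise NumericsError(
                f"tether-factor identity violated: {g!r} vs {via_p_ini!r}"
            )
    return g


def sigma_steady(psi_a: float, kin) -> float:
    """Steady-state contact probability sigma (independent of k0)."""
    if not 0.0 <= psi_a <= 1.0:
        raise DomainError("psi_a must lie in [0, 1]")
    if psi_a == 0.0:
        return 0.0
    rho, K = kin.rho, kin.K_elo
    sigma = psi_a * (rho + K) / ((psi_a + kin.alpha_elo) * rho + (1.0 + psi_a) * K)
    g = boltzmann_tether_factor(kin)
    alt = psi_a / (psi_a + g)
    if not math.isclose(sigma, alt, rel_tol=1e-12, abs_tol=1e-15):
        raise NumericsError(f"sigma identity violated: {sigma!r} vs {alt!r}")
    return sigma


def sigma_timecourse(binding: BindingParameters, kin, t, sigma0: float = 0.0):
    """Closed-form relaxation of the bound fraction.

    ``sigma(t) = sigma_ss + (sigma0 - sigma_ss) exp(-k0 (Psi_a + g) t)`` with
    ``g`` the tether factor; the relaxation rate carries the only k0
    dependence, the plateau does not.
    """
    if not 0.0 <= sigma0 <= 1.0:
        raise DomainError("sigma0 must lie in [0, 1]")
    g = boltzmann_tether_factor(kin)
    s_ss = binding.psi_a / (binding.psi_a + g) if binding.psi_a > 0 else 0.0
    t = np.asarray(t, dtype=float)
    out = s_ss + (sigma0 - s_ss) * np.exp(-binding.k0 * (binding.psi_a + g) * t)
    return out if out.ndim else float(out)


def simulate_binding(
    binding: BindingParameters, kin, t_end: float, seed: int, burn_frac: float = 0.2
) -> float:
    """Continuous-time two-state (bound/unbound) simulation of Eq. (12)'s jump
    process; returns the time-averaged bound fraction after a burn-in."""
    g = boltzmann_tether_factor(kin)
    k_on = binding.k0 * binding.psi_a
    k_off = binding.k0 * g
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    t, bound = 0.0, False
    t_burn = burn_frac * t_end
    bound_time = 0.0
    while t < t_end:
        rate = k_off if bound else k_on
        if rate == 0:
            dwell = t_end - t
        else:
            dwell = rng.exponential(1.0 / rate)
        t_next = min(t + dwell, t_end)
        if bound:
            bound_time += max(0.0, t_next - max(t, t_burn))
        t = t_next
        bound = not bound
    return bound_time / (t_end - t_burn)


def _schedule_for_ratio(
    ratio: float, chi: float, t0_coefficient: float, N0: float, Ns: float
) -> tuple[ExtrusionSchedule, float]:
    """Dimensionless (b = tau1 = 1) schedule realizing tau_N0/tau_ex = ratio.

    Every quantity in the scans depends on N0 only through the ratio:
    a^2/l_eq^2 = 1/(chi ratio) and t0/tau_N0 = t0_coefficient/ratio^2.
    """
    tau_m = N0 / ratio
    a = reaction_zone_from_dimensionless(chi, tau_m, 1.0, 1.0)
    chain = ChainParameters(N0=N0, b=1.0, Ns=Ns, tau1=1.0, a=a)
    tau_ex = N0 * tau_m
    t0 = t0_coefficient * tau_ex**2 / chain.tau_N0
    return ExtrusionSchedule(chain=chain, tau_m=tau_m, t0=t0), a


def contact_scan_vs_linker(
    ratios,
    *,
    chi: float = 5.0,
    t0_coefficient: float = 10.0,
    alpha_elo: float = 0.3,
    rho_over_K_elo: float = 2.2,
    N0: float = 50.0,
    Ns: float = 1.0,
) -> pd.DataFrame:
    """Contact probability vs linker length (as the ratio tau_N0/tau_ex).

    For each ratio the zone probability is computed twice -- over the active
    extrusion cycle and for the equilibrium distribution (extrusion
    inhibited) -- and converted to sigma with the effective kinetics.  The
    loading time follows ``t0 tau_N0 / tau_ex^2 = t0_coefficient`` and the
    reaction zone ``2 kB T tau_m / (zeta0 a^2) = chi``, both of which are
    independent of N0; the ratio itself is proportional to N0.
    """
    kin = EffectiveKinetics(alpha_elo=alpha_elo, rho_over_K_elo=rho_over_K_elo)
    rows = []
    for ratio in np.atleast_1d(np.asarray(ratios, dtype=float)):
        if not ratio > 0:
            raise DomainError("ratios must be positive")
        schedule, a = _schedule_for_ratio(ratio, chi, t0_coefficient, N0, Ns)
        dist = relaxation_factor_ode(schedule)
        psi_active = reaction_zone_probability(dist, a)
        psi_eq = equilibrium_reaction_zone_probability(a, schedule.chain.l_eq)
        rows.append(
            {
                "ratio": float(ratio),
                "psi_a_active": psi_active,
                "psi_a_equilibrium": psi_eq,
                "sigma_active": sigma_steady(psi_active, kin),
                "sigma_equilibrium": sigma_steady(psi_eq, kin),
            }
        )
    return pd.DataFrame(rows)


def contact_scan_vs_rho(
    rho_over_K_elo,
    *,
    ratios=(1.0, 10.0, 20.0),
    chi: float = 5.0,
    t0_coefficient: float = 20.0,
    alpha_elo: float = 0.3,
    N0: float = 50.0,
    Ns: float = 1.0,
) -> pd.DataFrame:
    """Contact probability vs Pol II concentration (rho / K_elo) for several
    linker-length ratios; monotone increasing whenever alpha_elo < 1."""
    rho_vals = np.atleast_1d(np.asarray(rho_over_K_elo, dtype=float))
    if np.any(rho_vals < 0):
        raise DomainError("rho_over_K_elo must be non-negative")
    rows = []
    for ratio in ratios:
        schedule, a = _schedule_for_ratio(float(ratio), chi, t0_coefficient, N0, Ns)
        dist = relaxation_factor_ode(schedule)
        psi_active = reaction_zone_probability(dist, a)
        for rho in rho_vals:
            kin = EffectiveKinetics(alpha_elo=alpha_elo, rho_over_K_elo=float(rho))
            rows.append(
                {
                    "ratio": float(ratio),
                    "rho_over_K_elo": float(rho),
                    "psi_a": psi_active,
                    "sigma": sigma_steady(psi_active, kin),
                }
            )
    return pd.DataFrame(rows)
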