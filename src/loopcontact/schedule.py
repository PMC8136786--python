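"""Deterministic extrusion/relaxation cycle of cohesin on the linker.

Time zero is the instant at which a cohesin has just extruded the entire
linker into its loop, so the promoter sits at the condensate surface,
``psi(z, 0) = delta(z)``.  The cycle then consists of

* a relaxation process ``0 <= t <= t0`` during which the arm count stays
  ``N(t) = N0`` while the loop built by the previous cohesin keeps growing,
  ``Np(t) = N0 (1 + t / tau_ex)``, and
* a loop-extrusion process ``t0 <= t <= t0 + tau_ex`` (``t' = t - t0``)
  during which a newly loaded cohesin shrinks the arm,
  ``N(t') = N0 (1 - t'/tau_ex)``, dragging the promoter back to the surface.

The promoter-height statistics depend on the schedule only through the local
mean-square parameter ``l^2(t) = N (Np - N) b^2 / (3 Np)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, NumericsError
from .params import ChainParameters

__all__ = ["ExtrusionSchedule", "local_msd_parameter", "cycle_time_grid"]


def local_msd_parameter(N, Np, b: float = 1.0):
    """Local-equilibrium variance parameter ``l^2 = N (Np - N) b^2 / (3 Np)``.

    ``N`` is the arm count (units between promoter and enhancer outside the
    loop) and ``Np`` the loop count; the subchain-in-a-loop variance vanishes
    when the arm is fully extruded (``N = Np`` or ``N = 0``) and recovers the
    equilibrium ``l_eq^2 = N0 b^2 / 3`` in the limit ``N = N0``, ``Np -> inf``.
    """
    N = np.asarray(N, dtype=float)
    Np = np.asarray(Np, dtype=float)
    if np.any(Np <= 0):
        raise DomainError("Np must be positive")
    if np.any(N < 0) or np.any(N > Np):
        raise DomainError("require 0 <= N <= Np")
    out = N * (Np - N) * b * b / (3.0 * Np)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ExtrusionSchedule:
    """One period of the cohesin loading/extrusion cycle.

    Parameters
    ----------
    chain : ChainParameters
    tau_m : float
        Time to translocate one Kuhn unit; ``tau_ex = N0 tau_m``.
    t0 : float
        Cohesin loading time (identified with ``tau_on``); may be
        ``math.inf`` to study the pure relaxation process.
    multiple_cohesins : bool
        Alternative schedule with several cohesins on the linker:
        ``Np = N0 t0 / tau_ex`` constant and ``N(t) = N0 (t0 - t)/tau_ex``
        over a period ``t0``.  Off by default.
    """

    chain: ChainParameters
    tau_m: float
    t0: float
    multiple_cohesins: bool = False

    def __post_init__(self) -> None:
        if not self.tau_m > 0:
            raise DomainError("tau_m must be positive")
        if not self.t0 > 0:
            raise DomainError("t0 must be positive")
        if not self.multiple_cohesins and math.isfinite(self.t0) and self.tau_ex >= self.t0:
            warnings.warn(
                f"tau_ex = {self.tau_ex:.3g} >= t0 = {self.t0:.3g}: outside the "
                "regime tau_ex < tau_on assumed by the theory",
                stacklevel=2,
            )

    @property
    def tau_ex(self) -> float:
        return self.chain.N0 * self.tau_m

    @property
    def period(self) -> float:
        return self.t0 if self.multiple_cohesins else self.t0 + self.tau_ex

    @property
    def N_floor(self) -> float:
        """Smallest physical arm count: the promoter itself spans Ns units."""
        return min(max(self.chain.Ns, 1.0), self.chain.N0)

    @property
    def l2_floor(self) -> float:
        """Variance floor used by the stiff-endpoint regularization."""
        if not math.isfinite(self.period):
            # pure relaxation: the arm never shrinks; Np -> inf limit
            return self.N_floor * self.chain.b**2 / 3.0
        Np_end = self.Np_of_t(self.period)
        return local_msd_parameter(self.N_floor, max(Np_end, 2.0 * self.N_floor), self.chain.b)

    def _check_range(self, t: np.ndarray) -> None:
        if np.any(t < -1e-9 * self.tau_ex) or (
            math.isfinite(self.period) and np.any(t > self.period * (1 + 1e-12) + 1e-9)
        ):
            raise DomainError("t outside the cycle [0, period]")

    def N_of_t(self, t):
        """Arm count N(t) (units not yet extruded by the current cohesin)."""
        t = np.asarray(t, dtype=float)
        self._check_range(t)
        N0 = self.chain.N0
        if self.multiple_cohesins:
            N = N0 * (self.t0 - t) / self.tau_ex
            N = np.clip(N, 0.0, self.Np_of_t(t))
        else:
            N = np.where(t <= self.t0, N0, N0 * (1.0 - (t - self.t0) / self.tau_ex))
            N = np.clip(N, 0.0, N0)
        return N if N.ndim else float(N)

    def Np_of_t(self, t):
        """Loop count Np(t) of the loop containing the linker."""
        t = np.asarray(t, dtype=float)
        self._check_range(t)
        N0 = self.chain.N0
        if self.multiple_cohesins:
            Np = np.full_like(t, N0 * self.t0 / self.tau_ex)
        else:
            Np = N0 * (1.0 + t / self.tau_ex)
        return Np if Np.ndim else float(Np)

    def l2_of_t(self, t, floor: bool = True):
        """Variance parameter ``l^2(t)``, optionally floored near full extrusion.

        Flooring clips the arm count from below at ``N_floor`` so the
        promoter's own ``Ns`` units keep the variance finite as
        ``t -> t0 + tau_ex``.
        """
        t = np.asarray(t, dtype=float)
        N = np.asarray(self.N_of_t(t), dtype=float)
        Np = np.asarray(self.Np_of_t(t), dtype=float)
        if floor:
            N = np.clip(N, self.N_floor, Np)
        out = local_msd_parameter(N, Np, self.chain.b)
        return out


def cycle_time_grid(
    schedule: ExtrusionSchedule,
    *,
    beta: float = 0.05,
    alpha: float = 0.02,
    n_cap: int = 1000,
    t_start: float | None = None,
    t_end: float | None = None,
    max_steps: int = 2_000_000,
) -> np.ndarray:
    """Adaptive time grid resolving the stiff ends of one cycle.

    The step obeys ``dt <= min(span/n_cap, beta * l^2(t)/D, alpha * t)`` and,
    approaching ``t_end``, ``dt <= max(alpha * (t_end - t), beta * l2_floor/D)``
    so the grid refines geometrically both at the singular start (where
    ``l^2 ~ t``) and at the extrusion endpoint (where ``l^2 ~ t_end - t``),
    while terminating in a bounded number of steps.
    """
    if t_end is None:
        if not math.isfinite(schedule.period):
            raise DomainError("t_end required for an infinite-period schedule")
        t_end = schedule.period
    D = schedule.chain.diffusion
    if t_start is None:
        t_start = 1e-6 * min(schedule.tau_ex, schedule.chain.tau_N0, t_end)
    dt_cap = (t_end - t_start) / n_cap
    dt_floor = beta * schedule.l2_floor / D
    times = [t_start]
    t = t_start
    while t < t_end:
        dt = min(dt_cap, beta * float(schedule.l2_of_t(t)) / D, alpha * t)
        dt = min(dt, max(alpha * (t_end - t), dt_floor))
        t = min(t + dt, t_end)
        times.append(t)
        if len(times) > max_steps:
            raise NumericsError(
                f"cycle_time_grid exceeded {max_steps} steps; relax beta/alpha"
            )
    return np.asarray(times)
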