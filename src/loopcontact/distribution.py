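"""The promoter-height distribution family and derived quantities.

The promoter's height ``z`` above the condensate surface follows, at every
instant, the radial law of an isotropic 3-D Gaussian,

    psi(z; s2) = (4/sqrt(pi)) * z^2 / (2 s2)^{3/2} * exp(-z^2 / (2 s2)),

with variance parameter ``s2 = l_eq^2 r(t)``; the z^2 factor encodes the
repulsion of the linker from the condensate.  The relaxation factor ``r(t)``
is the mean-square height normalized by its equilibrium value,
``<z^2>(t) = 3 l_eq^2 r(t)``, with ``r = 1`` at equilibrium and ``r = 0`` the
delta function at the surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import special

from .exceptions import DegenerateDistributionError, DomainError
from .schedule import ExtrusionSchedule

__all__ = [
    "psi_family",
    "psi_eq",
    "radial_gaussian_cdf",
    "effective_potential",
    "PromoterDistribution",
]

_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


def psi_family(z, s2: float):
    """Density of the radial-Gaussian family with variance parameter ``s2``."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise DomainError("z must be non-negative")
    if not s2 > 0:
        raise DegenerateDistributionError(
            "variance parameter is zero: the distribution is a delta at the surface"
        )
    out = (4.0 / np.sqrt(np.pi)) * z * z / (2.0 * s2) ** 1.5 * np.exp(-z * z / (2.0 * s2))
    return out if out.ndim else float(out)


def psi_eq(z, l_eq: float):
    """Equilibrium height distribution (the family member with ``r = 1``)."""
    if not l_eq > 0:
        raise DomainError("l_eq must be positive")
    return psi_family(z, l_eq * l_eq)


def radial_gaussian_cdf(z, s2):
    """Closed-form mass below ``z``: ``erf(x) - (2/sqrt(pi)) x exp(-x^2)``,
    ``x = z / sqrt(2 s2)``.  Degenerate ``s2 = 0`` gives a unit step at 0."""
    z = np.asarray(z, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(z < 0):
        raise DomainError("z must be non-negative")
    if np.any(s2 < 0):
        raise DomainError("variance parameter must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(s2 > 0, z / np.sqrt(2.0 * s2), np.inf)
        x = np.where(z == 0, 0.0, x)
        out = np.where(
            np.isfinite(x),
            special.erf(x) - _TWO_OVER_SQRT_PI * np.where(np.isfinite(x), x, 0.0)
            * np.exp(-np.where(np.isfinite(x), x, 0.0) ** 2),
            1.0,
        )
    return out if out.ndim else float(out)


def effective_potential(z, l2: float):
    """Effective potential ``U_eff/kB T = -log psi_loc`` for the dumbbell.

    Equals ``z^2/(2 l^2) - 2 log z + const`` with the constant fixed by the
    normalization of the density itself (i.e. exactly ``-log psi_family``).
    Returns ``+inf`` at ``z = 0`` where the entropic ``-2 log z`` wall diverges.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise DomainError("z must be non-negative")
    if not l2 > 0:
        raise DegenerateDistributionError("l^2 must be positive")
    with np.errstate(divide="ignore"):
        logz = np.log(z)
    const = np.log((4.0 / np.sqrt(np.pi)) / (2.0 * l2) ** 1.5)
    out = z * z / (2.0 * l2) - 2.0 * logz - const
    out = np.where(z == 0, np.inf, out)
    return out if out.ndim else float(out)


@dataclass
class PromoterDistribution:
    """Time-dependent promoter-height distribution, parameterized by ``r(t)``.

    Attributes
    ----------
    l_eq_sq : float
        Equilibrium variance parameter ``l_eq^2 = N0 b^2 / 3``.
    r : callable
        Relaxation factor ``r(t) >= 0`` with ``r(0) = 0``.
    grid : ndarray
        Monotone evaluation times covering the solved span.
    schedule : ExtrusionSchedule, optional
        The driving schedule (needed for cycle averages).
    """

    l_eq_sq: float
    r: Callable[[np.ndarray], np.ndarray]
    grid: np.ndarray = field(default_factory=lambda: np.array([]))
    schedule: Optional[ExtrusionSchedule] = None

    def r_of(self, t):
        out = np.clip(np.asarray(self.r(np.asarray(t, dtype=float)), dtype=float), 0.0, None)
        return out if out.ndim else float(out)

    def msd(self, t):
        """Mean-square promoter height ``<z^2>(t) = 3 l_eq^2 r(t)``."""
        return 3.0 * self.l_eq_sq * self.r_of(t)

    def psi(self, z, t: float):
        """Density ``psi(z, t)``; raises for the degenerate ``r = 0`` case."""
        return psi_family(z, self.l_eq_sq * self.r_of(t))

    def zone_mass(self, a: float, t):
        """Probability mass inside the reaction zone ``0 < z < a`` at time t."""
        if not a > 0:
            raise DomainError("a must be positive")
        return radial_gaussian_cdf(a, self.l_eq_sq * np.asarray(self.r_of(t)))
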