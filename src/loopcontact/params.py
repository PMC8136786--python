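"""Chain and time-scale parameters, and estimators tying them to measurables.

The linker chromatin between an enhancer (anchored at a transcriptional
condensate) and its target promoter is modelled as an ideal (Rouse) chain of
``N0`` Kuhn units of length ``b``.  A single unit carries a genomic content of
``kb_per_unit`` kilobases and relaxes on the friction time scale
``tau1 = zeta0 * b**2 / (6 kB T)``.  The promoter occupies ``Ns`` units and can
bind the condensate surface when it sits inside a reaction zone of thickness
``a``.

Internally all formulas are written so that choosing ``b = 1`` and ``tau1 = 1``
yields the dimensionless convention used throughout the dynamic modules:
lengths in units of ``b``, times in units of ``tau1``, which removes ``kB T``
and ``zeta0`` from the numerics (``D = b**2 / (6 N0 tau1)``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import DomainError

__all__ = [
    "ChainParameters",
    "TimeScales",
    "kuhn_units_from_genomic_length",
    "equilibrium_size",
    "relaxation_time",
    "tau1_from_msd_prefactor",
    "tau_m_from_extrusion_speed",
    "reaction_zone_from_dimensionless",
    "dimensionless_from_reaction_zone",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise DomainError(f"{name} must be positive, got {value!r}")


def kuhn_units_from_genomic_length(length_kb: float, kb_per_unit: float = 1.65) -> float:
    """Number of Kuhn units N0 in a linker of ``length_kb`` kilobases.

    Fractional values are allowed: the continuum theory treats unit counts as
    continuous.
    """
    _check_positive(length_kb=length_kb, kb_per_unit=kb_per_unit)
    return length_kb / kb_per_unit


def equilibrium_size(N0: float, b: float) -> float:
    """Equilibrium length scale ``l_eq = sqrt(N0 b^2 / 3)``.

    The equilibrium mean-square promoter height is ``<z^2> = 3 l_eq^2 = N0 b^2``.
    """
    _check_positive(N0=N0, b=b)
    return math.sqrt(N0 * b * b / 3.0)


def relaxation_time(N0: float, tau1: float) -> float:
    """Rouse relaxation time ``tau_N0 = N0^2 tau1`` of the linker chain."""
    _check_positive(N0=N0, tau1=tau1)
    return N0 * N0 * tau1


def tau1_from_msd_prefactor(A: float, b: float) -> float:
    """Invert the nucleosome subdiffusion prefactor for the unit time ``tau1``.

    The Rouse mean-square displacement of a tagged unit grows as
    ``MSD(t) = A * sqrt(t)`` with ``A = 8 b^2 / (3 pi^{3/2} sqrt(tau1))``, so
    ``tau1 = (8 b^2 / (3 pi^{3/2} A))^2``.  ``A`` and ``b`` must use matching
    length units (e.g. um^2 s^-1/2 and um).
    """
    _check_positive(A=A, b=b)
    return (8.0 * b * b / (3.0 * math.pi**1.5 * A)) ** 2


def tau_m_from_extrusion_speed(speed_kb_per_s: float, kb_per_unit: float = 1.65) -> float:
    """Per-unit extrusion time ``tau_m`` from a genomic extrusion speed."""
    _check_positive(speed_kb_per_s=speed_kb_per_s, kb_per_unit=kb_per_unit)
    return kb_per_unit / speed_kb_per_s


def reaction_zone_from_dimensionless(chi: float, tau_m: float, tau1: float, b: float) -> float:
    """Reaction-zone size ``a`` from the group ``chi = 2 kB T tau_m / (zeta0 a^2)``.

    With ``zeta0 = 6 kB T tau1 / b^2`` this inverts to
    ``a = b sqrt(tau_m / (3 chi tau1))``.
    """
    _check_positive(chi=chi, tau_m=tau_m, tau1=tau1, b=b)
    return b * math.sqrt(tau_m / (3.0 * chi * tau1))


def dimensionless_from_reaction_zone(a: float, tau_m: float, tau1: float, b: float) -> float:
    """Inverse of :func:`reaction_zone_from_dimensionless` (returns chi)."""
    _check_positive(a=a, tau_m=tau_m, tau1=tau1, b=b)
    return tau_m * b * b / (3.0 * tau1 * a * a)


@dataclass(frozen=True)
class ChainParameters:
    """Composition and friction of the enhancer-promoter linker.

    Parameters
    ----------
    N0 : float
        Number of Kuhn units in the linker (fractional allowed).
    b : float
        Kuhn length (nm in physical units; 1 in the dimensionless convention).
    Ns : float
        Kuhn units in the promoter.  The theory assumes ``Ns << N0``; a
        warning is emitted when ``Ns / N0 > 0.1``.
    tau1 : float
        Single-unit friction time ``zeta0 b^2 / (6 kB T)`` (s, or 1).
    a : float
        Reaction-zone thickness above the condensate surface (same units
        as ``b``).
    kb_per_unit : float
        Genomic content of one Kuhn unit (kb).
    """

    N0: float
    b: float = 1.0
    Ns: float = 1.0
    tau1: float = 1.0
    a: float = 1.0
    kb_per_unit: float = 1.65

    def __post_init__(self) -> None:
        _check_positive(
            N0=self.N0, b=self.b, Ns=self.Ns, tau1=self.tau1, a=self.a,
            kb_per_unit=self.kb_per_unit,
        )
        if self.Ns / self.N0 > 0.1:
            warnings.warn(
                f"Ns/N0 = {self.Ns / self.N0:.3g} > 0.1: the theory assumes a "
                "promoter much shorter than the linker (Ns << N0)",
                stacklevel=2,
            )

    @property
    def l_eq_sq(self) -> float:
        """Equilibrium variance parameter ``l_eq^2 = N0 b^2 / 3``."""
        return self.N0 * self.b * self.b / 3.0

    @property
    def l_eq(self) -> float:
        return math.sqrt(self.l_eq_sq)

    @property
    def diffusion(self) -> float:
        """Centre-of-friction diffusivity ``D = kB T/(N0 zeta0) = b^2/(6 N0 tau1)``."""
        return self.b * self.b / (6.0 * self.N0 * self.tau1)

    @property
    def tau_N0(self) -> float:
        """Rouse relaxation time ``N0^2 tau1`` of the linker."""
        return relaxation_time(self.N0, self.tau1)


@dataclass(frozen=True)
class TimeScales:
    """The three time scales governing one extrusion/relaxation cycle."""

    tau_m: float
    tau_on: float
    tau_ex: float
    tau_N0: float

    @classmethod
    def from_chain(cls, chain: ChainParameters, tau_m: float, tau_on: float) -> "TimeScales":
        _check_positive(tau_m=tau_m, tau_on=tau_on)
        tau_ex = chain.N0 * tau_m
        if not tau_ex < tau_on:
            warnings.warn(
                f"tau_ex = {tau_ex:.3g} >= tau_on = {tau_on:.3g}: the theory "
                "assumes the linker is extruded faster than cohesin is reloaded "
                "(tau_ex < tau_on)",
                stacklevel=2,
            )
        return cls(tau_m=tau_m, tau_on=tau_on, tau_ex=tau_ex, tau_N0=chain.tau_N0)
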