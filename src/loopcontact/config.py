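"""Flat, validated run configuration for the command-line interface.

Keys carry explicit unit suffixes (``b_nm``, ``tau1_s``, ...); unknown keys
are rejected so that a typo cannot silently fall back to a default.  A run
re-executed from its emitted config (same seed) reproduces identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .params import ChainParameters
from .schedule import ExtrusionSchedule

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["relax", "cycle", "scan-linker", "scan-rho", "validate"] = "cycle"

    # chain (physical defaults: 100 kb linker, b = 50 nm, 1.65 kb per unit)
    N0: float = Field(default=100.0 / 1.65, gt=0)
    b_nm: float = Field(default=50.0, gt=0)
    Ns: float = Field(default=1.0, gt=0)
    tau1_s: float = Field(default=0.0035, gt=0)
    kb_per_unit: float = Field(default=1.65, gt=0)

    # schedule (tau_m from a 1 kb/s extrusion speed; t0 ~ TAD recovery time)
    tau_m_s: float = Field(default=1.65, gt=0)
    t0_s: float = Field(default=1800.0, gt=0)
    multiple_cohesins: bool = False

    # reaction zone (default from 2 kB T tau_m / (zeta0 a^2) = 5.0)
    a_nm: float = Field(default=280.3, gt=0)

    # kinetics (effective parameterization)
    alpha_elo: float = Field(default=0.3, ge=0, le=1)
    rho_over_K_elo: float = Field(default=2.2, ge=0)
    k0_per_s: float = Field(default=1.0, gt=0)

    # scan controls
    chi: float = Field(default=5.0, gt=0)
    t0_coefficient: float = Field(default=10.0, gt=0)
    ratio_min: float = Field(default=0.1, gt=0)
    ratio_max: float = Field(default=100.0, gt=0)
    n_ratios: int = Field(default=13, ge=1)
    rho_max: float = Field(default=10.0, gt=0)
    n_rho: int = Field(default=25, ge=1)
    rho_ratios: tuple[float, ...] = (1.0, 10.0, 20.0)

    # numerics / reproducibility
    seed: int = 0
    n_grid: int = Field(default=400, ge=2)

    def chain(self) -> ChainParameters:
        return ChainParameters(
            N0=self.N0, b=self.b_nm, Ns=self.Ns, tau1=self.tau1_s,
            a=self.a_nm, kb_per_unit=self.kb_per_unit,
        )

    def schedule(self) -> ExtrusionSchedule:
        return ExtrusionSchedule(
            chain=self.chain(), tau_m=self.tau_m_s, t0=self.t0_s,
            multiple_cohesins=self.multiple_cohesins,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2, sort_keys=True)
            fh.write("\n")
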