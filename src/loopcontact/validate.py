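"""Cross-validation suite: moment ODE vs finite-difference PDE vs Brownian
dynamics, plus the closed-form kinetics identities.

Used by the ``loopcontact validate`` CLI command and by the test suite.  The
checks are deliberately small (coarse grids, modest ensembles) so the suite
runs in seconds; the test suite runs the same comparisons at full size.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .bd import empirical_msd, simulate_paths
from .dynamics import relaxation_factor_ode
from .fp import family_distance, solve_cycle_fp
from .kinetics import (
    EffectiveKinetics,
    PolIIKinetics,
    boltzmann_tether_factor,
    p_ini_steady,
    sigma_steady,
)
from .params import ChainParameters
from .schedule import ExtrusionSchedule

__all__ = ["run_validation_suite", "oracle_triangle"]


def oracle_triangle(
    ratio_ex_over_relax: float,
    *,
    N0: float = 32.0,
    t0_over_tau_N0: float = 2.0,
    n_paths: int = 2000,
    seed: int = 0,
    nz: int = 1200,
    n_cap_fp: int = 600,
    fp_store_every: int = 5,
) -> dict:
    """Compare r(t) from the moment ODE, the FP solver and BD on one cycle.

    Returns the sup-norm discrepancy of the ODE vs FP curves (relative to the
    cycle maximum of r), the worst BD z-score, and the largest L1 distance of
    the FP density from the radial-Gaussian family.
    """
    chain = ChainParameters(N0=N0, b=1.0, Ns=1.0, tau1=1.0)
    tau_m = ratio_ex_over_relax * chain.tau_N0 / N0
    schedule = ExtrusionSchedule(chain=chain, tau_m=tau_m, t0=t0_over_tau_N0 * chain.tau_N0)

    dist = relaxation_factor_ode(schedule)
    sol, r_fp = solve_cycle_fp(
        schedule, nz=nz, n_cap=n_cap_fp, store_every=fp_store_every
    )
    r_ode_on_fp = dist.r_of(sol.times)
    scale = float(np.max(r_fp))
    ode_fp = float(np.max(np.abs(r_ode_on_fp - r_fp)) / scale)

    # certify the Gaussian-family closure at 10 evenly spaced cycle times,
    # past the delta-like start that the uniform grid cannot resolve
    targets = np.linspace(0.05, 1.0, 10) * schedule.period
    sample = np.unique(np.searchsorted(sol.times, targets).clip(0, sol.times.size - 1))
    l1 = max(family_distance(sol.psi[k], sol.z, chain.l_eq_sq) for k in sample)

    ens = simulate_paths(schedule, n_paths=n_paths, seed=seed)
    mean, se = empirical_msd(ens)
    theory = dist.msd(ens.times)
    keep = se > 0
    zscores = np.abs(mean[keep] - theory[keep]) / se[keep]
    return {
        "ratio": ratio_ex_over_relax,
        "ode_vs_fp_rel": ode_fp,
        "fp_family_l1": float(l1),
        "bd_max_zscore": float(np.max(zscores)),
        "mass_drift": float(np.max(np.abs(sol.mass - 1.0))),
    }


def _kinetics_checks(rng: np.random.Generator) -> list[tuple[str, bool, str]]:
    checks = []
    worst = 0.0
    for _ in range(200):
        kin = PolIIKinetics(
            rho=rng.uniform(0, 10),
            K_ini=rng.uniform(0.01, 10),
            lambda_ini=rng.uniform(0.01, 10),
            lambda_elo=rng.uniform(0.01, 10),
            epsilon=rng.uniform(0, 8),
        )
        g = boltzmann_tether_factor(kin)
        alt = 1.0 - p_ini_steady(kin) * (1.0 - math.exp(-kin.epsilon))
        worst = max(worst, abs(g - alt))
    checks.append(("tether-factor identity", worst < 1e-12, f"max |diff| = {worst:.2e}"))

    kin = EffectiveKinetics(alpha_elo=0.3, rho_over_K_elo=2.2)
    psi = 0.37
    s = sigma_steady(psi, kin)
    s_inf = sigma_steady(psi, EffectiveKinetics(alpha_elo=0.3, rho_over_K_elo=1e9))
    checks.append(
        (
            "sigma large-rho asymptote",
            abs(s_inf - psi / (psi + 0.3)) < 1e-6,
            f"sigma(rho->inf) = {s_inf:.6f}",
        )
    )
    s0 = sigma_steady(psi, EffectiveKinetics(alpha_elo=0.3, rho_over_K_elo=0.0))
    checks.append(
        ("sigma rho=0 limit", abs(s0 - psi / (1 + psi)) < 1e-12, f"sigma(0) = {s0:.6f}")
    )
    checks.append(("sigma bounded", 0.0 <= s <= 1.0, f"sigma = {s:.6f}"))
    return checks


def run_validation_suite(
    *, seed: int = 0, ratios=(0.1,), n_paths: int = 2000, drift_scale: float = 1.0
) -> pd.DataFrame:
    """Execute the oracle cross-checks and kinetics identities.

    ``drift_scale != 1`` perturbs the FP drift (negative control); the FP/ODE
    comparison is then expected to fail, and the suite must flag it.
    """
    rows = []
    for ratio in ratios:
        res = oracle_triangle(ratio, n_paths=n_paths, seed=seed)
        if drift_scale != 1.0:
            chain = ChainParameters(N0=32.0, b=1.0, Ns=1.0, tau1=1.0)
            tau_m = ratio * chain.tau_N0 / 32.0
            schedule = ExtrusionSchedule(chain=chain, tau_m=tau_m, t0=2.0 * chain.tau_N0)
            dist = relaxation_factor_ode(schedule)
            sol, r_fp = solve_cycle_fp(
                schedule, nz=1200, n_cap=600, store_every=5, drift_scale=drift_scale
            )
            res["ode_vs_fp_rel"] = float(
                np.max(np.abs(dist.r_of(sol.times) - r_fp)) / max(np.max(r_fp), 1e-12)
            )
        rows.append(
            (
                f"ODE vs FP (ratio={ratio})",
                res["ode_vs_fp_rel"] < 1e-2,
                f"sup-rel = {res['ode_vs_fp_rel']:.2e}",
            )
        )
        rows.append(
            (
                f"FP within Gaussian family (ratio={ratio})",
                res["fp_family_l1"] < 5e-3,
                f"max L1 = {res['fp_family_l1']:.2e}",
            )
        )
        rows.append(
            (
                f"BD within 3 SE (ratio={ratio})",
                res["bd_max_zscore"] < 3.0,
                f"max |z| = {res['bd_max_zscore']:.2f}",
            )
        )
        rows.append(
            (
                f"FP mass conservation (ratio={ratio})",
                res["mass_drift"] < 1e-6,
                f"max drift = {res['mass_drift']:.2e}",
            )
        )
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    rows.extend(_kinetics_checks(rng))
    return pd.DataFrame(rows, columns=["check", "passed", "detail"])
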