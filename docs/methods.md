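# Methods

## Model and assumptions

The enhancer–promoter linker is an ideal (Rouse) chain of `N0` Kuhn units of
length `b`, anchored at the enhancer to the surface of a large, stable
transcriptional condensate. Only the height `z` of the promoter above the
surface is tracked. The linker's repulsion from the condensate and its
embedding in a longer chain give the equilibrium radial-Gaussian law
`ψ_eq(z) ∝ z² exp(−z²/(2 l_eq²))` with `l_eq² = N0 b²/3`. Excluded-volume,
hydrodynamic and topological interactions are neglected (concentrated-
solution screening), enhancer unbinding is neglected, and the promoter is
assumed much shorter than the linker (`Ns ≪ N0`; a warning is emitted above
`Ns/N0 = 0.1`).

Cohesin is loaded at the enhancer every `t0 = τ_on` and extrudes one Kuhn
unit per `τ_m`, so the linker (`τ_ex = N0 τ_m`) alternates between a
relaxation process (arm count `N = N0`, loop count `N_p = N0(1 + t/τ_ex)`)
and an extrusion process (`N = N0(1 − t′/τ_ex)`). Loading is deterministic
(`t0 = τ_on`), matching the regime `τ_ex < τ_on`; a multiple-cohesin
schedule (`N_p = N0 τ_on/τ_ex` constant, `N = N0(τ_on − t)/τ_ex`) is
available behind a flag and off by default. Each cycle ends with the
promoter extruded into the loop, resetting `ψ(z) = δ(z)`, which makes the
dynamics exactly periodic — long-time averages reduce to one-cycle averages.

## The moment closure

The dumbbell-in-a-potential Smoluchowski equation with local-equilibrium
stiffness is the radial Fokker–Planck equation of a 3-D isotropic
Ornstein–Uhlenbeck process with per-component variance target `l²(t)` and
diffusivity `D = k_BT/(N0 ζ0) = b²/(6 N0 τ1)`. That process maps the
radial-Gaussian family onto itself, so the density is fully parameterized by
the relaxation factor `r(t) = ⟨z²⟩/(3 l_eq²)`, which satisfies the exact
first-moment equation `dr/dt = (1 − r l_eq²/l²(t))/τ_N0` with
`τ_N0 = N0² τ1`. This replaces an eigenfunction-expansion solution of the
PDE; its exactness is *asserted numerically*, not assumed: the
finite-difference solver must reproduce `r(t)` to better than 1 % (sup-norm
relative to the cycle maximum of `r` — pointwise relative error is
ill-defined at the `r(0) = 0` start) and the L1 distance of the PDE density
from the family member with matching second moment must stay below 5×10⁻³
at ten evenly spaced cycle times past `t/period = 0.05` (earlier times are
delta-like and below grid resolution).

Numerical choices for the ODE:

- The coefficient diverges as `τ_ex/t` at `t = 0`. Integration starts at
  `t_min = 10⁻⁶ min(τ_ex, τ_N0)` from the exact leading-order series
  `r(t) = t/(τ_N0 + τ_ex)`, and `r` is extended linearly below `t_min`.
- As `t′ → τ_ex` the arm vanishes and `l² → 0`. The arm count is floored at
  `N_floor = max(Ns, 1)` — the promoter's own units — which keeps the
  stiffness finite. Consequently the computed `r` at the cycle end follows
  the collapse law `r ∝ (τ_ex − t′)^{min(1, τ_ex/τ_N0)}` only down to the
  floor scale; the physical return to `z = 0` is carried by the cycle reset
  itself. For `τ_ex ≪ τ_N0` this collapse is confined to a vanishing sliver
  of the cycle (the promoter is "hardly affected, then drops steeply").
- LSODA with `rtol = 10⁻⁸` handles the stiff endpoint automatically.

`Ψ_a` is the one-cycle average of the closed-form zone mass
`F(a; r) = erf(x) − (2/√π) x e^{−x²}`, `x = a/√(2 l_eq² r)`, computed by
adaptive quadrature in time with a breakpoint at `t0`; no nested
z-integration is performed.

## The two oracles

**Finite differences.** The PDE is discretized in the 3-D radial variable
(`p = ψ/z²`) in flux form on a cell-centred grid (`z_max = 6 l_eq`,
`nz = 2000` by default), with Chang–Cooper exponential face weighting. For
this geometry the face-midpoint drift integrates `z²/2` exactly, so the
discrete equilibrium is the sampled radial Gaussian to machine precision,
and the zero boundary fluxes (the `z²` weight vanishes at the origin)
conserve total probability to round-off. Time stepping is Crank–Nicolson
with midpoint coefficients on an adaptive grid (below); the δ(z) initial
condition is represented by the family member with `r0 = 10⁻⁴`. Halving dz
and dt at the default resolution changes `⟨z²⟩` at the cycle end by < 0.2 %.

**Brownian dynamics.** The 3-D Cartesian OU process is simulated by
Euler–Maruyama and `z = |R|` taken afterwards, avoiding the `−2/z` origin
singularity exactly. Paths start from `z = 0`; the first grid point is
seeded from the exact early-time series so no variance is lost in the
sliver `[0, t_min]`. Randomness is counter-based: path `i` uses the `i`-th
spawned `SeedSequence` child with a Philox generator, so each path is
bit-reproducible independently of the ensemble size or chunking.

**Shared time grid.** Both solvers use steps
`dt ≤ min(span/n_cap, β l²(t)/D, α t, max(α(t_end − t), β l²_floor/D))`
with `α = 0.02` and `β = 0.05` (PDE, unconditionally stable) or `β = 0.005`
(BD, keeping the per-step Euler bias ≈ `β/2 ≈ 0.25 %`, well inside the
Monte-Carlo bands at 10⁴ paths). The `α` terms resolve the coefficient
variation where `l²` is proportional to `t` or to `t_end − t`; the floor
term bounds the total step count.

## Binding kinetics

At most one Pol II occupies the promoter, so the tether exponent `n` takes
values {0, 1} and `⟨e^{−nε}⟩ₙ = 1 − P_ini(1 − e^{−ε})` with `P_ini` the
steady-state initiation-state occupancy; the package verifies this identity
against the `(α_elo ρ + K_elo)/(ρ + K_elo)` form at every evaluation. The
binding and unbinding prefactors share the single rate constant `k0`, which
cancels from the steady state — `σ = Ψ_a/(Ψ_a + ⟨e^{−nε}⟩ₙ)` — and only
sets the relaxation rate `k0(Ψ_a + ⟨e^{−nε}⟩ₙ)` of the closed-form time
course. `Ψ_a` enters as its cycle average, not as an instantaneous rate:
the steady state of the slow binding dynamics samples the fast periodic
polymer dynamics only through that average.

## Scans

The linker-length scan fixes the dimensionless groups
`t0 τ_N0/τ_ex² = 10`, `2k_BT τ_m/(ζ0 a²) = 5`, `α_elo = 0.3`,
`ρ/K_elo = 2.2` and varies `τ_N0/τ_ex ∝ N0`. All scan quantities depend on
`N0` only through that ratio (`a²/l_eq² = 1/(χ·ratio)`,
`t0/τ_N0 = 10/ratio²`), so the scan is computed directly in the ratio with
a fixed internal `N0 = 50`. For ratios above the `t0`-rule crossover the
schedule leaves the `τ_ex < τ_on` regime and a warning is emitted; the scan
still evaluates there. The Pol II concentration scan uses
`t0 τ_N0/τ_ex² = 20` and ratios {1, 10, 20}. The microscopic triple
`(λ_ini, λ_elo, ε)` realizing a given `α_elo` is underdetermined, so scans
take `α_elo` and `ρ/K_elo` directly (`EffectiveKinetics`).

## Problem sizes and defaults

Oracle cross-checks run on a dimensionless 32-unit chain
(`b = τ1 = 1`, `t0 = 2 τ_N0`) over one full cycle at
`τ_ex/τ_N0 ∈ {0.01, 0.1, 1}`, with `nz = 2000` spatial nodes, ~2000
adaptive time steps and 10⁴ Brownian paths — sizes at which the
discretization errors sit well below the 1 % / 3-standard-error comparison
bands while a full validation pass completes in well under a minute.
Physical defaults in the CLI config follow the worked estimates: `b = 50 nm`,
1.65 kb per unit, `τ1 = 0.0035 s`, `τ_m = 1.65 s` (1 kb/s), `t0 = 1800 s`
(TAD-recovery scale), `a ≈ 280 nm` (from the χ = 5 rule).

## What the synthetic ensembles do and do not show

The Brownian ensemble realizes exactly the model's dumbbell reduction — the
same approximation chain as the theory — so agreement certifies the
numerics and the moment closure, not the biological fidelity of the
dumbbell itself. Real chromatin adds tension propagation along the chain,
heterogeneous extrusion speeds, stochastic cohesin loading (a Poisson
variant of the schedule is noted but off by default), condensate turnover
and Pol II concentration feedback, all outside scope here. Contact
probabilities are therefore qualitative predictions — orderings, monotonic
trends and turnover points — rather than calibrated absolute values.

## Known limitations

- The arm-count floor makes the terminal collapse of `⟨z²⟩` saturate at
  `r ≈ (N_floor/N0)^{τ_ex/τ_N0}`; for `τ_ex ≪ τ_N0` the unfloored collapse
  would anyway occupy an exponentially small end sliver.
- `ζ` and `ζ0` are treated as the same per-unit friction constant.
- Fractional unit counts are allowed everywhere (the continuum schedule
  does not quantize cohesin steps).
- The equilibrium (extrusion-inhibited) branch of the linker scan uses the
  same reaction-zone rule as the active branch.
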