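# Methods

## Model

The simulation couples `Nc` self-propelled disc-shaped cells to three
periodic continuum fields on one uniform `N × N` grid over the square
box `[0, L*)²`:

* **Cell kinematics.** Cell `i` moves at `Vprop · ρ(r_i) · p(φ_i)` plus
  pairwise Gaussian steric repulsion `∇Π`, `Π(r) = F0 exp(−r²/l0²)`
  (minimal-image distances, periodic wrap). Propulsion depends linearly
  on the local substrate integrity `ρ` — the simplest interpolation
  between full speed on intact matrix and stall on fully degraded
  matrix. Positions advance by explicit Euler.
* **Durotaxis.** The polarization angle obeys
  `dφ/dt = kσ(|u(x⁺)| − |u(x⁻)|) + √(2 D_rot) ξ`, where `x^±` are the
  two lateral side points at `±(d/2)` along the normal of `p` and `|u|`
  is sampled by bilinear interpolation of the displacement components.
  The sign convention turns the cell **toward** the side with the
  larger displacement magnitude. This is the choice that produces
  aggregation: a linear-stability argument for a cell in the
  radially decaying `|u|` field of a neighbor shows the
  heading-toward-source orientation is the stable fixed point under
  this sign (and the unstable one under the opposite sign), and only
  this choice reproduces durotaxis-driven clustering and the tendency
  of cells to follow degraded, softened trails. The noise is an
  Euler–Maruyama increment `√(2 D_rot Δt) z`.
* **Substrate mechanics.** `η ∂u/∂t = ∇·σ + T` with
  `σ = ½E0(1+ερ)(∇u + ∇uᵀ)`: degraded matrix is softer, so
  displacements grow around degraded regions. Each cell exerts a
  traction `T̂_i(x) p(φ_i)` built from two Gaussian lobes of width
  `lT = d/8` at `±d/4` along the polarization, truncated to the cell
  footprint `|x − r_i| < d/2` and re-centered node-wise to an exactly
  zero grid sum (momentum-free traction). The sub-cellular traction
  distribution of a real crawling cell is not observable at this
  resolution; the dipole is the minimal profile satisfying the modeling
  constraints (compact support, zero net force, parallel to the
  polarization), and its amplitude is calibrated as described below.
  Emergent quantities that depend on the detailed near-field
  displacement pattern inherit this surrogate choice (see the
  limitations below).
* **Enzyme kinetics and degradation.**
  `∂C/∂t = D_C ΔC + Σ_i ν_C e^{−|x−r_i|²/d²} − γ1 C ρ − β C` and
  `∂ρ/∂t = −γ2 C ρ`. The production Gaussian is truncated at `4d`
  (relative tail `e^{−16}`).

## Numerical scheme

Time step `Δt = 5·10⁻³`, fixed. Each step performs, in order:
traction assembly → semi-implicit update of `u` → semi-implicit update
of `C` (reaction terms explicit in the forcing) → exact exponential
update `ρ ← ρ·exp(−γ2 C Δt)` → explicit Euler for positions and
orientations. The semi-implicit systems
`(I − Δt L) f_{n+1} = f_n + Δt g(f_n)` (with `L` either `D_C Δ` or
`(1/η)∇·σ`, both discretized in flux form with half-node coefficients,
so constants are annihilated and grid means conserved) are solved by
**red–black ordered Gauss–Seidel** iteration to a max-norm residual of
`gs_tol·(1 + ‖rhs‖∞)`, `gs_tol = 10⁻⁸` — far below the O(Δt) splitting
error. Two standard accelerations keep the cost practical without
changing the scheme: over-relaxed sweeps (SOR; the factor defaults to
the classical optimum computed from each operator's diagonal-dominance
ratio, and `ω = 1` recovers the plain sweep), and a warm start from the
linear extrapolation `2f_n − f_{n−1}` (an initial guess only). `C` is
clipped at zero only for round-off-scale undershoot (`> −10⁻¹²`
relative is an error).

Degenerate inputs: coincident cells exert zero steric force (the
Gaussian gradient vanishes at the origin) with a warning; a cell whose
footprint contains no grid node deposits no traction; solver
non-convergence or any invariant breach (negative `C`, `ρ ∉ [0,1]`,
non-finite state) aborts the step with its index.

With durotaxis off the displacement field influences nothing
(one-way coupling), so its solve is skipped; with degradation off the
`C` and `ρ` fields stay at their initial state. This changes no
observable of those conditions.

## Parameters

Nondimensionalization: lengths in `l = 25 µm`, times in `τ = 4 h`
(velocity unit 6.25 µm/h). Directly mapped values: `L* = 20`,
`d = 0.4`, `Vprop = 0.32`, `D_C = 27.65`, `γ1 = 0.79`, `β = 28.8`
(diffusion length of the enzyme `√(D_C/β) ≈ 1` unit = 25 µm, which
sets the width of degraded trails). `ε = 0.5`.

The remaining coefficients have no consistently mappable dimensional
value and are fixed once by calibration:

* `F0 = 0.2106`, `l0 = d`: the amplitude solves, by ODE integration,
  the requirement that a fully overlapping pair separates to distance
  `d` within one time unit.
* `T0 = 40` (with `E0 = η = 1`): steady single-cell displacement
  `|u| ≈ 0.05` (1.25 µm) one cell diameter from the center.
* `kσ = 400`: in the near-saturated turning regime — the reference
  dimensional value implies `kσ·τ ≫ 1`, and cluster statistics are flat
  for `kσ` between ~80 and ~1000, which is also the regime in which a
  further 10× increase leaves clustering unchanged.
* `D_rot = 0.1` (persistence time `10 τ`).
* `ν_C = 1` by convention (the enzyme equation is linear in `C`, so
  `ν_C` only sets the scale of `γ2 C`); `γ2 = 45` is then calibrated so
  that population arrest occurs mid-observation-window
  (`T_degr ≈ 20–30` for the default densities). The degraded area *at*
  arrest is insensitive to this choice (65–74% across a 4× range of
  `γ2`), because it is set by the geometry of the degradation trails,
  not by their speed.

## Problem sizes

Default grid `N = 200` (`Δx = 0.1 = d/4`); all observables vary on the
cell scale `d = 0.4`, so this resolves them while keeping desk-scale
runs in seconds-to-minutes. The headline degraded-area measurement
(Nc = 40) runs on this grid. Replicate ensembles and sweeps use an
`N = 128` profile (`Δx = 0.156`), verified against the fine grid on
matched seeds (S1 identical to the recorded cadence, arrest time and
degraded area within a few percent). Ensembles use 10 replicates;
pooled 40-replicate cluster totals are estimated as 4× the mean
per-replicate count.

Arrest (`T_degr`) is the first recorded time at which the mean local
`ρ` under the cells (disc of radius `d/2`) drops below 0.01 and stays
below it for 10 consecutive frames (1 time unit at the default
recording cadence).

Cluster pooling: shape metrics (aspect ratio) and connectivity indices
are pooled over clusters of **≥ 4 cells** — the size class whose totals
the benchmark tabulations quote; "clustered cell" speed averages over
cells in clusters of ≥ 2 cells, measured from the instantaneous
velocity at the final step and normalized by `v0 = Vprop`
(2 µm/h). Sensitivity sweeps report the post-arrest mean of the `S1`
series and the mean connectivity of final clusters of ≥ 2 cells
(at strongly elevated degradation rates ≥ 4-cell clusters need not
exist).

## What the simulations do and do not show

The synthetic dynamics reproduce: the ~70% degraded area at arrest;
durotaxis-driven clustering (S1 roughly 3–5 with durotaxis vs the
random-proximity level ~1.4–2 without, at matched seeds); the
elongation of clusters by degradation (higher aspect ratio, lower
connectivity with degradation than without); near-total immobilization
of clustered cells by degradation (> 50× speed contrast); and the
insensitivity of post-arrest clustering to a 10× increase of `kσ`.

Known limitations, all tied to the surrogate traction profile:
with our dipole, durotaxis-on/degradation-off clusters remain *dynamic*
(cells orbit within clusters at 0.3–0.5 `Vprop`, rather than the ~0.18
`v0` measured for the benchmark ensembles); degradation, arriving before aggregation
completes, *reduces* the number of ≥ 4-cell clusters instead of
increasing it; and the post-arrest cluster-size fold-change under 10×
`γ2` is ~1.5 rather than ~5, because the baseline S1 at arrest
saturates near 3 while the 10×-rate runs freeze at the
random-proximity floor (~1.4–2.0 depending on density). The model also
omits, by design, cell proliferation, cell–cell adhesion, cell-shape
dynamics, and any vertical (3D) invasion component.

The no-durotaxis control has an irreducible floor: 40 uniformly random
points in the box have `S1 = 1.98 ± 0.28` at the 2-unit cutoff, and
steric head-on stalls add roughly +0.1 to time averages, so individual
replicates can average slightly above 2.
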