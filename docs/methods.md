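# Methods

## The physical model

`particokinetics` simulates the transport of a dilute suspension of
spherical particles (or their agglomerates) through a static column of
cell-culture medium to the vessel bottom, where a cell monolayer captures
everything that arrives. Two mechanisms move particles vertically:

* **Gravitational settling** at the Stokes terminal velocity

  $$V = \frac{g\,(\rho_p - \rho_f)\,d^2}{18\,\mu}$$

  with particle density ρ_p, fluid density ρ_f, hydrodynamic diameter d and
  dynamic viscosity μ. V is signed: a buoyant particle (ρ_p < ρ_f) drifts
  upward (the package warns, since the regime is untypical for the
  materials of interest).

* **Brownian diffusion** with the Stokes–Einstein coefficient

  $$D = \frac{RT}{3 N_A \pi \mu d} = \frac{k_B T}{3\pi\mu d}.$$

  k_B is computed as R/N_A from the CODATA R and N_A (equivalent to the
  CODATA k_B to well beyond 6 digits).

Both expressions assume creeping flow; the particle Reynolds number
ρ_f|V|d/μ is screened on every problem build and the solver refuses (or,
configurably, warns) at Re ≥ 1. All built-in scenarios sit at Re < 0.1 by a
wide margin.

The suspension concentration n(x, t) obeys the one-dimensional
convection–diffusion (Mason–Weaver) equation

$$\partial_t n = D\,\partial_x^2 n + V\,\partial_x n,\qquad x\in[0,L],$$

with x = 0 at the bottom (cells) and x = L at the free surface, so positive
V carries mass toward x = 0. Conditions: uniform initial profile n = n₀;
zero total flux through the free surface; an absorbing bottom n(0, t) = 0
(particles adhere on contact and leave the suspension — a reflecting bottom
is available for the non-adherent variant). The delivered fraction is the
column mass deficit

$$f(t) = 1 - \frac{1}{L}\int_0^L \frac{n}{n_0}\,dx.$$

In dimensionless form (x̄ = x/L, t̄ = tV/L) the problem depends only on
α = D/(VL), the inverse Péclet number. When |V| < 1e-15 m/s this scaling
degenerates; the solver then simply works in the diffusion scaling (the
discretization is dimensional in time throughout, so no special-casing of
the equations is needed — α is reported as ∞).

### Agglomerates

Agglomerates are modeled as impermeable fractal spheres: solid mass scales
with envelope diameter as d_agg^DF (fractal dimension 1 < DF ≤ 3, packing
factor 0 < PF ≤ 1, default 0.637 for randomly packed spheres):

* monomers per agglomerate: Np = (d_agg/d)^DF / PF,
* porosity: ε = 1 − (d_agg/d)^(DF−3),
* effective density: ρ_agg = (1−ε)ρ_p + ε·ρ_f,
* settling velocity: V_agg = g(ρ_agg−ρ_f)·d^(3−DF)·d_agg^(DF−1)/(18μ),
  algebraically the Stokes velocity of a solid d_agg sphere at ρ_agg.

Diffusivity uses the envelope diameter. Trapped medium is not counted as
particle mass; the surface-area dose metric counts constituent monomer
surface Np·πd² (the biologically argued quantity), not the envelope.

Note that the porosity relation above omits PF from the pore-space term
(packing contributes only through Np). An alternative form in the
flocculation literature includes it, ε = 1 − PF(d_agg/d)^(DF−3), which
lowers every effective density by the solid-fraction factor PF. The choice
matters for one qualitative prediction, discussed under *Known
limitations*.

## Numerics

* **Spatial discretization**: finite volumes with exponentially fitted
  (Scharfetter–Gummel) interface fluxes, exact for steady drift–diffusion at
  any Péclet number. The particle range of interest spans Pe ≈ 1e-3 to
  ≈ 1e8 (20 nm polymer beads to micron metal spheres); central differences
  oscillate and plain upwinding is over-diffusive across that range.
  Default 400 cells, geometrically refined toward the absorbing bottom
  (largest:smallest cell ratio 50) to resolve the depletion boundary layer.
* **Boundary treatment**: the absorbing wall is a ghost value 0 at distance
  δ (half the bottom cell) entering the same exponentially fitted flux; the
  top face flux is identically zero.
* **Time integration**: the semi-discrete system is linear with a constant
  tridiagonal operator; it is integrated with an implicit adaptive BDF
  method (rtol 1e-7, atol 1e-9 by default) with the exact sparse Jacobian.
* **Accounting**: f(t) comes from the mass deficit, which is exactly
  conservative under finite volumes. The time-integrated bottom flux is
  carried as an extra state and reported as `mass_balance_error` (the
  maximum deviation between the two accountings); it measures
  time-integration error and sits near machine precision in practice,
  far below the 1e-4 acceptance level.
* **Verification**: the solver is checked against three independent closed
  forms (module `oracles`): a semi-infinite drift–diffusion first-passage
  solution (valid while 2√(Dt)+Vt ≤ 0.2L; the e^{Vx/D}·erfc product is
  evaluated through erfcx so it cannot overflow at high Péclet), the
  absorbing/reflecting pure-diffusion eigen-series, and the plug-flow
  sedimentation limit. Agreement is within 1% across a 100-point random
  (D, V, L, t) sweep, and grid refinement (double cells, halved tolerances)
  moves the delivered fraction by < 0.1% on all fixtures.

## Dosimetry conventions

Administered totals convert between number and mass through the solid
volume (ρ_p πd³/6 per monomer; Np times that per agglomerate). All per-area
metrics divide by the deposition (well-bottom) area. The AUC is the
trapezoidal integral of the *cumulative* delivered dose over time
(metric·hours) — a time-weighted dose.

Polydisperse suspensions (DLS-style class tables: diameter + number
fraction) are solved class by class — the PDE is linear and particles are
non-interacting — and summed. Class mass weights are number fractions times
per-class solid mass (∝ d_agg^DF in agglomerate mode). The mixture
`fraction_delivered` is the mass-weighted one.

## Fixture scenarios and the synthetic size distribution

All built-in scenarios share: T = 310 K, ρ_f = 1.0 g/mL, μ = 0.69 mPa·s
(0.74 mPa·s for the serum-containing silica study — serum raises viscosity
about 5% at 10%, which the config system exposes as a linear
`serum_percent` multiplier). Temperatures in fixtures use 310 K, not
310.15 K. Material densities (g/cm³): polystyrene 1.05, amorphous silica
2.2, TiO₂ 4.23, iron oxide 5.2, gold 19.32.

* **Polystyrene counting** — 24/100/210/500/1100 nm beads,
  3.7e8 particles/mL, 0.31 cm media height, 500 s, counted on a
  3.717e-5 cm² microscopy field (4.26e3 particles initially above it). The
  ~30 s handling delay in the original bench protocol is *not* added to the
  500 s window. The diffusion-dominated sizes land on 181/89/62 counts
  (reference simulated values 181/89/63). The published simulated counts
  for 500 and 1100 nm (73, 62) exceed the independent first-passage oracle
  (≈43, ≈47) under the stated parameters; this package does not attempt to
  reproduce those two values (the solver agrees with the oracle to < 1%
  there and the cause of the original discrepancy — numerical dispersion or
  unstated effective sizes — cannot be determined from the printed
  parameters).
* **Silica media heights** — 34.8 nm hydrodynamic diameter (the reported
  TEM size is 29.3 nm; the hydrodynamic value is what transport sees),
  heights 1.1–4.5 mm, 6 h, constant-concentration (37 µg/mL) and
  constant-mass (16.7 µg) designs in 0.81 cm² wells. Delivered fraction
  falls monotonically with height; the shallow well delivers ≈ 0.63
  (pure-diffusion series gives 0.627, settling adds the rest). The model
  predicts a ≈4-fold fraction increase from 4.5 to 1.1 mm.
* **Iron-oxide agglomerates** — 34.8 nm monomers agglomerated to a mean
  993.7 nm (SD 272.1 nm) distribution, 1.06 mm media height, 2 µg/mL, 8 h,
  PF 0.637, DF scanned over 2.0–2.4 (delivered mass rises monotonically
  with DF). The original DLS class table is unpublished, so the package
  generates a **synthetic** five-class stand-in: a seeded lognormal sample
  (n = 1e5) binned into five log-spaced classes between its 1st and 99th
  percentiles, pinned to the printed mean/SD. This reproduces the summary
  statistics, not the unpublished histogram shape; conclusions that depend
  on distribution tails should not lean on it.
* **Generalization sweeps** — 24-h, 10 µg/mL, 3 mL, 3.1 mm grids: size
  (10–3000 nm) × density (five materials) AUCs per metric; a TiO₂
  media-height sweep; and an agglomeration-state sweep (Np = 1–1e4 Fe₂O₃
  monomers of 34.6 nm at DF 2.2 and 2.4). Np = 1 is run as the bare
  monomer, since inverting the particle-count relation at Np = 1 would give
  an envelope smaller than the monomer itself.

What the synthetic generator does *not* emulate: dynamic agglomeration
during exposure, class-to-class interactions, measurement noise in DLS
fractions, and non-lognormal (e.g. bimodal) dispersions. Passing tests
therefore demonstrate correct transport arithmetic for a stated
distribution, not fidelity to any particular bench suspension.

## Design choices in genuinely open spots

* Config concentrations require an explicit unit tag (`ug_per_mL` or
  `particles_per_mL`); a bare number is exactly the dose-metric ambiguity
  the package exists to prevent. A literature value printed as
  "3,717 × 10⁻⁵ cm²" is read with "," as a decimal point (consistent with
  the 4.26e3 particle total); outputs use "." only.
* Published media viscosities quoted as "0.9598 Pa·s" / "1.011 Pa·s" are
  three orders of magnitude above water and are interpreted as mPa·s (cP),
  consistent with the simulation value 0.00069 Pa·s used everywhere.
* Np is kept as a real number (the count relation is continuous); rounding
  is left to presentation.
* The command-line `sweep`/`scenario` tables are plain pandas renderings;
  run artifacts are RFC-4180 CSV plus JSON summaries, and identical configs
  produce byte-identical outputs.

## Known limitations

* No advection, thermal convection, evaporation, meniscus effects, vessel
  side walls, or 2-D/3-D geometry; no hindered settling or hydrodynamic
  particle–particle interactions; spheres only (no fibers); no cellular
  uptake/exocytosis — the absorbing bottom equates "delivered" with
  "cell-associated".
* Agglomeration state is fixed for the duration of a run.
* Because V_agg ∝ d_agg^(2(DF−2)) under the porosity relation used (no PF
  in the pore-space term), the settling speed *rises* with agglomerate size
  for any DF > 2. Consequently the 24-h delivered fraction versus Np at
  DF = 2.2 is U-shaped (diffusion loss first, settling gain later), and at
  Np = 1e4 slightly exceeds the bare-monomer value — the expectation that
  loose packing makes delivery decrease monotonically with agglomerate
  size holds over Np ≈ 1–10³ here but not at the extreme end. Including PF
  in the porosity (the alternative form above) lowers agglomerate densities
  enough to restore the monotone-decreasing behavior; the package
  implements the form without PF and leaves the corresponding qualitative
  test failing, rather than silently switching relations. At DF = 2.4 the
  delivered fraction rises steeply with Np as expected.
* The first-passage oracle is only valid while the depletion layer is thin;
  no closed form is provided for the finite-column drift–diffusion
  absorbing problem (non-self-adjoint eigenproblem) — the numerical solver
  is authoritative there.

## Problem sizes

Defaults (400 cells, refinement 50, BDF at 1e-7/1e-9) solve a scenario in
tens of milliseconds, so the full test suite — including the 100-point
oracle sweep, the 30-cell size×density grid and the agglomeration sweeps —
completes in well under a minute. Tests use 150–200 cells where many
scenarios are run; grid-convergence tests compare 400 against 800 cells.
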