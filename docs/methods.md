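# Methods

## The rebinding model and its assumptions

A hydrogel-coated flow-injection biosensor reports the mass of a tethered
probe–target complex **BP** as a response in RU (100 RU ≙ 1 mg/ml within the
hydrogel; `G = 100 RU` per g/L converts the saturation response `Rmax` into a
molar probe concentration `P = Rmax/(G·Mr_B)`). When the complex dissociates,
the released target **B** is overwhelmingly likely to rebind a neighbouring
probe before it escapes the hydrogel, so the apparent dissociation rate is
slowed from `kd′` to `kd′·α` with

    α = β / (β + ka′·P),   β = kt + f·ka·A,   f = 1/(1 + kd/kt).

The model treats free target as a transient encounter species partitioned
between three first-order sinks: re-association (`ka′·P`), capture by a
soluble inhibitor (`ka·A`), and escape at the mass-transport rate `kt`
(escape time τ = 1/kt). Capture is only productive if the inhibitor complex
**AB** escapes before it re-dissociates; the factor `f` is the probability of
that race, and it is what makes the observed decay sensitive to sub-second
`kd` — at `kd = kt` half the inhibition is lost. An irreversible (covalent)
inhibitor adds an inactivation channel with partition factor
`z = 1 + kinact/kt`; for drug-like `kinact ≤ 1 s⁻¹` and the `kt` of
practical hydrogels (tens to hundreds of s⁻¹), `z ≈ 1` and reversible and
covalent inhibitors produce indistinguishable inhibition curves, so `ka` and
transient `kd` of a covalent binder can be measured as if it were reversible.

Assumptions, stated explicitly:

1. **Quasi-steady state.** Free **B** equilibrates among its sinks much
   faster than the response decays. Valid when `kt + ka′P ≫ kd′·α`, which
   holds by orders of magnitude in all regimes simulated here.
2. **Constant α.** `P` in the model is the *total* probe concentration; the
   free-probe concentration drifts as occupancy changes during dissociation.
   The model is therefore exact only in the limit of small occupancy, which
   drives the fit-window policy below.
3. **A single transport rate.** `kt` lumps flow-cell and hydrogel resistance
   into one first-order escape rate shared by **B** and **AB**.
4. **Excess inhibitor.** `A` is constant during the inhibitor injection.

## Parameters, units and defaults

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| `ka`, `kd` | inhibitor–target rates | M⁻¹s⁻¹, s⁻¹ | study draws | quantities under test |
| `ka′`, `kd′` | probe–target rates | M⁻¹s⁻¹, s⁻¹ | 1e6, 0.05 | moderate-affinity probe; `1/kd′` in the 1–300 s practical band |
| `kinact` | inactivation rate | s⁻¹ | 0 | covalent channel off unless studied |
| `kt` | hydrogel escape rate | s⁻¹ | fitted/calibrated | not measurable a priori; estimated from blank curves |
| `P` | probe concentration in gel | M | 1e-3 | ≙ `Rmax = 3000 RU` at 30 kDa target |
| `G` | response conversion | RU per g/L | 100 | typical SPR hydrogel sensor |
| `Mr_B`, `Mr_A` | molecular weights | g/mol | 30000, 200 | protein target, small-molecule inhibitor |
| `D_A` | bulk diffusion of inhibitor | m²/s | 5e-10 | small molecule in water |
| flow cell | h × l, sensing region, gel | m | 20e-6 × 0.5e-3, 0.2e-3 × 200e-9 | conventional microfluidic biosensor geometry |
| `nu_c` | centre-line velocity | m/s | 0.1 | conventional operating point; studies sweep 0.001–0.15 |
| sampling / noise | detection | Hz / RU | 1 Hz, 0.03 RMS | instrument-realistic data rate and baseline noise |

Transport conversions: the response-scaled coefficient is
`kt′ = 1e9·Mr_B·kt` (1e9 g·m/mol scaling); the two-compartment simulator
works in molar units with `kt` in s⁻¹, related to response-scaled grids via
`kt_s = kt′/(G·Mr_B)` — this choice makes the quasi-steady-state identity
`koff = kd′·α` hold exactly and keeps the Damköhler number invariant. The
printed flow-cell expression `kt = T_γ·1.281·(ν_c·D/(2hl))^{1/3}` is
implemented exactly as stated; because it is not dimensionally a rate, the
classical Lévêque-type flux form `1.281·(ν_c·D²/(hl))^{1/3}` (a velocity,
m/s) is available behind `variant="leveque"`. Both obey the `ν_c^{1/3}` and
`T_γ`-linearity laws the tests rely on. In every fitting workflow `kt` is a
fitted or blank-calibrated parameter, never taken from these formulas.

## The virtual instrument

`flowcell_sim` solves the 2-D advection–diffusion–reaction system for the
soluble species (A, B, AB, and AB\* when `kinact > 0`) coupled to reaction
ODEs for the tethered species (P, BP) inside the hydrogel:

- **Flow.** The steady laminar profile in a thin straight channel is imposed
  analytically (Poiseuille, `u(y) = ν_c(1 − (2y/h − 1)²)`, no-slip walls):
  for this geometry it is the exact steady solution of the incompressible
  momentum equation, so no numerical flow solve is needed.
- **Hydrogel.** A 200 nm film on the sensing wall with polymer density
  `1 − exp(−100(1 − z))` over relative height `z`; probe concentration scales
  with density; tethered species do not diffuse or advect. Soluble species
  have size-dependent partitioning `Kpart = exp(−1e-3·Mr^{2/3})` and hindered
  in-gel diffusion. Two printed formulas are internally inconsistent with
  their stated physics and are implemented in the physically consistent
  orientation with the literal form behind a flag: bulk diffusion
  `D = D_A·(Mr_A/Mr)^{1/3}` (heavier species diffuse more slowly;
  `size_scaling="literal"` gives the direct ratio) and in-gel diffusion
  `Dgel = D·Kpart/2` (twofold viscosity increase slows diffusion;
  `gel_hindrance="literal"` gives `2·D·Kpart`).
- **Numerics.** Cell-centred finite volumes on a structured grid, uniform
  sub-grid across the gel and geometrically growing rows above it;
  first-order upwind advection and harmonic-mean two-point diffusion fluxes;
  method of lines with the implicit BDF integrator and an explicit Jacobian
  sparsity pattern. Detection is the area-weighted mean BP concentration over
  the gel, converted at 100 RU per mg/ml, sampled at 1 Hz, with optional
  seeded Gaussian baseline noise.
- **Resolution.** The package default grid is 96 columns × 52 rows (20 rows
  across the gel). The surrogate studies run a 40 × 28 grid: halving the grid
  spacing changes the response by < 1% (tested), and the study error tables
  are unchanged to ~0.1% under refinement, so the coarse grid is the
  appropriate working resolution.

The flow-cell height of 20 µm is read as a length (the source text's "µM" is
a unit typo). What the simulator deliberately does *not* emulate: 3-D wall
effects (the channel is wide relative to its height), transient start-up
flow, bulk refractive-index shifts, baseline drift, surface heterogeneity
beyond the gel density profile, and non-specific binding. Passing tests on
surrogate data therefore demonstrate internal consistency of the method under
ideal instrument behaviour, not robustness to every experimental artifact —
double referencing exists in `fitting` precisely because real data need it.

## Fitting

Curve sets are fitted by trust-region nonlinear least squares over all curves
simultaneously. Every parameter carries a role — `fixed`, `global` (one
value for the set) or `local` (one value per curve) — and positive rate
constants are fitted in natural-log space (default bounds 1 to 1e12 M⁻¹s⁻¹
and 1e-7 to 1e6 s⁻¹ expressed through the shared bound table). Jacobians are
finite-difference; fits are deterministic given identical start values, and
an optional multistart list takes the lowest-SSE solution (ties broken by
first encountered). NaN samples in a curve set mark per-curve exclusion
windows. Statistics: `%χ² = 100·RMS(residual)/max(response)` (the
literal squared-average variant is behind a flag; both stay far below the 5%
quality threshold on all self-fits); parameter SE from the Jacobian-based
covariance with singularity flagged; 95% CI = 1.96·SE (normal
approximation), delta-transformed back from log space.

## Study protocols

All dissociation-phase fits use an **early-decay measuring window**: the
first 10 s after injection onset are discarded (development of the
quasi-steady state and of the inhibitor front) and each curve is truncated
once its response falls below 50% of its window-start value. Rationale:
assumption 2 above — the constant-α model degrades as occupancy (hence free
probe) drifts; restricting the fitted span bounds that drift. Blank
calibration curves are fitted **over the same time window as the matching
inhibited curve**, so the calibration absorbs the same occupancy drift as the
measurement; this halves the systematic error of transient-kd recovery
compared with letting each blank choose its own window.

- **Association-rate ladder.** 0.5 mM inhibitor against a pre-loaded surface
  (R₀ = 0.1·Rmax) in a 10 µm channel at 0.15 m/s; serial 1.5-fold ka ladder
  over 2.5 orders of magnitude (15 rungs from 1e5 M⁻¹s⁻¹), the assay's
  single-concentration measuring span; `ka` local per curve, everything else
  fixed at generating or blank-calibrated values; 0.03 RU noise. Reported:
  relative error `1 − true/fitted`, fold error, and the 95% CI of `ka·A` as a
  fraction of the estimate, inside the window `|relative error| < 0.2`.
- **Transient-kd sweep.** 1 mM inhibitor at flow velocities 0.0316, 0.01 and
  0.001 m/s; kd grid spanning two orders (10–1000 s⁻¹, bracketing the
  calibrated `kt` range of 84–264 s⁻¹ where the partition function `f` is
  informative); per-flow blank-calibrated `kt` held fixed — the
  flow-independent coefficient `tc = kt·u^{−1/3}` is reported as the
  transport summary (the cube-root law holds to 2–5% in the simulator; the
  residual deviation is physical, because the hydrogel's own resistance does
  not scale with flow) — then `ka` and `kd` fitted globally per curve set.
- **Starting-occupancy sweep.** The transient-kd protocol (kd = 100 s⁻¹, the
  grid centre) repeated at R₀/Rmax ∈ {0.0156, 0.0312, 0.0625, 0.125} with
  `kd` fixed at truth, isolating the occupancy-induced systematic error of
  `ka`; blanks re-simulated at each occupancy.
- **Saturated start.** R₀ = Rmax with both `ka` and `kd` fitted. With no
  free probe there is no rebinding at the outset, so the constant-α model
  does not apply to the early decay at all; each curve is fitted from its
  downward crossing of 0.25·Rmax (free probe recovered to ≥ 75% of total),
  the boundary of the model's validity domain, and the reported fold error
  quantifies the residual penalty of saturated loading. Transport is
  calibrated from low-occupancy blanks because `kt` is a property of the
  flow cell and hydrogel, not of the loading level. Higher flow velocities
  (0.1–0.01 m/s) are used here: the faster escape shortens the
  rebinding-free transient so more of each curve lies in the valid domain.
- **Monte-Carlo recovery.** (ka, kd) pairs drawn log-uniformly over
  4 ≤ log₁₀ka ≤ 9 and −6 ≤ log₁₀kd ≤ 4; the rebinding format simulates three
  serial tenfold dilutions of inhibitor from 1 mM at two flow velocities
  (0.1 and 0.01 m/s, `tc = 800`) and back-fits `ka`, `kd` globally with `kt`
  fixed; the competitive format uses the Motulsky–Mahan model with six
  dilutions and a moderate-affinity tracer (k₁ = 1e6 M⁻¹s⁻¹, k₂ = 0.05 s⁻¹,
  L = KD/9 = 5.56 nM, matching the 10% starting occupancy of the rebinding
  format). Default 200 draws, 0.06 RU noise, 9-point log-grid multistart per
  fit; failures are recorded per draw, never raised. Affinity-space maps
  tabulate the inhibition window (blank minus inhibited signal, mean of the
  final 4 samples of a 5-minute 1 mM injection) with a 0.5 RU detection
  cutoff.

## Numerical choices and degenerate inputs

- Degenerate model inputs return their analytic limits instead of raising:
  `P = 0` or fully inhibited rebinding give α = 1; `A = 0` gives the
  blank-curve relation; `ka′·P = 0` gives `T_γ = 1`; `kinact = 0` gives
  z = 1. A blank whose observed rate is not below `kd′` returns an
  infinite-`kt` sentinel with a warning (no rebinding detectable).
- The Motulsky–Mahan closed form evaluates its equal-eigenvalue degeneracy by
  the analytic limit rather than by cancelling small differences; it matches
  a stiff ODE oracle to 1e-6 of Rmax over random parameter draws.
- Two-compartment integration: LSODA at rtol 1e-8 (configurable); the ideal
  1:1 limit is taken analytically at `kt = inf`. Dissociation runs start
  from the quasi-steady free-target level `B₀ = kd′·BP₀/(kt + ka′·P)` to
  avoid a spurious initial transient.
- Single-exponential rate extraction seeds a log-linear fit and refines by
  bounded least squares; non-monotone input is fitted anyway but flagged.
- `diffusion_rescale_ka` exposes its exponent (default 1/3, the
  collision-frequency scaling) because mass-ratio normalisations between
  solution- and surface-phase rate constants vary between 1/3 and 1 in
  practice; no single value is hard-coded as truth.

## Known limitations

- The algebraic model's residual systematic error against the virtual
  instrument is ~3–5% for `ka` and `kd` under the study conditions; it grows
  outside the transient window `kt/8 ≲ kd ≲ 4·kt` and with starting occupancy
  (≈ 1.2-fold at R₀ = Rmax even with the windowed protocol).
- `kt` calibration assumes the blank and inhibited curves share transport;
  surfaces with strong non-specific binding would violate this.
- The competitive-format comparator deliberately omits depletion and
  rebinding corrections — it is the plain analytic reference model.
- Experimental workflows (double referencing, threshold normalization,
  loading fits) are implemented and tested on synthetic data only; no
  instrument raw data ship with the package.
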