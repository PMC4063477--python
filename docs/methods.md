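# Methods

## Model structure

The package models a guild of three ground-foraging ant species competing
for discrete, ephemeral food patches in a temperate deciduous forest.
Two timescales are coupled in a hybrid dynamical system:

* **Fast (minutes–hours): patch dynamics.**  Unoccupied patches p₀ appear
  at rate λₛσ(t) (σ the normalized seasonal food-production curve), are
  discovered at per-species pressure Dᵢ = λᵣ rᵢ aᵢ Nᵢ fᵢ(t), may be taken
  over during confrontations according to the takeover matrix W, and are
  removed by the holder's clearance (λ_c cᵢ) or by non-focal species (b).
  Because baits in this system are discovered within minutes and occupancy
  stabilizes within hours, the patch state is assumed to reach its
  quasi-steady state (QSS) within each day.  p₀* has a closed form and the
  occupied densities solve an S×S linear system, triangular in rank order
  under a strict hierarchy.
* **Slow (years): colony demography.**  Colony densities are frozen within
  a year; the yearly food credit of species *i* is the sum of its daily QSS
  patch holdings times its clearance rate, converted to colonies by food
  quality ε′ and by 1/(wᵢaᵢ) (food mass → workers → colonies).  The annual
  map Nᵢ ← Nᵢ + μ(Bᵢ − L Nᵢ) relaxes to the fixed point Nᵢ* = Bᵢ(N*)/L.

Food is credited only when the holder clears a patch; patches lost to
takeover transfer without food credit.  Non-focal clearance b removes both
occupied and unoccupied patches.  Both choices are configurable model
conventions; neither is empirically constrained by the source system.

### Numerical treatment

* The daily QSS systems for a whole (days × microhabitats) batch are
  solved by vectorized Gaussian elimination without pivoting.  The QSS
  matrix is column diagonally dominant with positive diagonal (an
  M-matrix) for any admissible W, which guarantees both stability of the
  elimination and non-negativity of the solution.  The batched solver is
  cross-validated against dense LAPACK solves and against long-time
  integration of the full patch ODEs (relative agreement ≤ 1e−6).
* The annual map uses μ = 0.5/L by default.  Equilibria are invariant to μ
  (verified to ≤ 0.1% over μL ∈ [0.05, 0.5]); μ only sets relaxation
  speed, and 0.5/L converges fastest while remaining stable.  Convergence
  is declared when the largest per-species yearly change falls below 1e−6
  of the community total; communities that decay to less than 1e−12 of
  their initial total are recorded extinct.  Hitting the 2000-year cap is
  flagged per microhabitat, never silently truncated.
* Species are flagged present at equilibrium when their colony share is at
  least 1e−3 of the community.
* A 365-day calendar is used, day 0 = Jan 1; month boundaries at the
  standard cumulative day counts.

## Parameters

| Parameter | Meaning | Default / range | Units |
|---|---|---|---|
| r = (1, 2.2, 1) | relative per-capita discovery rate (Nf, Ar, Pi) | fixed | – |
| c = (1, 6, 17) | relative patch-clearance rate | fixed | – |
| w = (0.1, 1.3, 0.7) | worker mass | fixed | mg |
| a = (137.5, 300, 1200) | foragers per colony | fixed | ants |
| rank | behavioral dominance (subordinate → dominant) | Nf < Ar < Pi | – |
| λₛ | max patch production | U(0, 200) | patches·time⁻¹·area⁻¹ |
| λ_c | inverse patch size | U(0, 200) | time⁻¹ |
| ε′ = ε/μ | food quality | U(0, 2) | ants·mg·time·patches⁻¹ |
| b | non-focal clearance | U(0.1, 0.2) | time⁻¹ |
| λᵣ | discovery scale (defines time/area units) | 1 | area·time⁻¹·ant⁻¹ |

Only an upper bound (< 2.2) is known for the *P. imparis* discovery rate;
the default 1.0 reflects that this species competes through dominance and
fast clearance rather than discovery, and the value is configurable.
Foragers per colony equal observed average colony sizes (midpoint of
125–150 for *N. faisonensis*); the distinction between colony size and
forager force is not resolvable from the source data.

## Abundance currency

The model's state variable is colonies per area, but cross-species
"abundance" comparisons depend strongly on currency because the three
species differ 13× in worker mass and 9× in colony size.  Because
Bᵢ ∝ cᵢ/(wᵢaᵢ), *N. faisonensis* mints ~28–61× more colonies per unit of
food than its competitors, so colony counts are always dominated by it
(baseline colony-share evenness ≈ 0.09) and no parameterization of this
model can make colony counts even.  Standing forager biomass
(wᵢ aᵢ Nᵢ) is the currency under which the model's historical community
is close to even and under which the trait-equalization experiments
reproduce the expected winners and losers; it is therefore the default
reporting currency for ensemble summaries, with colony- and worker-based
summaries also available (`abundance_weights`).  Ensemble averages use
the ratio-of-means convention (ensemble totals) by default, consistent
with percent changes computed on totals; mean-of-ratios is available
behind a flag.  Per-species percent changes between scenarios are
identical under all three currencies.

## Synthetic inputs and what green tests establish

No machine-readable phenology from the original 1970s field studies
survives, so the package ships synthetic approximations as editable text
fixtures:

* per-species monthly foraging curves constrained by the published
  qualitative descriptions (*P. imparis* bimodal with spring and fall
  peaks and a summer trough; *A. rudis* and *N. faisonensis* unimodal with
  mid-summer peaks; *N. faisonensis* intense July–October with slight
  winter activity);
* a 17-knot seasonal food-production curve (understory arthropod
  abundance as proxy), summer-peaked with moderate early-spring and
  late-fall availability;
* a 12-month mid-Atlantic temperature series and Gaussian thermal
  performance curves per species (cool-optimum winter ant, heat-sensitive
  *A. rudis*, broadly warm-tolerant *N. faisonensis*).

These fixtures emulate the *structure* of the real inputs (annual
periodicity, non-negativity, max-normalization, knot grids) but not their
exact values.  Green ensemble tests therefore establish that the
mechanism produces the documented community patterns under a faithful
stand-in world — not that the historical curves have been recovered.
Quantitative comparisons to published ensemble statistics carry wide
tolerance bands for this reason, and several are expected to miss:
in this stand-in world the extended-summer scenarios redirect competitive
pressure onto *P. imparis*'s shoulder-season food rather than onto
*N. faisonensis*, whose biomass dominance makes it nearly invulnerable
here.

## Scenario conventions

* Phenological shifts move spring (Mar–Jul) activity earlier and fall
  (Sep–Jan) activity later by 7×weeks days; August and February are
  continuity buffers where the two shifted branches are blended with
  linear cross-fade weights.  Shifted curves are re-normalized.  The
  transform is applied to both foraging and resource curves.  It is not
  mass-preserving: a summer-unimodal season widens (~+7% integral per
  week) and the bimodal winter-ant season shrinks — this asymmetry *is*
  the extended-summer treatment.
* Warming multiplies daily foraging by the thermal-response ratio at
  warmed vs baseline temperature, clips to [0, 1], and does not
  re-normalize (warming may genuinely depress total activity).  Where the
  baseline response is < 1e−6 the warmed response is used directly,
  avoiding 0/0 at season edges.  Resource phenology is held at baseline.
* Food supplementation adds absolute amounts at the 17 resource knots
  without re-normalization.
* Trait equalization redraws the shared trait value independently for
  every microhabitat, from a random stream separate from the microhabitat
  draws, preserving common random numbers across scenarios.

## Sensitivity analysis

The supplementation analysis draws one Latin hypercube over 21 inputs
(4 microhabitat parameters + 17 supplementation amounts, each uniform on
[0, 1] by default — up to the seasonal maximum of the normalized resource
curve; the range is configurable), runs each sampled system to
equilibrium, and computes partial rank correlation coefficients per
species: rank-transform all columns, regress the focal column's ranks and
the response's ranks on all other columns, and correlate the residuals.
Microhabitat parameters are controlled for as covariates.  Significance
uses a two-sided t test with n − 2 − p degrees of freedom at 90%
confidence; ties take average ranks.  Defaults are n = 100 000 for
headline parity and ~1000–5000 for tests (PRCC standard error ≈ 0.014 at
n = 5000).

## Known limitations

* No spatial structure, daily activity cycles, stochastic colony
  founding/death, within-year colony growth, or age structure.
* Uniqueness of the community equilibrium is not guaranteed; an
  initial-condition robustness sweep (10× up/down) quantifies but does not
  resolve multi-stability, and non-robust microhabitats are logged.
* The thermal-response curves are stand-ins; warming-scenario outputs are
  qualitative.
* Combined shift + warming scenarios are deliberately out of scope.
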