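# Methods

This note documents the models behind `sundaland`, the assumptions and
defaults that matter, what the synthetic data do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Burial dating

### Forward model

A quartz sample carries two nuclide inventories.  The *inherited*
component is the steady-state concentration acquired while the source rock
eroded at rate ε (m/Ma):

    N_inh(ε) = Σ_p  f_p P S / (λ + ρ_src ε / Λ_p)

where P is the total surface production rate, S the site scaling factor,
f_p and Λ_p the fraction and attenuation length (g/cm²) of production
pathway p, ρ_src the source-rock density, and λ the decay constant.  After
deposition the inherited component is fully shielded and decays, while the
*post-burial* component grows as steady denudation at rate E brings the
sample from depth toward its present depth z.  With the sample depth
history z(τ) = z + Eτ (τ = time before present) the production integral
has the closed form used throughout:

    N_post = Σ_p  f_p P S exp(−ρ z/Λ_p) · (1 − e^−(λ+ρE/Λ_p)t) / (λ + ρE/Λ_p)

Assumptions: full shielding of the inherited component during burial
(deep burial), steady pre-burial and post-burial denudation, no
re-exposure episodes, and no isochron-style geometry.

### Constants and defaults

| parameter | default | note |
|---|---|---|
| ¹⁰Be half-life | 1.387 ± 0.012 Ma | standard value |
| ²⁶Al half-life | 0.705 ± 0.024 Ma | standard value |
| SLHL ¹⁰Be spallation production | 4.02 ± 0.32 at/g/yr | AMS-standardization dependent |
| ²⁶Al/¹⁰Be production ratio R₀ | 6.61 ± 0.50 | ²⁶Al production = R₀ × P₁₀ |
| spallation attenuation | 160 g/cm² | |
| muon pathways | 1.5% @ 1500, 0.5% @ 4320 g/cm² | see below |
| sediment density | 2.0 g/cm³ | buried section |
| source-rock density | 2.7 g/cm³ | volcanic source terrain |

Muon production matters here even though it is a small surface fraction:
under fast exhumation (hundreds of m/Ma) the post-burial window samples
metres of depth where spallation is extinguished but muon production is
not.  The two-term exponential muon approximation with literature-standard
attenuation lengths is a deliberate simplification (config-exposed;
`NuclideConstants.spallation_only()` exists for closed-form oracles).  The
muon terms are scaled with the same site factor as spallation, which
slightly overstates tropical muon production; at the few-percent production
fractions used, the effect on recovered ages is well below the reported
uncertainties.

Site scaling uses the published latitude/pressure polynomial scheme with
an ICAO standard-atmosphere elevation-to-pressure conversion.  The literal
polynomial coefficients evaluate to 1.0021 at the sea-level/high-latitude
reference; the implementation divides by that value so the reference
factor is exactly 1 and the production rate keeps its published SLHL
meaning.

### Joint inversion

`JointBurialModel.fit()` minimises

    χ² = Σ_i [ (N10_model,i − N10_i)²/σ10_i² + (N26_model,i − N26_i)²/σ26_i² ]

over the shared burial age t and post-burial rate E, with each sample's
source denudation rate ε_i profiled out: for fixed (t, E) the model is
monotone in ε_i, so a 64-point log-spaced scan over 0.05–2000 m/Ma
followed by a vectorized golden-section refinement (28 iterations,
~10⁻⁶ relative) minimises each sample's contribution independently.  The
outer 2-D problem is solved by bounded Nelder-Mead from 8 Latin-hypercube
starts (t ∈ [0, 7] Ma, E ∈ [0, 2000] m/Ma).  On noiseless synthetic
profiles the generating parameters are recovered to better than 10⁻³
relative.

Uncertainties come from Monte-Carlo resampling (default 1000 draws): the
measured concentrations are perturbed by their reported σ and — by default
— the production constants (P₁₀, R₀, both half-lives) by their printed
uncertainties, then each draw is re-inverted from a warm start using a
cheaper parabolic refinement of the ε profile (the ~10⁻³ precision loss is
irrelevant for a dispersion estimate).  Constants resampling is on by
default because the ratio-decay relation maps the R₀ uncertainty alone to
~0.16 Ma of age uncertainty — without it the reported σ would reflect only
counting statistics and substantially understate the credible interval of
an absolute age.  The recovery experiment (20 synthetic profiles at 5%
noise) uses 200 draws per profile, enough to estimate σ to ~5%.

### Minimum-age end-member and outlier filter

Ignoring post-burial production, the two measurements of a single sample
determine (ε, t) exactly; the solver eliminates t through the ¹⁰Be
equation and finds ε by bracketed root finding (`brentq` on log ε).  A
measured ratio at or above the attainable steady-state ratio returns t = 0
flagged as a boundary solution.  The per-sample minimum ages are combined
by an inverse-variance weighted mean with an iterative chi-square filter:
while χ² of the retained set exceeds the 95% critical value for the
current degrees of freedom, the sample with the largest standardized
residual is removed.

Because the synthetic profiles are generated *with* post-burial
production, their minimum-age pipeline output (≈1.5 Ma at the default
scenario) is systematically younger than the generating 1.78 Ma burial
age — the same joint-versus-minimum offset structure seen in real
fast-exhuming sections, and a useful internal consistency check.

## Landscape evolution

The mass-continuity equation combines uplift, linear soil-creep diffusion,
and detachment-limited stream-power incision; the incision and diffusion
terms *lower* elevation where slope and curvature demand erosion (the
equation is integrated in that standard sign convention).  Numerics per
time step (default dt = 100 yr over 10 kyr):

1. uplift added explicitly on non-ocean cells — the ocean is the fixed
   base level (holding the seafloor also prevents open-boundary edge pits
   from rising indefinitely and destroying the base level);
2. explicit diffusion with no-flux edges (mass conserving); the CFL bound
   dt ≤ Δx²/4κ is checked and violations raise an error naming the
   maximum admissible dt;
3. D8 re-routing: ocean = cells at/below sea level connected to the grid
   edge; interior depressions (priority flood) are endorheic lakes whose
   inflow terminates at their pits — flow never crosses a lake rim;
4. implicit stream-power incision ordered receiver-before-donor
   (unconditionally stable for n = 1; doubling dt changes the outcome by
   <1% on the test fixtures), applied to land cells only, with
   K = ε_K P^d (PA)^m, PA in m³/yr internally and converted to m³/s only
   at the water-bodies/resistance interface;
5. the eroded volume of the step is deposited uniformly over lake cells
   (a simple mass-conserving sink; flux reaching the ocean is exported
   and recorded in the mass-balance dictionary).  Full transport-limited
   sedimentation is out of scope.

The erodibility is treated, as in large-scale landscape models, as a
dimensional calibration constant absorbing the units of P^d (PA)^m.

## Resistance surface

Costs follow the printed endpoint table exactly (barriers 1.0; rivers
0.70 at 5.5×10³ m³/s rising linearly to 0.95 at the largest modelled
discharge; slope 0 / 0.1→0.6 / 0.8 across 0.5° and 5°).  Choices the
endpoint table does not fix:

* **Combination rule** — elementwise maximum of the slope and
  water-distance components (preserves every printed endpoint and keeps
  the surface normalized); a clipped sum is selectable.
* **Water-distance cost** — cost = c_max (1 − e^(−d/L)) with invented
  defaults L = 20 km, c_max = 0.6; both config-exposed, and no acceptance
  quantity depends on them.  Distance is measured to the nearest water
  cell minus one cell width, so land cells bordering water (coastlines)
  are costless — coasts act as preferential pathways.
* **Shoreline slope** — slope is evaluated on a surface whose water cells
  take the elevation of the nearest land cell, so submarine scarps do not
  penalize beach cells.
* **River cells** carry the crossing cost only (not the slope/distance
  components); `auto_cap` recomputes the 0.95 endpoint at the domain
  maximum discharge so it is attained on miniature domains.

## Walker

The two-state walker follows the published mechanistic-model concept
(state-switching Markov chain, wrapped-normal turning kernel,
perceptual-range sensitivity) with these documented approximations:

* **Discrete headings.**  Both the turning kernel and the
  perceptual-range weighting live on the same n = 24 heading lattice.
  The wrapped-normal pmf is evaluated from its theta-series using the
  mean-resultant-length parameterization (0.99 for the travelling state,
  0 for the exploratory state).
* **Perception.**  w(θ) = 1 − mean resistance along the ray of length
  5 km in direction θ, sampled at half-cell spacing (off-grid samples
  count as barriers); heading probabilities are the turning pmf times
  w(θ).  Ray weights are precomputed per cell.
* **Barrier handling.**  Headings whose destination cell is a barrier or
  off-grid get zero probability before a single categorical draw; if all
  headings are blocked the walker stays in place.  This is the
  deterministic equivalent of resample-with-retries and fixes the random
  consumption at exactly two uniforms per step, which is what makes
  realization i reproducible from seed ⊕ i alone, independent of batch
  composition.  Domain edges therefore block like barriers.
* **Speed modulation.**  Displacement = 100 m × (1 − local resistance),
  realizing slower progression in complex landscapes; travelled distances
  therefore undercount step_length × steps wherever resistance is
  nonzero.
* **Goal.**  Arrival is first entry within a goal radius (default 10 km,
  config-exposed).

Ensemble occupancy weights the per-cell visit counts of successful
realizations by (1 − cost) — bounded and order-preserving where a literal
inverse cost diverges at zero; 1/(cost+0.05) is selectable — then smooths
with an isotropic Gaussian (default bandwidth two cell widths), zeroes
barriers, and normalizes to unit integral.  Every recorded step of a
successful trajectory counts, including stay-in-place steps, so occupancy
also reflects time spent, not only ground covered.

## Synthetic data and problem sizes

The landscape generator emulates a drowned-shelf physiography as a fixed
template: ocean along the west, a gently ramping lowland corridor through
the centre, rough highlands in the east (slopes beyond the 5° cost knee),
and one carved interior depression guaranteeing an endorheic lake.
Smoothed-box-filtered Gaussian noise supplies relief texture.  It does
*not* attempt real coastline geometry, vegetation, climate fields beyond a
linear precipitation gradient, or eustatic cycling — so passing tests
demonstrate the correctness and calibration of the method chain, not the
realism of any particular paleogeography.

Default study conditions: 200×200 cells at 1 km, sea level −30 m,
nuclide profiles of 15 depths over 0.2–5.8 m generated at burial age
1.78 Ma, post-burial denudation 436 m/Ma, per-sample source denudation
drawn from 21–80 m/Ma, 5% relative lognormal noise (multiplicative,
matching the relative character of AMS counting uncertainties).

The end-to-end experiment runs three fixed northern entry points against
a southern goal (10 km radius) with 100 walkers × 2×10⁵ steps per entry —
a deliberate miniature of a full-scale study (10³ walkers × 5×10⁶ steps
on a continent-sized grid), sized so the whole chain completes in a few
minutes on one CPU.  On this 200-km domain the full-scale Niger-class
river threshold exceeds any attainable discharge, so the experiment uses a
50 m³/s threshold that selects the miniature's trunk streams, with the
river-cost cap at the domain maximum.  Entry/goal placement and the
corridor band used in the occupancy contrast are part of the fixture
design, chosen once on the landscape template.

## Known limitations

* One shared production-pathway set for both nuclides; no isochron mode;
  no geomagnetic/time-dependent scaling.
* The LEM has no flexure, no sediment routing beyond the lake sink, and
  n = 1 only (the implicit solver requires it; other n raise).
* The walker has no memory beyond one step, no demographic or habitat
  states; success criteria are radius-based.
* Lakes never re-drain once deposition fills them within a run (routing
  is recomputed each step, so a filled lake simply stops being a
  depression).
* GeoTIFF I/O covers single-band float32 rasters with the pixel-scale,
  tiepoint and nodata tags only — not tiled, multi-band, or CRS-tagged
  files.
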