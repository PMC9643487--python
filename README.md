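# sundaland

Burial dating and landscape-conditioned dispersal simulation for
paleobiogeography.

The package addresses a two-part problem faced when reconstructing the
arrival of early hominins on a drowned continental shelf such as Sundaland:
*when* a sedimentary horizon was deposited, and *how* a walking species
could have crossed the intervening landscape.  It is written for
geochronologists and movement ecologists who want both halves of that
workflow — cosmogenic-nuclide burial dating and resistance-based movement
simulation — as one tested, scriptable toolchain that runs end-to-end on
synthetic data with known ground truth.

## What it computes

**Burial dating (`sundaland.tcn`).**  In-situ cosmogenic ²⁶Al and ¹⁰Be
accumulate in quartz during exhumation and decay after burial, ²⁶Al about
twice as fast as ¹⁰Be (half-lives 0.705 and 1.387 Ma).  A sample's
concentrations are modelled as

    N(z, t) = N_inh(ε) e^(−λt) + Σ_p P_p S exp(−ρz/Λ_p) (1 − e^(−(λ+ρE/Λ_p)t)) / (λ + ρE/Λ_p)

with inheritance `N_inh(ε) = Σ_p P_p S / (λ + ρ_src ε/Λ_p)` set by the
steady-state source denudation rate ε, post-burial production governed by
the shared denudation rate E that advects the sample toward the surface,
production pathways p (spallation plus two muon terms, attenuation lengths
Λ_p), and site scaling S from the latitude/pressure polynomial scheme.
`JointBurialModel.fit()` inverts a whole depth profile for a common burial
age t and post-burial rate E (per-sample ε profiled out), with Monte-Carlo
uncertainties; `MinimumBurialModel` solves the no-post-production
end-member exactly, and `weighted_mean_with_outliers` applies the
chi-square outlier filter to a set of minimum ages.

**Landscape evolution (`sundaland.lem`).**  Elevation evolves by

    ∂z/∂t = U + κ∇²z − ε_K P^d (PA)^m S^n        (n = 1, implicit solver)

with uplift U, soil-creep diffusivity κ = 5×10⁻³ m²/yr, stream-power
erodibility ε_K = 4×10⁻⁶, m = 0.5, precipitation exponent d = 0.42, and
water flux PA accumulated by D8 routing with endorheic lakes (priority
flood) and ocean base level at −30 m.

**Resistance mapping (`sundaland.resistance`).**  Ocean and lakes are
absolute barriers (cost 1.0); rivers above a Niger-scale discharge
threshold (5.5×10³ m³/s) cost 0.70–0.95 linearly up to the largest
modelled discharge; slope costs 0 below 0.5°, 0.1→0.6 linearly to 5°, and
0.8 above; distance to freshwater adds an exponentially saturating term.

**Dispersal (`sundaland.walk`, `sundaland.trajstats`).**  Either Dijkstra
least-cost paths (the omniscient-traveller reference) or a two-state
Markov walker: a strongly correlated travelling state (wrapped-normal
turning concentration 0.99) and an uncorrelated exploratory state, with
switch probabilities 0.01/0.002, 100 m steps modulated by local
resistance, and heading choice biased by the mean resistance sensed along
rays within a 5 km perceptual range.  Ensembles yield success rates
(Wilson intervals), travelled-distance distributions, travel times under
slow/medium/fast migration speeds (1/5/10 km/yr), and a cost-weighted
occupancy kernel density.

`sundaland.synthetic` generates every input — shelf landscapes with a
lowland corridor and nuclide depth profiles drawn from the forward model —
so the whole chain is testable without external data, and
`sundaland.pipeline` wires the stages into one experiment.

## Worked example

Date a synthetic depth profile generated at a burial age of 1.78 Ma with
436 m/Ma of post-burial denudation and 5% measurement noise:

```python
from sundaland import synthetic, tcn

scenario = synthetic.ProfileScenario(seed=7, relative_noise=0.05)
table = synthetic.make_profiles(scenario)          # pandas DataFrame
site = tcn.SiteContext(latitude=-7.466, elevation=99.0)
model = tcn.JointBurialModel.from_dataframe(table, site)
results = model.fit(n_mc=500, seed=0)
print(results.summary())
```

```
Joint 26Al/10Be burial inversion
==============================================
samples                         15
burial age (Ma)              1.663 +/- 0.210
post-burial denudation       582.9 m/Ma  (16-84%: 447-780)
pre-burial denudation         23.2 - 81.3 m/Ma
chi2 / dof                    9.69 / 13
Monte-Carlo resamples          500 (seed 0)
```

The generating burial age (1.78 Ma) lies inside the reported 1σ interval;
chi-square per degree of freedom near 1 says the 5% noise level is fitted
consistently.  `results.post_burial_fractions()` reports how much of each
modelled concentration accumulated after burial — 20% (¹⁰Be) and 36%
(²⁶Al) at the shallowest sample here — the diagnostic separating this
"burial with post-production" model from plain two-nuclide decay dating.

The dispersal half runs the same way from Python
(`sundaland.pipeline.run_corridor_experiment()`) or the shell:

```bash
sundaland simulate-profile --seed 3 --out profile.csv
sundaland invert-joint profile.csv
sundaland cost-build --elevation z.asc --precipitation p.asc --out cost.asc
sundaland walk-batch --resistance cost.asc --sites sites.csv \
    --start central --goal goal --n 100 --max-steps 200000
```

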