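# Methods

This note records the models implemented in `enashift`, the defaults and
why they were chosen, the numerical choices, and what the synthetic inputs
do and do not emulate.

## Mass balance

The static web follows the Ecopath bookkeeping convention.  For every
living group i,

    B_i · PB_i · EE_i = Σ_j B_j · QB_j · DC_ij + Y_i ,

where `DC_ij` is the fraction of predator j's diet on prey i and `Y_i` the
summed landings.  `check_mass_balance` reports the residual
`B·PB·EE − (predation + catch)` (negative when allocated production exceeds
what is available); `solve_missing_ee` inverts the identity for unknown
EEs and refuses webs with EE > 1, naming the offending group.  Biomass
accumulation and migration are held at zero in the static balance; they
live in the dynamic model as the `e`/`I` terms.

Fractional trophic levels solve `TL_i = 1 + Σ_j DC_ji·TL_j` with producers,
detritus and imported food at TL 1.

`to_flow_network` expands a balanced web into an (n+3)×(n+3) flow matrix
with import, export and dissipation boundary nodes.  Primary production
enters producers from the import node (so the boundary input equals imports
plus primary production, which simplifies mean path length below).
Consumer respiration is `(1−GS)·Q − B·PB`; if inconsistent inputs make this
negative it is floored at zero with a warning rather than rejected, keeping
the network valid for ENA while surfacing the bad input.  Egestion `GS·Q`
and non-predation deaths `(1−EE)·B·PB` are split across the detritus pools
by an explicit routing table (fixture default 50/50, since the relative
sizes of the sediment and water-column detrital inflows are not constrained
by the inputs).  Each detritus pool is closed against the boundary: surplus
inflow leaves as export (burial), deficit enters as import.

## Dynamics

Consumers follow

    dB_i/dt = g_i Σ_j Q_ji − Σ_j Q_ij + I_i − (M0_i + F_i(t) + e_i) B_i ,

with `g_i` the net growth efficiency (production/consumption).  Consumption
uses the foraging-arena closure

    Q_ij = a_ij · v_ij · B_i · B_j / (2 v_ij + a_ij B_j) ,

increasing and concave in predator biomass with asymptote `v_ij·B_i`.  The
exchange rate and search rate are back-solved from the baseline flows and a
dimensionless vulnerability multiplier k ≥ 1 (`v = 2k·Q0/B_i0`,
`a = 2v/(B_j0(2k−1))`), so that the predation mortality exerted by a
predator saturates at `2k` times baseline — low k means bottom-up
(donor-controlled) links, high k top-down ones.  The fixture uses k = 2
everywhere except links into the cod stages (k = 3), standing in for the
shape of a fitted vulnerability table.

Producers replace the consumption gain with a saturating production term
`P(B) = pp(t) · 2·PB·B / (1 + B/B0)`, which equals `PB·B0` at baseline and
caps at twice the baseline rate; the saturation provides the producer
self-limitation that keeps the equilibrium attracting.  Detritus pools are
donor-driven: egestion and deaths in, consumption and a calibrated
burial/export rate out.  Multi-stanza fish (cod larvae → juvenile → small →
adult; juvenile → adult sprat and herring) are linked by fixed graduation
rates moving biomass source → sink; the full age-structured stanza
machinery is out of scope and the simplification is compensated by the
calibration below.

`M0_i` (and the detritus burial rates) are not inputs: they are back-solved
so that every derivative is exactly zero at the balanced state under
baseline forcing.  This makes the key structural property — baseline
forcing ⇒ stationary biomasses — hold by construction rather than by
trusting hand inputs, and it is verified to 1e-4 relative over 33 simulated
years in the acceptance suite.

Forcing is annual and stepwise-constant within the year: absolute fishing
mortalities per group, a primary-production multiplier, and optional named
multipliers on individual trophic links.  Which environmental driver scales
which link is deliberately a per-run configuration choice, not a built-in
mapping.

### Integration

A fixed-step fourth-order Runge–Kutta scheme advances the state, with
yearly outputs on a monthly (or finer) reporting grid: yearly biomass is
the within-year mean, yearly flows are accumulated integrals.  Plankton
parameters make the system stiff (per-capita rates up to ~300 yr⁻¹ in the
fixture), far outside the stability region of a monthly explicit step, so
the integrator derives its internal sub-step count from the fastest
per-capita rate in the web (1.2 × the maximum of `PB·pp + QB·env + M0 +
F + e + burial + graduation`, ≈364 steps/yr for the fixture).  This keeps
the scheme deterministic and reproducible while making it stable for any
web the generators produce.  Biomass is floored at 1e-9 of baseline with a
warning; halving the step changes yearly biomasses by < 1e-5 relative once
inside the stable regime.

## Indicators

All information indices use log base 2 (bits) and include boundary flows,
after Ulanowicz:

* `AMI = Σ (T_ij/TST)·log2(T_ij·TST/(T_i·T_j))`, `H` its Shannon upper
  bound, `A = TST·AMI`, `C = TST·H`.
* Overhead decomposes exactly into import, export, dissipation and internal
  (redundancy) parts; `A + overheads = C` holds to machine precision and is
  asserted on every generated web.  Redundancy is reported both in
  flow-bits and as % of C; the shift analysis uses % of C, and both scales
  are written to the CV table since either may be wanted for regime
  comparison.
* Cycling follows Finn's structure matrix `N = (I − G)⁻¹` with
  `G_ij = T_ij/T_j` (input-fraction convention); the cycled fraction is
  `Σ_i ((N_ii−1)/N_ii)·T_i / TST`.  The predatory cycle index is the same
  quantity on the subnetwork with detritus pools (and all their flows)
  removed, i.e. recycling through living compartments only.  Both are
  verified against a truncated walk-enumeration oracle on small networks.
* `MPL = TST / total boundary input` (Finn's convention; with primary
  production entering as import the denominator is the import row sum).
* `PPR` back-traces each caught unit through the diet-proportioned flow
  graph: one unit of group i's production requires `1/g_i` units of prey
  production apportioned by diet, producers and detritus count as primary
  sources, imported food as external; cycles are handled by solving the
  linear system.  Reported as a fraction of total primary production.
* Kempton's Q uses groups with TL ≥ 3 (threshold configurable), ranked by
  descending biomass; `Q = (S/2)/log10(B_25/B_75)` with the quartile
  biomasses log-interpolated on the dominance curve.

Undefined values (zero catch → mTLc, fewer than two upper-trophic groups →
Q, zero respiration → TPP/TR) propagate as explicit missing values, never
silent zeros.

## Shift detection

**STARS** implements Rodionov's sequential t-test with the original
mean-shift algorithm (no red-noise prewhitening): detection threshold
`diff = t_{1−α/2, 2l−2} · sqrt(2σ_l²/l)` with `σ_l²` the average variance
of all sliding l-year windows (sample variance); a candidate shift is
confirmed iff the cumulative regime shift index over the following l years
stays positive.  Outliers beyond `h` standard deviations are Huber
down-weighted, symmetrically, both in regime means and in the RSI.
Defaults: α = 0.05, l = 5 for forcing and indicator series, l = 10 for
biomass series, h = 3.  Shifts that can only be confirmed within the final
l years are reported with an `end_truncated` flag rather than dropped, and
excluded from `confirmed_years`.  Regime means are emitted Huber-weighted
(default) and raw.  Measured operating characteristics at the shipped
conditions (33-year series): a 3-SD step is recovered within ±1 year in
≈94–95% of seeds — the residual being the method's own ±2-year dispersion
under noise — and the white-noise confirmed-shift rate is ≈5–6%, well
within twice the nominal level.

**PCA** is standardised (correlation-matrix) PCA of ln(x+1)-transformed
series; variables that can be negative (anomalies) use the sign-preserving
`sign(x)·ln(1+|x|)`.  Components are oriented so the largest-|loading|
variable loads positively, making loadings and score trajectories
reproducible.  PC1 of a forcing block serves as the pressure index, PC1 of
a biomass block as the state index; STARS on the scores dates their shifts.

**Chronological clustering** z-scores the variables, compares years by
Euclidean distance, and agglomerates under a temporal-contiguity
constraint.  The linkage between adjacent groups is the
connectedness-quantile of their cross distances (50% = median linkage); a
candidate fusion is refused when a permutation test (999 permutations of
the pooled years, fresh draws from the config seed) finds the observed
linkage significantly large at α (default 0.01, the clustering-intensity
level).  Two prescriptions of the original method temper spurious
boundaries: a refusal whose smaller side is a single year marks that year
as an outlier, not a boundary; and refusals are re-tested whenever either
side's composition changes, so a boundary stands only if the rejection
persists against the final neighbouring segments.  Measured at the shipped
conditions: two 10-year blocks 10 noise-SD apart yield exactly the junction
boundary in ≈98% of seeds (the rest carry one extra boundary from chance
multivariate clumping that genuinely rejects at α = 0.01); homogeneous
20–33-year noise stays a single segment in ≈97% of seeds.

**Traffic-light tables** bin each variable's own series into quintiles by
rank (ties to the lower bin), rows ordered by PC1 loading descending, with
the conventional green-to-red palette.  **Coefficients of variation** are
sample SD over |mean| per closed year interval (e.g. 1974–89 means
1974..1989 inclusive); a zero mean gives an explicit missing value.
**Anomalies** subtract either the first value or the period mean.

## Synthetic inputs

`make_random_web` draws cascade-ordered webs (predators eat lower-indexed
groups and detritus) with rates in field-plausible ranges, then caps the
demand on any prey at 90% of its production by shaving diet fractions into
the import term — so every generated web balances by construction with
EE ≤ 0.9.  These webs exercise the ENA identities across sizes and
connectances.

`make_baltic_fixture` reproduces the *shape* of a Central Baltic food-web
model: 21 groups (cyanobacteria and phytoplankton as producers; micro-,
meso- and three named copepod groups; mysids; meio- and macrozoobenthos;
sprat, herring and cod as multi-stanza fish; seals; sediment and
water-column detritus), three fleets (cod, sprat, herring), and five stanza
links.  Its biomasses, rates, diets and vulnerabilities are synthetic
placeholders chosen for balance and plausible trophic structure — they are
not a calibrated Baltic model, and indicator levels computed from them are
properties of the fixture, not of any real sea.  The biomass shift analysis
excludes seals (a forcing-like group) and both detritus pools by default,
leaving 18 series.

`make_forcing_scenario` builds piecewise-constant forcing levels with steps
at given years plus stationary AR(1) noise; `make_block_series` builds the
two-block multivariate Gaussian test bed for the clustering and PCA
properties.  Default scenario span is 33 years starting 1974, matching the
annual, three-decade setting the pipeline targets.

What passing tests show — and do not.  The generators produce exact step
changes with Gaussian (optionally AR(1)) noise, stationary within regimes.
Real forcing and biomass series carry trends, seasonality aliased into
annual means, observation error correlated across series, and transitions
that are gradual rather than discrete; detector performance measured here
(STARS ≈95% step recovery, CC ≈98% block recovery) is an upper bound on
what such cleaner conditions allow and does not certify behaviour on
trending or autocorrelated-beyond-AR(1) data.

## Pipeline

`run_pipeline` chains three analyses: (i) screening of the forcing series
themselves, (ii) screening of the simulated biomasses (longer STARS cut-off
since biomass integrates forcing), (iii) yearly indicators with STARS,
chronological clustering and per-regime CVs.  Constant series are dropped
from screening (a relative-variation filter at 1e-9 distinguishes genuine
constancy from floating-point jitter).  One config seed drives every
stochastic stage; the JSON manifest records that seed and a hash of the
configuration (excluding the output directory), and identical config + seed
reproduces the bundle byte for byte.  All tables are delimited text with a
units header; flow networks can be exchanged in SCOR format.

## Known limitations

* No seasonality; forcing is stepwise-constant within years.
* Stanza links are fixed-rate biomass transfers, not age-structured
  recruitment; strong perturbations of stanza chains redistribute biomass
  less realistically than full stanza models.
* PPR can in principle exceed total primary production in heavily
  detritus-subsidised webs, since detritus counts as a primary source.
* The chronological-clustering permutation test is calibrated per fusion,
  not familywise; on long homogeneous series occasional boundaries at the
  chosen α are expected behaviour, not bugs.
* Vulnerability multipliers are inputs; nothing here fits them to data.
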