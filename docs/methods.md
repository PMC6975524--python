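# Methods

## Model structure

A simulation step at SLR increment `x` has three stages.

**Partition.** Exposure arrives as a table of sub-zone records (a block-group
analogue): for each sub-zone and increment, its population and the portion
living on land flooded at that increment. The affected half of a zone,
`θ_i^A`, is the sum of its sub-zones' affected populations at `x`; the
unaffected half `θ_i^U` is the remainder, so the two halves conserve the zone
population exactly. Exposure must be *nested*: a sub-zone's affected
population is nondecreasing in the increment (validated on load). Zones with
`θ_i^U = 0` are fully flooded — they still emit climate migrants but are
removed from every destination universe. Both halves inherit the parent
centroid, since no sub-zone geometry survives the tabular exposure format.

**Flows.** Climate flows route `θ^A → θ^U` with identity production; the
intra-zone pair (`θ_i^A → θ_i^U`) is allowed and is assigned a fixed
intra-zone distance (default 1 km, strictly positive so distance-decay
weights stay finite) and zero intervening opportunities. Business-as-usual
flows route `θ^U → θ^U` with rate 0.03/yr, self-pairs excluded. Rows are
normalised over the offered destination set (closed system), replacing the
open-system radiation normalisation `1/(1 − m_i/M)`: the framework defines
`P_ij` as a distribution over destinations, and every produced migrant must
settle somewhere in the modelled region.

**Effects.** Direct = `Σ_i θ_i^A`. Indirect: county `j` is flagged at
threshold `d`% when `incoming_scenario(j) − incoming_baseline(j) >
(d/100)·pop(j)` (strict inequality), where the baseline is the same system
with zero flooding and only business-as-usual flows. Intra-county arrivals
(`θ_j^A → θ_j^U`) are excluded from the incoming count by default: those
people are existing residents, and counting them would flag every flooded
county as indirectly affected, erasing the direct/indirect distinction. The
switch `exclude_intra_county=False` restores the inclusive count. The `d%`
threshold references the step's projected county population. Flags nest by
construction: flagged at 9% implies flagged at every smaller `d`.

## Scenario timelines and modes

Built-in timelines: medium (0.3/0.6/0.9 m in 2055/2080/2100) and high
(0.3–1.8 m in 2042/2059/2071/2082/2091/2100); custom schedules load from
JSON. `timeline_lookup` is a nondecreasing step function of the year.

Two orthogonal run modes:

- **Population mode.** `exogenous` (default) re-reads each step's populations
  from the input projections and uses the *total* affected population at the
  step's increment — appropriate when the projections already embed
  demography, and matching per-increment reporting. `compounded` carries net
  migration forward: the affected population at step `t` is the increment
  over the previous step (people cannot be displaced twice), arrivals join
  the destination's `θ^U` and are eligible for later migration, and total
  population is conserved to machine precision. The exogenous default
  reflects that the projection feedback loop is conceptual, not a fitted
  dynamic.
- **Model mode.** `dual` uses the separately trained climate model for `T′`;
  `single` is the ablation that routes climate flows through the
  business-as-usual model, quantifying what the separation buys.

## Mobility models

All models consume the same feature rows `(m_i, m_j, d_ij, s_ij)`. Distances
are haversine between parent-zone centroids (Earth radius 6371.0 km); a
precomputed distance matrix can override them (used by the planar toy
geometries in the tests). `s_ij` sums the `θ^U` populations of third zones
strictly closer to the origin than the destination — strict inequality, so
boundary ties are excluded and the toy enumerations are deterministic; the
flooded portions of third zones are not opportunities. The implementation
sorts zones by distance per origin and uses prefix sums
(O(n² log n) overall); tests compare it against a direct scan.

The **extended radiation** weight with exponent `α > 0` is

    w = [((m_i+m_j+s)^α − (m_i+s)^α)(m_i^α + 1)] / [((m_i+s)^α + 1)((m_i+m_j+s)^α + 1)]

which approaches the radiation weight as populations grow at `α = 1` (tested
at m = 10⁶, relative gap < 10⁻⁴). A `DistanceTiltedModel` multiplies any
base model's weight by `exp(−d/λ)` (default λ = 200 km), emulating the
short-range bias of post-disaster displacement.

The **neural scorer** is a fully connected network (default two hidden tanh
layers of 64 units, linear output) over standardised
`(log1p m_i, log1p m_j, log1p d, log1p s)`. The probability row is the
per-origin softmax of the scores; the loss is the multinomial cross-entropy
between the softmax rows and observed per-origin flow shares, each origin
weighted by its outflow; pairs absent from the flow table are observed
zeros. Optimisation is full-batch Adam (lr 0.01, up to 800 epochs) with
early stopping on a 15% held-out origin split evaluated every 10 epochs
(patience 40 evaluations). The architecture, loss and normalisation are this
package's design choices — nothing in the framework pins them — and all
hyperparameters are constructor arguments. Weight initialisation and the
origin split derive from a single seed; refitting with the same data and
seed is bit-for-bit reproducible. Models persist as plain JSON (Python float
repr round-trips exactly).

Degenerate inputs: an origin whose destinations all carry zero weight gets a
uniform row with a warning (a forced migrant goes *somewhere*); a
single-destination origin gets probability 1; an all-zero training flow
table is rejected. The gravity model is deliberately not implemented; the
`MigrationModel` base class is the extension hook.

## Shock filter

Given two consecutive years of flows and coastal flags, a county is flagged
when it is coastal, its outgoing total rose by more than 100%, and its
*current-year* outgoing total exceeds 1,000 migrants. The floor is applied
to the shock year because that is when the elevated outflow exists; the
comparison uses whatever rows the tables contain (inter-county by
construction). Zero previous outflow counts as an infinite increase
(flagged with a warning if the other criteria hold). A manual exclusion
list handles shocks with known non-climate causes. The training split sends
(shocked origin → unshocked destination) pairs to the climate model,
(unshocked → unshocked) pairs to the business-as-usual model, and drops
pairs with shocked destinations — arrivals into a disaster zone are neither
process.

## Synthetic data

`generate_region` places `n` zones (default 200, one county per zone)
uniformly in a rectangular box with the coastline along the southern edge;
the lowest-latitude 30% are coastal. Populations are log-normal (μ = 9,
σ = 1; median ≈ 8,100 — county-like). Each zone splits into 1–4 sub-zones by
a Dirichlet share; the affected fraction at increment `x` is
`0.8 · (x/1.8)^1.5 · exp(−dist_inland/30 km)` times a per-sub-zone
vulnerability multiplier that is constant across increments, so nesting
holds by construction and inland zones have exactly zero exposure.
`generate_flows` draws, per origin, a multinomial of size `round(rate·m_i)`
over a generating model's row — extended radiation (α = 0.5) for
business-as-usual, its distance-tilted variant for climate flows, so the
dual-model machinery has a real signal to separate. `inject_shock` scales
selected counties' outgoing totals by a multiplier > 1 and redistributes the
extra migrants over a distance-tilted row. All randomness flows through
explicitly passed seeds; no global state.

What the generator does *not* emulate: real US geography and road networks,
spatial autocorrelation of population, economic covariates of migration,
multi-zone counties, or the IRS reporting quirks (suppression of small
flows, the 2010–2011 methodology break). Passing tests therefore demonstrate
internal consistency and recoverability of the framework's mechanisms under
its own assumptions, not predictive skill on real migration data.

## Problem sizes and numerics

The test and acceptance fixtures use a 200-zone region (≈ 40,000 ordered
pairs) for the conservation, recovery and ablation checks and a 40-zone
region for pipeline smoke tests; these sizes give stable statistics while
keeping a full run to minutes on one CPU. Conservation of production is
exact to float rounding (observed ≲ 10⁻¹⁵ relative); probability rows sum to
1 within 10⁻⁹; population halves are reals (projections are fractional),
with integer rounding only on request. Neural recovery of a generating
extended-radiation model scores CPC ≈ 0.97 on held-out origins; the
dual-vs-single ablation differs at CPC ≈ 0.83–0.91, confirming the model
separation is consequential at this scale.

## Known limitations

No destination capacity constraints, return migration, or within-year
dynamics; exposure must arrive pre-processed (no inundation modelling);
flooded land area is not tracked (no geometry is ingested); indirect-effect
flags are sensitive to the baseline model choice, which is shared between
scenario and baseline by construction.
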