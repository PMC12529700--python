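# Methods

## The estimation problem

A cattle population's biomass and stock value are sums of individual
liveweights and market values, but national data systems record neither
for the standing population — only for animals at slaughter valuation
(weight and assessed value) and at marts (price by sale category). What
the registration/movement system does record, for every animal, is sex,
breed, date of birth and the herd it is in on any given day. `herdmass`
bridges the two: it learns weight-for-age and value-for-age curves from
the valued animals and transfers them to the whole population through
the movement records.

## Liveweight and value models

For each sex and each response (liveweight in kg, value in €) we fit a
segmented linear regression in age `t` (days):

    E[y] = β0 + β1 t + Σ_k δ_k (t − ψ_k)+ + breed + month + year

- `(x)+ = max(x, 0)`, so the curve is continuous and piecewise linear
  with slope `β1 + Σ_{j≤k} δ_j` right of break-point `ψ_k`.
- Breed category (dairy / continental beef / British-Irish beef),
  calendar month and year enter as unordered categorical offsets with
  the earliest level as reference. Predictions at levels unseen during
  fitting use the reference level and log a warning (needed when
  predicting months/years absent from the training data).
- Separate models per sex: growth trajectories and price formation
  differ enough between males and females that pooling biases both.

**Estimation.** Break-points are estimated by iterative linearization:
given current `ψ`, regress on `{1, t, (t−ψ_k)+, −1{t>ψ_k}, dummies}`;
the coefficient ratio (indicator / slope-change) is the first-order
update to each `ψ_k`. Updates are step-halved until the break-points
stay ordered and interior; a component whose slope-change coefficient is
numerically zero is frozen (its break-point is unidentified at that
step). Convergence is declared when the largest move falls below `tol`
(default 1e-4 of the age range) within `max_iter` (default 50)
iterations. Break-points are kept at least five observations away from
either end of the age distribution — boundary break-points are
unidentifiable and produce arbitrary slope estimates.

On failure the fitter falls back to a profiled grid search on a 1-day
age lattice: with `ψ` fixed the model is linear, so the residual sum of
squares is profiled by projecting each hinge column onto the orthogonal
complement of the current design (incremental Gram–Schmidt). `K = 1`
and small lattices are searched exhaustively; larger multi-break
problems use a coarse exhaustive pass (~120 lattice points) followed by
two coordinate-wise refinement sweeps at 1-day resolution. The
exhaustive search also serves as the independent oracle in the test
suite, which requires the iterative RSS to match it within 0.1% on
small instances.

**Choosing the number of break-points.** K is incremented from 1 to 3;
the selected K is the smallest whose successor improves R² by less than
`delta_r2_threshold` (default 0.01 — "minor improvement" is not an
objective quantity, so the threshold is exposed in configuration). Each
K+1 fit is additionally warm-started from the chosen K's break-points
plus a point in the widest remaining gap, keeping R² non-decreasing in
K in practice. All candidate fits are retained on the returned object
for audit.

**Training samples.** Models are trained on samples stratified by the
six animal classes (calf, heifer, steer, bull, cow, pregnant heifer)
with equal numbers per class — 600/class (3,600) for liveweight and
1,000/class (6,000) for value by default — so that no class dominates
the age axis; the class sizes are bounded by the least frequent class.

## Cleaning rules

Slaughter records are retained when complete (value present and
non-zero, liveweight, dates of birth and death, sex, breed), inside the
liveweight windows 30–1,400 kg (calves, heifers, steers) and 200–1,400
kg (bulls, cows, pregnant heifers) — both endpoints read as inclusive —
and when the breed code resolves. Cross codes (terminal `X`, e.g.
`FRX`) resolve to the sire breed before lookup. Each dropped record is
attributed to the first rule it fails (completeness → window → breed),
so per-rule counts sum to the total. The packaged breed map is built
from common herdbook code conventions and is user-replaceable; the
operational national list is not public.

## Population snapshots

The movement event log (birth, death, paired move-out/move-in) is
compiled per animal into residence intervals `[start, end)`; an animal
is in herd `h` on the first of a month iff its interval covers that
date. Events dated exactly on a snapshot date take effect at that
snapshot (move on the 1st → destination herd; death on the 1st →
excluded); the rule is arbitrary but deterministic and documented.
Contradictory sequences (death before birth, move-in with no origin,
events predating birth) quarantine the whole animal — excluded from all
snapshots, listed with a reason, processing continues. An animal with a
move-out and no matched move-in keeps its history up to the move-out
and is reported as an open move-out; it is counted in no herd
afterwards (the alternative — attributing animals in transit to source
or destination — cannot be decided from the data).

## Herd classification

Each herd-year is labelled from its January/May/September snapshot
composition and its year's flows, by ordered rules: herds with no data
in all three index months fall back to trading / fattening /
unclassified on flows alone (high turnover with short stays → trading;
older-age inflow → fattening); herds with calvings split by the breed
make-up of adult females (> 730 days) into dairy (≥ 50% dairy-breed),
mixed (both fractions ≥ 30%) and beef, with subtypes from progeny
handling — e.g. dairy herds rearing male calves (DRm), retaining their
own heifers (D) or selling all calves young (DnR_nC / DnR_C); beef
herds by the age at which home-bred progeny leave (weanling ≤ 365 d →
BSW, youngstock ≤ 550 d → BSY/BSY_nR, finished at home → BSB) with a
breed-purity rule for pedigree herds; herds without calvings split into
trading, fattening and store/rearing (subtypes by the sex × breed
make-up of the youngstock). Departures older than 1,000 days are treated
as culls, not progeny sales. All thresholds live in one versioned YAML
file; the rule order is fixed in code and recorded in each
classification's rule trace. The original tree's thresholds are not
public, so these defaults are calibrated to recover the synthetic
archetypes (≥ 95% on noise-free herds) and are expected to be replaced
wholesale when real thresholds are available.

## Aggregation and deflation

Per herd-month, predicted weights and values are summed over members.
The within-year profile is the mean herd-month total per herd type and
calendar month across herds and years. A herd's annual average is the
mean of its 12 monthly totals, with empty months contributing zero by
default (a herd destocked half the year carries half the biomass; the
alternative, averaging occupied months only, is behind a flag). The
herd-type annual average is the mean over herds; the sector total is
the **sum of herd annual averages** (the alternative — the mean of the
12 national monthly totals — is also implemented and differs only when
herds appear or disappear mid-year). Values are deflated as
`real = nominal × 100 / index(period)`, monthly index for monthly
series and the annual index for annual series; the annual index is the
December (year-end) value, which makes a constant-drift series satisfy
`index(base+k years) = 100·(1+g)^k` exactly. Biomass is carried in kg
and value in € everywhere; conversion to '000 tonnes or € million
happens only in the plotting helpers.

## Value-model validation

Market records carry a sale category but no birth date, so each
category maps to an age range in months (a user-replaceable YAML; the
operational crosswalk is not public). The model predicts at each
integer month of age in the range, covariates fixed at the market
table's median sale month and year, and the unweighted mean of those
predictions is compared with the observed mean price per (sector,
category), where sector is dairy vs beef from the breed code. The
predicted side is averaged over the group's empirical sex × breed
composition — predicting a single modal cell would bias any sector that
mixes breed categories. The comparison reports the signed relative
difference and a within-10% flag.

## Synthetic data: what it emulates, what it does not

Ground truth for weight and value is exactly the model's functional
form — piecewise-linear in age with additive month/year offsets and
Gaussian noise (heteroscedastic option: SD proportional to the mean).
Break-points sit at the four fitted national structures (608/1878,
713/1884, 682/1254, 335/1041 days); slopes and intercepts are chosen
for realism (birthweight ≈ 40 kg, mature cows ≈ 700–800 kg, mature gain
≈ 15 kg/yr) since the real coefficients are not published.
Consequences for interpretation:

- Parameter-recovery tests show the estimator finds the truth when the
  model is correctly specified. They say nothing about curvature
  misspecification in real growth data.
- The movement simulator drives births, sales and deaths from herd
  archetypes (spring-dominant calving, weanlings sold in autumn, dairy
  bull calves sold in spring, store herds releasing in October, trading
  herds with 10–40-day stays). It reproduces the qualitative seasonal
  patterns the aggregation should detect, and conservation holds by
  construction. It does not emulate disease-risk structure in the
  valuation sample (the real slaughter data come from a disease
  eradication programme and over-represent high-risk herds), private
  sales outside marts, or geography.
- Market self-consistency fixtures use a *balanced* generation mode
  (equal records per category × month × sex × breed cell): with random
  cells, finite-sample covariate imbalance alone produces percent-level
  category errors at zero price noise, which is Monte-Carlo error, not
  model inconsistency. Random generation remains the default.

Default archetype sizes follow the national annual median herd sizes by
type (beef 31, fattening 31, store/rearing 17, dairy 139, mixed 110,
unclassified 7, trading 23 head).

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the Monte Carlo studies
at 50 replicates of n = 600, the oracle comparisons at n = 300 with age
ranges of a few hundred days (where a full 1-day-lattice search is
exact), and the population chain at ~35 herds over three years (~6,000
animals, ~130,000 snapshot memberships) — sizes chosen so the whole
suite completes in a few minutes while every stage is exercised at
non-trivial scale. Tolerances: aggregation additivity is checked to
1e-6 relative (pure floating-point summation error); break-point
recovery to 5% and slopes to 10% median relative error at noise SD
40 kg; oracle RSS agreement to 0.1%. Ties and degenerate inputs:
empty herds contribute zero rows, not errors; animals with unmappable
breed codes are skipped and counted; negative predictions (possible for
extreme covariate combinations under an additive model) are floored at
1 kg / €1 with a logged count.

## Known limitations

- The additive month/year structure cannot capture age × season
  interactions (compensatory growth after poor winters).
- No uncertainty is attached to the break-points or predictions; the
  original estimator reports none and the pipeline propagates none.
- The classifier defaults, breed map and category-age map are stand-ins
  calibrated on synthetic archetypes; swap in operational versions via
  their YAML files before interpreting real classifications.
- Sector totals depend on the empty-month and sum-vs-mean conventions
  documented above; both alternatives are implemented so the
  sensitivity can be measured.
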