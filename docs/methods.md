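# Methods

## The model

`nestmove` fits a two-layer hidden-state model that couples horizontal
satellite-telemetry movement with vertical dive behavior.

**Movement layer.** Latent planar locations `Y_t` (km, local azimuthal
projection) sit on a regular 6-hour grid.  Displacements follow a
state-switching correlated random walk:

    Y_{t+1} ~ Normal( d_t, diag(sigma_x^2, sigma_y^2) )
    d_t     = Y_t + gamma_{S'_t} R(theta_{S'_t}) (Y_t - Y_{t-1})

where `S'_t ∈ {traveling, ARS}` is the behavioral state of interval `t`,
`gamma_s ∈ [0,1]` the autocorrelation in step length, `R(theta_s)` a
rotation by the mean turning angle, and `sigma` a per-coordinate process sd
shared between states (the model writes a single covariance outside the
state subscript).  Traveling means long, straight, persistent steps; ARS
(area-restricted search) short steps with large turns.  States evolve as a
Markov chain on the logit scale, `logit P(traveling | prev) =
alpha_top[prev]`, one free logit per conditioning state.

**Observation layer.** Argos fixes arrive irregularly.  A fix at fraction
`j` of interval `t` observes the chord interpolation
`(1-j) Y_{t-1} + j Y_t` plus isotropic normal error whose sd is fixed per
Argos class (3, 2, 1, 0, A, B).  The per-class sds ship as configuration
(`data/argos_errors.yaml`), populated from the Vincent et al. (2002)
calibration that underlies the standard class-specific measurement models;
replace them with your own calibration when available.

**Dive layer.** Within ARS, behavior is subdivided into foraging and
resting by a second, dive-frequency Markov chain `S''` with
`logit P(foraging | S', prev S'') = alpha_sub[S', prev S'']` — the row is
selected by the *current interval's* movement state, so the sub-chain keeps
evolving (without emitting) through traveling intervals.  A dive's maximum
depth is drawn from `Normal(mu_c, sd_c)` truncated below at 10 m, where the
component `c` is the traveling component when `S' = traveling` and the
`S''` component otherwise.  Truncation at the 10-m dive-definition
threshold is a deliberate choice: the data support is `(10, ∞)` by
construction, and an untruncated emission would put mass on impossible
depths.  An untruncated mode (`truncated=False`) exists for sensitivity
checks.

**Priors and identifiability.**

| parameter | prior | rationale |
|---|---|---|
| `gamma` (2) | Uniform(0,1), with `gamma_traveling > gamma_ars` | ordering pins state labels in the movement layer |
| `theta` (2) | Uniform(−π, π] | uninformative on the circle |
| `process_sd` (2, km) | Half-Normal(10) | weakly informative at regional-movement scale |
| `alpha_top`, `alpha_sub` (6 logits) | Normal(0, 2) | covers persistence from 0.02 to 0.98 |
| `dive_mu` traveling, resting (m) | Uniform(0, 30) | shallow components by biology |
| `dive_mu` foraging (m) | Uniform(50, 250) | deep feeding dives |
| `dive_sd` (3, m) | Half-Normal(50) | weakly informative |

The disjoint depth bounds prevent label switching between foraging and
resting; the `gamma` ordering prevents it between traveling and ARS.  The
source protocol used prior bounds plus nesting alone; the explicit ordering
makes seeded tests deterministic and costs nothing when regimes are
separated.  Note one tension in the source material: the traveling
mean-depth prior is bounded at 30 m, yet the reported traveling mean depth
is 41 m.  With 10-m truncation, a component mean of 25–30 m yields observed
mean depths near 40 m, so the bound and the estimate are compatible; our
generative default uses `mu_travel = 25 m`.

**Initial conditions.** The first top state and first sub-state of a track
are uniform; the first two locations carry a flat prior (the generator
draws them from a wide normal).  These initial terms are included in every
density, the forward recursion, and the simulator identically.

## Inference

Metropolis-within-Gibbs with three blocks per iteration:

1. **Collapsed sub-logit update.** The four `alpha_sub` entries are updated
   by random-walk Metropolis against the dive-chain likelihood with `S''`
   *integrated out* (a forward scan over each track's dives).  Dives in
   traveling intervals carry no emission information about `S''`, so
   conditioning on sampled sub-states couples the logits to states the
   logits themselves generated — mixing stalls (observed R-hat ≈ 1.8 at
   10,000 iterations).  The collapsed proposal removes the coupling
   (R-hat ≈ 1.01).  Validity: the update conditions on everything except
   `S''`, and the state block that immediately follows redraws `S''` from
   its full conditional before anything else conditions on it (a standard
   partially collapsed Gibbs composition).
2. **Discrete states by FFBS.** Both layers are drawn jointly and exactly
   per track by forward filtering–backward sampling on the augmented chain
   `z_t = (S'_t, K_t)`, where `K_t` is the sub-state after the last dive at
   or before `t`.  Each interval's dives are folded into 2×2 log-space
   transfer matrices, so the filter is O(T + D); within-interval sub-paths
   are then backward-sampled conditioned on entry and exit sub-states.
3. **Locations.** Each grid location takes one random-walk Metropolis step
   on its local full conditional (≤ 3 process factors plus the fixes of the
   two adjacent intervals).
4. **Remaining parameters.** Scalar random-walk Metropolis for `gamma`,
   `theta`, `process_sd`, `alpha_top`, and each dive component's `mu`/`sd`,
   with proposals outside the support rejected outright.  `theta` proposals
   wrap on the circle.

Proposal scales adapt toward 44% acceptance (30% for locations, inside the
20–50% band) every 100 iterations *during burn-in only* and are frozen
afterwards, so retained draws come from a fixed Markov kernel.  Chains are
initialized deterministically: locations at linearly interpolated fixes,
top states by a median step-length split, sub-states by a 50-m depth split,
parameters at prior medians (with `gamma = (0.75, 0.25)` to satisfy the
ordering).  Per-chain seeds derive from the master seed via
`SeedSequence(entropy=seed, spawn_key=(chain,))`, so adding chains never
reshuffles existing ones.

Convergence uses the classic (non-split) Gelman-Rubin potential scale
reduction, `sqrt(((n-1)/n W + B/n) / W)`, with the conventional < 1.1
threshold; zero within-chain variance is flagged degenerate rather than
returned as NaN.  The reference protocol is 2 chains × 30,000 iterations,
28,000 burn-in, thinning by 4 (500 retained draws per chain).

## Synthetic data

The generator draws from exactly the model above plus the Argos degradation
process.  Defaults emulate the observed study regime — 11 animals, ~8 fixes
and ~24 dives per 6-h interval (about 9,000 fixes and 26,000 dives over a
season), a mixed error-class distribution weighted toward the poor A/B
classes, and 10% of intervals with no fixes.  Fix times are drawn as unique
whole-second offsets within each interval, so written timestamps recover
the interpolation fraction `j` exactly and noiseless round-trips through
preprocessing are bit-exact.  Dive durations (lognormal) and shape codes
(uniform) are schema filler the model ignores, as the emission model uses
depth only.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about field data: t-distributed (heavy-tailed) Argos
errors, duty-cycled or surfacing-dependent transmission gaps, depth
measurement error and on-board aggregation artifacts, migration legs, and
any covariate structure in the transitions.  The per-interval fix count is
Poisson, a stand-in: the empirical fix-rate distribution of real tags is
not documented in the source material.

A config switch (`sub_reinit`) re-initializes the sub-chain from its ARS
stationary distribution at traveling→ARS entries instead of carrying the
sub-state through traveling; the default is the literal carried-chain
indexing.  The switch is implemented in the generator (for sensitivity
studies of the indexing choice); the density layer and sampler target the
default indexing.

## Preprocessing

Defaults reproduce the study protocol: drop fixes without coordinates,
duplicate timestamps (first kept), unknown error classes, and — when a land
mask is supplied (GeoJSON polygons or any predicate; none is bundled) —
locations on land; iteratively remove the later fix of any consecutive pair
faster than 20 km/h; split tracks at gaps > 12 h and drop segments spanning
< 24 h; keep dives strictly deeper than 10 m and strictly longer than 20 s
(the dive definition read literally as strict inequalities).  Migration
legs are removed via explicit user-supplied per-animal time windows rather
than an automated northward-movement detector: the source gives no
algorithm, and guessing one would change results silently.

Regularization anchors the 6-h grid at the track's first fix.  Intervals
are half-open `[start, start + 6 h)` — a record on a boundary opens the
next interval with `j = 0` — except that a record at the final grid point
closes the last interval with `j = 1`, so every instant maps to exactly one
interval.  Geographic input is projected to planar km with a spherical
azimuthal-equidistant projection centered on the data centroid (adequate at
regional scale; distances from the center are exact on the sphere).

## Summaries

Decoding uses the most-likely-state rule: traveling when the posterior
probability exceeds 0.5 (ties go to ARS, since the rule names traveling
strictly), and for dives the plurality label among traveling / foraging /
resting across draws.  Time-in-state percentages are computed over dive
observations — the only layer where all three behaviors exist — per
individual, then averaged across individuals; the sd is reported on both
the percentage and the proportion scale, since the two appear mixed in
field reports.  Depth quartiles use type-7 linear interpolation of order
statistics (bit-stable).  Temporal profiles bin by UTC calendar month and
UTC hour; uncertainty bands are the min–max spread of the per-bin fraction
recomputed under 50 evenly spaced posterior draws of the latent labels,
around the full-posterior mean fraction.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale conditions: the convergence
experiment runs 2 animals × 100 intervals (~800 dives, dive rate 4/interval)
with 2 chains × 10,000 iterations; parameter recovery runs 20 replicates of
1 animal × 60 intervals with single 4,000-iteration chains; the exact-oracle
comparisons run on ≤ 6-interval toys where all `2^T × 2^D` discrete paths
are enumerable; decoding accuracy uses one 80-interval animal with
good-quality error classes.  The headline field-scale quantities (58.2% /
22.0% time in state, depth quartiles, 616 deep dives, the ~70% late-season
foraging rise) derive from proprietary tag data that is not deposited; they
appear here only as generative settings in recovery tests, never as
assertions about real data.

## Known limitations

- Argos errors are normal, not t-distributed; no covariates on transitions;
  exactly 2 + 2 states.
- The location update is single-site Metropolis; a joint (e.g., simplex or
  elliptical) update would mix faster on long tracks with poor fixes.
- `alpha_sub`'s traveling row is informed only through chain continuity
  across ARS segments and is therefore largely prior-driven — expected, and
  visible in its wide posterior.
- The collapsed logit update assumes the dive emission parameters are held
  fixed within the step (they are; they update in a later block).
- Per-rule attrition counts from the original field dataset (9,283 → 8,958
  fixes; 26,375 → 21,417 dives) cannot be replicated without the raw data
  and are not asserted anywhere.
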