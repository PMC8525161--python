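# Methods

## The drift model

The simulator implements the simplest closed neutral community: `J`
individuals, `S` species, no migration, no speciation, non-overlapping
generations. Year `t+1` is one multinomial draw with `J` trials and
probabilities `N_{i,t} / J` — ecologically, every individual dies after
contributing propagules in proportion to nothing but its existence, and
the next community is assembled from that propagule pool. Consequences
that the package treats as hard invariants rather than approximations:

* **Exact conservation.** Every yearly column of every trajectory sums to
  `J` (the multinomial guarantees it; `AbundanceTrajectory.validate`
  asserts it).
* **Martingale.** `E[N_{i,t+1} | N_t] = N_{i,t}`: nothing directional is
  built in. All indicator declines are therefore statistical artifacts of
  indicator construction, which is the point of the exercise.
* **Absorbing extinction.** A species at zero has replacement probability
  zero. Over long horizons the community fixes on a single mono-dominant
  species (property-tested at `J=20, S=4, 5000` years).
* **Binomial marginal.** The single-species marginal of the community
  step is exactly `Binomial(J, N/J)`; this identity carries the entire
  extinction-risk calibration (below) and is itself property-tested
  against the full multinomial step.

The initial state is one multinomial draw with equal probabilities
`1/S`. A species can, with probability `(1 − 1/S)^J` (~10⁻⁵⁶ at the
defaults), start at zero; the draw is accepted as-is and such a species is
extinct from the start. No rejection rule is applied because conditioning
on full initial presence would break the plain multinomial description and
the event is negligible at any realistic size.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `J` | 5000 | community size (individuals); the zero-sum constant |
| `S` | 40 | initial species richness; mean initial abundance `J/S = 125` |
| `n_years` | 50 | annual steps; 51 states stored, labelled 1970–2020 |
| `start_year` | 1970 | calendar label of the baseline state |
| `n_replicates` | 1000 | ensemble size for envelope estimation |
| `seed` | 0 | master seed |

Time indexing: "50 years between 1970 and 2020" is modelled as 50 annual
transitions over 51 stored states, so the baseline year and the endpoint
are both real community states.

Replicate `r` draws from `numpy.random.default_rng([seed, r])`. Streams
are therefore independent of execution order, ensembles parallelise
without changing results, and a run manifest (master seed + code version)
pins every output byte.

## Living Planet Index

Per-species annual growth is `λ_{i,t} = log10(N_{i,t+1} / N_{i,t})`,
computed only where the species is extant (`N_{i,t} > 0`). The yearly
cross-species arithmetic mean of `λ` is chained multiplicatively from a
baseline of exactly 1: `I_{t+1} = I_t · 10^{mean λ}`. This is the standard
geometric-mean construction; it is base-consistent (any log base used
consistently yields the identical index — unit-tested against an
independent natural-log chain), scale-invariant and invariant to species
reordering. No taxonomic or geographic weighting tiers are applied: the
neutral community has no such structure, and the production LPI machinery
(GAM smoothing, realm weights, species-inclusion bootstrap) is deliberately
out of scope.

**Why it declines under drift.** The ratio `N'/N` has conditional mean 1,
so by Jensen's inequality `E[λ] < 0`; to second order
`E[λ] ≈ −(1 − N/J) / (2 N ln 10)` per year, largest in small populations.
A doubling and the matching equal-absolute decline elsewhere do not cancel
on the log scale. The package verifies the mechanism directly (the sample
mean of `λ` over all valid entries of a 1,000-replicate ensemble is
negative by far more than four standard errors) and measures the effect:
at the defaults the ensemble-mean index ends near 0.76 with a 95%
percentile envelope of roughly [0.63, 0.87] in 2020.

**Transitions into extinction.** `λ = log10(0 / N)` is undefined. The
default policy substitutes half an individual for the single transition
into zero (`λ = log10(0.5 / N_t)`), a finite penalty that keeps the index
sensitive to extinction; alternatives `floor1` (substitute 1) and
`exclude` (drop the transition) are selectable. After that transition the
species leaves all later yearly means. At the default scale the choice is
almost immaterial (extinctions are rare within 50 years when species start
near 125 individuals: the 2020 envelope moves by ~0.02–0.04 between
policies); it matters for small or long-running communities.

**Ensemble summary.** The 95% band is the per-year 2.5th/97.5th
percentile across replicate index values — distribution-free, no
normality assumption; the replicate distribution of `I_t` is noticeably
right-skewed, so a parametric ±1.96·sd band would misplace the lower edge.

## Extinction-risk calibration

`P(extinct within h years | abundance a)` is estimated for
`h ∈ {10, 20, 100}` by Monte-Carlo on the exact binomial marginal chain
(initial abundance `Binomial(J, 1/S)`, matching the community
initialisation). Chains run `n_years + max(h)` steps so that every state
visited during the first `n_years` steps has the full longest horizon of
subsequent dynamics; each such visit contributes one trial per horizon —
the chain is Markov and time-homogeneous, so conditioning on *current*
abundance is well-defined and maximises trials per abundance bin. A
full-community mode (tracking every species inside multinomial community
replicates) is retained and tested as a cross-check; it is statistically
identical and an order of magnitude slower.

Two trial-counting modes:

* `visits="all"` (default): every visit counts. Each trial is
  individually unbiased, but overlapping futures correlate trials within a
  bin, so binomial standard errors understate the estimator's spread.
* `visits="first"`: at most one trial per chain per bin. Trials are then
  independent across chains and raw frequencies are exactly binomial —
  this mode backs the oracle-agreement tests (at `J=12`, every abundance
  and horizon agrees with the exact absorbing-chain matrix-power oracle
  within four binomial standard errors at 10,000 iterations).

**Smoothing.** Raw frequencies are made non-increasing in abundance by
trial-weighted isotonic regression (pool-adjacent-violators) per horizon.
The exact endpoints `P(0,h) = 1` and `P(J,h) = 0` are pinned with
overwhelming weight; unvisited bins inside the observed range are filled
by the regression's linear interpolation (a warning reports how many).
Horizons are then made mutually consistent by a running pointwise maximum
in increasing `h` — a longer horizon can never carry less risk; the
pointwise maximum of non-increasing curves stays non-increasing.
Smoothing is needed because thresholding raw noisy frequencies produces
non-ordered cutoffs.

**Exact oracle.** For small `J` the dense `(J+1)²` transition matrix
(rows `Binomial(J, a/J)`; 0 and `J` absorbing by construction) is applied
`h` times to the absorption indicator at zero, giving
`P(hit 0 within h | a)` exactly. A resource guard rejects `J > 4096`.

## Thresholds, categories, Red List Index

The criteria are the IUCN quantitative extinction-probability rules:
CR = (10 y, 0.50), EN = (20 y, 0.20), VU = (100 y, 0.10). Each cutoff is
the *largest* abundance whose smoothed probability still meets the
criterion, with `≥` inclusive (a bin exactly on the criterion is
threatened) — a conservative, deterministic convention. Cutoff ordering
`A_CR ≤ A_EN ≤ A_VU` is guaranteed by the cross-horizon monotonicity and
the decreasing criterion probabilities, and asserted anyway. Degenerate
curves (no positive abundance meets a criterion, or all of them do —
possible at tiny `J`) raise instead of returning nonsense. At the
defaults with 10,000 iterations the cutoffs land near `A_CR ≈ 4`,
`A_EN ≈ 16`, `A_VU ≈ 115`.

Classification per species-year: EX at zero; CR for `0 < N ≤ A_CR`; EN up
to `A_EN`; VU up to `A_VU`; LC above (inclusive upper bounds). Near
Threatened is never assigned: NT has no quantitative probability
criterion, so species failing VU are LC. The classification is total and
EX is absorbing because extinction is.

RLI per year: `1 − Σ_i w(c_{i,t}) / (w_EX · S)` with `S` the *original*
species count — extinct species stay in the denominator and depress the
index permanently. Two weight schemes ship: `standard`
(LC 0, NT 1, VU 2, EN 3, CR 4, EX 5 — the published RLI weighting, NT
present but unused here) and `equal` (0–4 evenly over the five assigned
categories). Both satisfy the endpoint identities exactly (all-LC → 1,
all-EX → 0, tested under both schemes) and both show the qualitative
decline; the default is `standard`.

**Why the RLI declines.** The cutoffs are roughly geometrically spaced,
so on the abundance scale the threshold bands are much narrower at low
abundance: a random decline in a small population crosses category
boundaries more readily than the matching random increase in a large one,
and improvements cannot compensate deteriorations. With species starting
near 125 and `A_VU ≈ 115`, drift moves an increasing share of species
below the cutoffs; the ensemble-mean RLI in 2020 sits below its 1970
value by far more than four standard errors.

## Problem sizes and numerical choices

Default experiment sizes — 1,000-replicate ensembles and 10,000
calibration iterations — were chosen because envelope and curve estimates
stabilise well below them at this community size; the full default
pipeline runs in seconds on one CPU, and the test suite re-runs the
complete default-scale experiments rather than scaled-down stand-ins.
Statistical assertions in tests use four-standard-error tolerances from
exact binomial or cross-replicate variances. All state is integer; index
arithmetic is double precision; ties and boundaries are resolved by the
inclusive conventions stated above; degenerate inputs (empty communities,
negative abundances, corrupted zero-sums, unknown categories or policies)
raise `ValueError` early.

## What the generator does and does not emulate

The simulator *is* the data-generating process of the study design:
synthetic abundance trajectories under pure drift. It reproduces the
features the indicators respond to — martingale dynamics, zero-sum
coupling, absorbing extinction, abundance-dependent extinction risk. It
deliberately omits everything a real monitoring series has: observation
error, incomplete and irregular sampling, taxonomic/geographic structure,
density dependence, migration, speciation, and any deterministic trend.
Passing tests therefore demonstrate properties of the *indicators under a
neutral null*, not predictions about real LPI or RLI data; empirical
series can be scored with the same code (`driftindex score`) precisely so
that such comparisons are made against this null rather than against a
static baseline.

Known limitations: a single closed community (no metacommunity rescue
effects, which would soften extinction risk); annual whole-community
replacement (generation time = census interval); criterion-E-style
probability thresholds only (no IUCN criteria A–D based on decline rates
or range); thresholds calibrated at one `J` do not transfer to other
community sizes.
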