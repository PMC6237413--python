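# Methods

## The recruitment model

`rddsim` models coupon-based chain referral as a multi-type
Galton–Watson branching process in discrete waves.  One *run* starts
from a single wave-0 seed.  Every member of wave W draws a number of
invitations to send from a beta-binomial distribution on {0, …, c},
each sent invitation is accepted independently with probability p, and
each accepted invitation creates one wave-(W+1) recruitee.  Both the
sending distribution and p may depend on the recruiter's *type* — the
combination of sex (F/M), age group (0–39 / 40–59 / 60+) and education
(lower-than-academic / academic), 12 types — and may differ between
seeds and later-wave recruitees.  A recruitee's own characteristics
are drawn from row-stochastic conditional tables given the recruiter's
categories, independently for the three characteristics, optionally
stratified into recruiter-wave bands {0, 1, 2+}.

Idealisations inherited from the branching-process view: the invitee
pool is infinite (no overlap between trees, no repeat invitations to
the same person), there is no network degree structure, and
acceptance depends on the recruiter's characteristics only.  Vaccine
belief is a *dependent* covariate — assigned from a logistic model of
the three characteristics, never feeding back into recruitment — so
any covariate of interest can be carried through the process the same
way.

### Why beta-binomial

The empirical sending distribution is bimodal: a majority sends 0
coupons and a secondary peak sits at the maximum c = 4.  The
beta-binomial covers the whole feasible (μ, σ²) region between the
binomial floor σ² = μ(1 − μ/c) (α + β → ∞) and the two-point ceiling
σ² = μ(c − μ) (α + β → 0), so a single family spans unimodal
near-binomial behaviour and extreme zero-or-everything behaviour.
Both bounds are open; the moment inversion
(π = μ/c, ρ = (σ²/(cπ(1−π)) − 1)/(c − 1), α + β = 1/ρ − 1) fails
loudly outside them, with an explicit `clamp` option that projects
onto a point 1e-6 inside the band — the same pragmatic move used when
an observed sample variance is incompatible with the family.  The
degenerate limits (μ = 0, μ = c, σ² = 0) are represented by explicit
point masses rather than extreme shapes, which keeps analytic limit
cases exact and avoids overflowing shape parameters.

### Thresholds

The offspring distribution (accepted invitations per recruiter) is
the beta-binomial thinned by p; its mean m = μ·p is the reproduction
number.  The extinction probability q is the smallest fixed point of
the offspring PGF; recruitment is sustainable iff m > 1, hence the
critical sending mean is μ* = 1/p, unreachable when 1/p > c (at the
observed p = 0.19, even all-out senders stay below one successful
invitation).  1 − q is the infinite-cap limit of the probability that
a tree reaches the size cap; the finite-cap simulated proportion
slightly *exceeds* 1 − q near criticality because a tree can reach
the cap and still be doomed, and the excess vanishes as m grows.
The analytic module is single-type; for type-heterogeneous parameter
tables it provides the mean offspring matrix
M[i,j] = m_i · P(type j | type i) whose spectral radius decides
criticality, while multi-type extinction probabilities are left to
simulation.

## Parameter defaults (fixtures)

Defaults describe the Dutch online survey population that motivates
the scenario catalogue (1015 seeds, 433 recruitees over 6 waves):

| parameter | default | notes |
| --- | --- | --- |
| max coupons c | 4 | standard respondent-driven methodology |
| cap N | 1000 recruitees | operational definition of a "large" tree |
| sending moments (μ, σ²) | overall 1.36, 3.21; seeds 1.33, 3.24; recruitees 1.47, 3.23 | invitations per participant |
| acceptance p | overall 0.192; seeds 0.189; recruitees 0.201 | probability per sent invitation |
| seed marginals | 65.2% F; 12.5/45.8/41.7% ages; 58.7% academic | drawn independently per characteristic |
| mixing tables | overall + wave-banded conditional proportions | rows renormalised (printed values are 2-dp rounded) |
| belief model | logistic; marginal 53.5% negative | see below |

Two fixture choices deserve emphasis:

- **Variance fixtures for the mean sweeps.**  The high-variance
  (bimodal) rule is σ²_high(μ) = min(3.4, 0.95·σ²_max(μ)) — the
  observed high variance where representable, otherwise just inside
  the ceiling; the low-variance (unimodal) rule is
  σ²_low(μ) = min(1.1, 1.05·σ²_min(μ)), just above the binomial
  floor.  These are reconstructions of the study's "high, as
  observed" and "lowest possible" settings: one value per μ, with the
  within-range sweep available by building custom configs.
- **Belief coefficients are synthetic.**  Only the population marginal
  (53.5% negative) and the direction of effects (sex and age matter;
  younger participants more often negative) are constrained by
  observation.  The fixture uses male +0.3, age 40–59 −0.8, age 60+
  −1.2, academic −0.2 on the log-odds scale, with the intercept
  0.9801015 calibrated by root-finding so that the *exact*
  marginalisation over the overall type distribution returns 53.5%.
  Effect magnitudes are plausible placeholders, and are documented as
  such.

Scenario families S2–S4 and S15–S18 carry an `approximate` flag: the
original per-type parameter tables and the individual-level seed
roster were never published, so fixtures substitute stratum-level
moments (overall, or seed vs recruitee) and independent marginal seed
rosters.  The `+0.6 / −0.6` recruitment boost of S15–S18 is applied
to the overall moments, giving μ = 1.96, σ² = 2.61, p = 1.

## What the generator emulates — and what it does not

The scenario engine *is* the data generator: there is no external
data set.  It reproduces the moments, marginals, mixing proportions
and acceptance rates summarised above, under the model's independence
assumptions.  It does **not** reproduce: the empirical joint
distribution of seed characteristics (only its marginals), per-type
sending heterogeneity beyond the seed/recruitee split (types share
stratum-level moments unless a per-type table is supplied in the
config), finite contact pools, or any dependence of acceptance on the
invitee.  Passing tests therefore validate the simulator and its
statistics against the *model*, not against the original field data;
conclusions about real surveys inherit the model's idealisations.

## Numerical choices

- **Pmf evaluation.**  For c ≤ 64 the beta-binomial pmf is built from
  the ratio recurrence with exactly-representable factors
  (relative error ~c·eps, normalisation good to 1e-12 across shapes
  1e-3–1e3); larger supports fall back to log-beta functions.
- **Extinction probability.**  Monotone fixed-point iteration from 0
  with step tolerance 1e-12.  The subcritical branch (m ≤ 1 ⇒ q = 1)
  and the degenerate single-child case (q = 0) are returned exactly
  from the threshold theorem rather than approached asymptotically —
  at m = 1 the iteration converges only like 1/n.
- **Sampling.**  Beta-binomial draws use the defining beta–binomial
  mixture from a `numpy.random.Generator`.  Every stream derives from
  one master seed via `SeedSequence(master, spawn_key=(dataset, i))`
  — roster draws at i = 0, the tree of seed i at i + 1 — so batches
  are reproducible and order-independent.
- **Cap semantics.**  The cap is checked after a wave completes:
  the wave that crosses N is retained in full (stopping at
  cumulative ≥ N, labelling "large" at size ≥ N, making the two
  consistent).  Whether the crossing wave should instead be truncated
  is not determined by the design being emulated; full-wave retention
  was chosen and only affects sizes above N.
- **MLE.**  L-BFGS-B on log-shapes started from the moment-matching
  estimate (α = β = 1 when the sample variance is incompatible);
  deterministic given the data, with the log-likelihood reported.
  All-equal counts raise a degenerate-distribution signal.
- **Equilibrium rule.**  A wave pair is stable when the relative
  change is below 2%; the equilibrium wave is the smallest W from
  which *all* later observed pairs are stable (the laxer
  first-stable-pair reading is available via `mode="first"`).  Pairs
  with a zero denominator are unstable by definition.
- **Composition truncation.**  Per-wave proportions are averaged over
  replicate data sets with equal weight; waves missing from a data
  set are dropped from that wave's average, not imputed.  Because the
  deepest waves of a capped run are reached by only a handful of
  slow-growing trees, convergence statements are evaluated over the
  first 10 waves (`max_wave=10`), where every replicate contributes
  with large denominators — matching the wave horizon over which the
  original convergence claims were made.

## Problem sizes

The shipped checks use desk-scale sizes chosen to keep the full suite
around two minutes: 1000 single-seed runs for near-critical
large-tree rarity, 2000 runs per parameter set for the six-point
simulation-vs-PGF agreement (3 binomial SE plus a 0.01 finite-cap
allowance), and 100 seeds × 200 replicate data sets for the
random-mixing stabilisation check.  The scenario catalogue's own
defaults (e.g. 1000 data sets of 1015 seeds for the empirically
calibrated scenarios) are faithful to the emulated study design and
correspondingly heavier; `run_grid`'s resumable CSV keeps long sweeps
restartable.

## Known limitations

- Single-type analytic theory only; multi-type extinction
  probabilities are validated by simulation.
- Moment inversion requires c ≥ 2 (for c = 1 the mean fixes the
  variance; use shapes or a point mass directly).
- The equilibrium statistic is a two-sided difference rule, not a
  formal convergence diagnostic; with noisy tails it is sensitive to
  the wave horizon, which is why the horizon is explicit.
- No inference back from recruitment trees to population proportions
  (no respondent-driven-sampling estimators): the package studies the
  recruitment process itself.
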