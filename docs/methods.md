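# Methods

## The lineage-progression model

`nsctrack` analyzes (and simulates) the behavior of adult pallial neural
stem cells observed on a discrete imaging grid: a cell is seen every 2–3
days, for about 43 days, as an apical-area (AA) measurement plus a 0–3
*deltaA* reporter intensity score, a proliferation-marker flag, and at most
one terminal event (cytokinesis or delamination).

The simulator implements the following continuous-time model, observed only
at imaging days:

1. **Activation.** A quiescent NSC activates with a per-day hazard set by
   its *deltaA* status — `gamma_neg` for reporter-negative cells,
   `gamma_pos` for reporter-positive cells — optionally modulated by apical
   area through a logistic link,
   `rate = gamma_s * 2 / (1 + exp(-area_coupling * (AA - AA_ref_s)))`.
   The factor reduces to exactly 1 at `area_coupling = 0` (the default): the
   data constrain only the monotone direction of the area effect, not its
   functional form, so the slope is a configurable knob rather than a
   calibrated constant. Per imaging interval of length `g` days the
   activation probability is `1 - exp(-rate * g)`, which composes exactly to
   the continuous-time exponential over any horizon.
2. **Division clock.** At activation the proliferation marker switches on
   and cytokinesis follows after an `Exponential(lambda_act)` delay
   (`lambda_act = 0.326/day`, i.e. a 2.1-day median). The onset is placed
   uniformly within its imaging interval — an approximation of the
   truncated-exponential conditional law that is indistinguishable at these
   hazards (activation probabilities per interval are ≤ a few percent).
3. **Division geometry.** The mother's area (frozen at activation) splits
   into daughters `A(1+x)/2` and `A(1-x)/2` with `x ~ Normal(0, 0.212)`
   truncated to |x| < 0.95. The daughters sum to the mother exactly before
   measurement noise. The imbalance SD is a free calibration: 0.212 puts
   ~60% of daughter pairs above a 20% relative area difference
   (`P(2|x|/(1+|x|) >= 0.2) = P(|x| >= 1/9) = 0.6` at that SD).
4. **Fate rule.** A *deltaA*-negative mother always produces one permanently
   negative daughter and one daughter that scores positive at DC with
   probability 0.7 (`fate_on_at_dc_prob`), else at DC+1 — the
   binary-asymmetric division. A positive mother produces two positive
   daughters of unequal score; a configurable 5% of these pairs later
   converts to an ON/OFF pair after an `Exponential(mean 11.5 days)` lag
   (most ON/ON pairs stay ON/ON at DC+4).
5. **Post-division behavior.** Each daughter returns to quiescence with
   probability `requiescence_prob` (223/250 by default for both statuses) or
   re-divides "reiteratively": immediate re-activation with the same
   division clock.
6. **Growth.** Quiescent negative cells grow multiplicatively at
   `ln(1.3)/40 ≈ 0.00656/day` (30% in 40 days); positive cells do not grow.
   Exponential rather than linear growth is used because observed growth is
   non-linear and all doubling-time arithmetic in the analysis is
   exponential.
7. **Delamination.** A positive cell whose (true) area falls below 10 µm²
   delaminates at its next observation. Since areas halve at division and
   only grow during quiescence, delamination in practice removes the small
   second/third-generation progeny of positive lineages — the synthetic
   delaminating population has a median area near 8 µm² and is ~100%
   reporter-positive.
8. **Rare switches.** Root tracks that never divide nor delaminate switch
   their reporter OFF (rate 9/703 per track per movie) or ON (5/703) at a
   random interior time point. Restricting the channel to nondividers keeps
   the fate rule exact and matches how the corresponding observation was
   tallied (a nondividing-track denominator).
9. **Measurement.** Observed areas are the true areas times
   `exp(Normal(0, 0.05))` per observation; scores, markers and events are
   recorded without error.

Notch blockade (`apply_ly`) replaces both status hazards from a start day by
one shared hazard while keeping the area modulation, and places cytokinesis
at the next imaging time point (the blockade induces a synchronized division
wave within days; an additional 2–3-day exponential delay would be
incompatible with the published 4-day division likelihood). The `ly_rate`
parameter is the published per-cell-per-day division likelihood over the
4-day assay (0.0852); internally it is converted to the hazard
`-ln(1 - 4 * ly_rate)/4 ≈ 0.104/day` so that the naive estimator
`divisions/(tracks*days)` recovers 0.0852 in expectation despite
risk-set depletion.

All randomness flows through one `numpy` generator from a single integer
seed; identical (parameters, n, seed) reproduce a cohort byte for byte.

### Initial conditions and snapshots

Root NSCs are 20% reporter-positive, with lognormal initial areas
parameterized by the status-conditional means/SDs (negative quiescent cells
112 ± 15.4 µm², positive 54 ± 3.7 µm²). Static snapshot tables draw a state
(qNSC / aNSC singlet / aNP at fractions 0.76 / 0.09 / 0.15), an area from
the per-state lognormals (84 ± 8.9, 54 ± 17.1, 10 ± 3.6 µm²), and a
*deltaA* status independently (positive fractions 0.23 / 0.87 / 0.99). The
state-level and status-conditional area tables come from different
experiments and are not consistent as a single mixture
(0.77·112 + 0.23·54 ≈ 99 ≠ 84), so snapshots honor the per-state moments
and the cohort simulator honors the status-conditional ones; a snapshot
therefore does not reproduce the within-state area–status anticorrelation.

### What the generator does and does not emulate

It emulates the statistical structure the analysis consumes: grid sampling,
censoring by movie end, event rarity, area halving plus slow regrowth, the
fate rules, and measurement noise on areas. It does not emulate spatial
structure (neighbor interactions, Notch signal propagation), score
measurement error, tracking errors or track fragmentation, fish-level
heterogeneity in rates (fish differ only by sampling noise), or
activation-state-dependent area change. Consequently, green tests certify
that the estimators recover the generating process on data with this
structure — not that the biological values themselves are correct, and not
robustness to mis-tracking.

A known internal tension of the study conditions is preserved rather than
resolved: per-movie division frequencies of 6.2%/34.2% are not consistent
with per-day hazards 0.0056/0.0246 under an exponential model (0.0056/day
over 42 days gives ~21% per movie). The generator uses the per-day hazards;
per-movie frequencies are emergent and not calibration targets.

## Estimators

**Interval-censored exponential fit.** Each onset→cytokinesis duration is
known only up to an interval `[L, U]` (right-censored: `U = ∞`). The rate
maximizes `Σ log(exp(-λL) - exp(-λU))` (right-censored terms contribute
`-λL`), computed stably as `-λL + log1p(-exp(-λ(U-L)))`, by bounded 1-D
minimization on `(1e-8, 10]` with tolerance 1e-8. The 95% CI is the profile
likelihood at the χ²₁ cutoff 3.84, bracketed by root-finding on both sides
of the MLE; it is preferred over a Wald interval because the sample sizes
are small and the rate is bounded below. Degenerate intervals `[t, t+ε]`
recover the closed-form uncensored MLE `n/Σt`.

For forest data the extraction brackets both end points by the grid: the
true duration lies in `[last undivided day − first marker-ON day (clamped at
0), division day − last marker-OFF day]`. This is the exact containing
interval; a construction using the division day on both sides would exclude
genuinely short durations and biases the recovered rate down by ~25%. The
single-interval likelihood on these brackets retains a small (~+7%) upward
bias because onset and division uncertainties enter jointly; the dedicated
calibration generator (`simulate_marker_durations`) therefore brackets each
duration directly by the grid partition, for which the likelihood is exact
(recovery at 0.326: mean MLE 0.325, 97% profile-CI coverage over 200
replicates).

**Division likelihood.** `divisions/(tracks × days)` with the exact
(Garwood) Poisson CI on the count divided by the exposure; Poisson rather
than binomial because events are rare and exposure-based. The forest-level
variant uses per-track risk time as exposure, which stays unbiased when the
per-movie division probability is not small. Reiterative daughter divisions
are not hazard-driven; hazard-recovery checks therefore switch that channel
off.

**Growth curves.** Nondividing tracks are normalized to their first observed
area; day bins are the union of observed imaging days (no interpolation);
the per-bin median carries a seeded percentile bootstrap 95% CI (1000
resamples), and the growth rate is the slope of `log(median)` against day,
with a bootstrap percentile CI. The bootstrap resamples values within bins;
with one value per track per bin this is equivalent to resampling tracks
bin-wise.

**Mann-Whitney summaries.** Midrank U statistics; groups of at most 20 use
the exact null distribution (deterministic small-sample p-values), larger
comparisons the tie-corrected normal approximation.

**Division-propensity logistic model.** `divided ~ area * delta_pos +
C(fish_id)` by default (add `C(treatment):delta_pos` for pooled
control/blockade tables), fitted by Newton/IRLS via statsmodels to
coefficient tolerance 1e-8 from a zero start. Areas enter in raw µm² (the
propensity is plotted against raw AA); a standardization flag is left to the
caller. For dividers the covariates are taken at the last pre-division time
point; for nondividers the mean area and most prevalent status over the
study period (mean rather than median — unstated in the source convention).
Complete separation is detected (single-class outcomes, 0/1 fitted
probabilities, or the optimizer's own separation error) and raised with a
diagnostic; no silent penalization. Type II Wald χ² tests respect
marginality: a main effect is tested as its coefficient block in the model
refitted without the interactions containing it; interactions are tested in
the full model. This matches `car::Anova(type = 2, test.statistic = "Wald")`
for interaction-free designs (cross-checked in the test suite against R).

**Window rescaling.** Assuming a memoryless division process,
`1 - p_k = (1 - p_1)^k`, so a probability estimated over a `w_from`-day
window rescales to `p_to = 1 - (1 - p_from)^(w_to/w_from)`, implemented with
`expm1/log1p`. `p = 1` is degenerate and returned as 1 with a warning.

**Fate multinomial.** Division modes of *deltaA*-negative mothers are fitted
with a multinomial log-linear model, intercept plus fish fixed effects by
default — a saturated design whose fitted probabilities equal the per-fish
empirical proportions (verified to 1e-6). A single observed category is
reported as degenerate rather than fitted; quasi-separation surfaces as an
explicit error.

## Annotation conventions

- **Division from quiescence:** at least 2 division-free imaging intervals
  (≈4–5 days) observed before cytokinesis; intervals, not days, are counted.
- **DC+k horizons are strict** (an observation exactly k points after DC);
  a fall-back to the last observation exists but defaults off to avoid
  silent look-ahead.
- **Pair asymmetry** uses the larger daughter as denominator (keeping the
  measure in [0, 1)) and an inclusive 20% threshold.
- **Post-division outcomes:** daughters with under 4 days of *potential*
  follow-up (movie end) are censored — conditioning on realized track length
  would selectively retain fast dividers. A re-division below the
  quiet-interval criterion is reiterative; one satisfying it means the
  daughter requiesced first. Delamination is its own category, excluded
  from the requiescence/reiterative binary.
- Missing scores propagate (`unclassifiable`, never silently negative);
  nothing is imputed.

## Problem sizes and determinism

The test suite and the reproduction script run at the study's own scales:
828-track cohorts, 584-track growth sets over 40 days, 500 censored
durations, 200-replicate coverage and 1000-replicate type-I-error Monte
Carlo, 261-track 4-day blockade assays. Every stochastic step takes an
explicit integer seed; stage seeds are derived from the run seed by hashing
stage labels.

## Limitations

- The raw experimental track tables are not redistributed; all quantitative
  claims about real data reduce to the printed counts used in the worked
  examples, and everything else is generator-based recovery.
- The forest-level duration extraction is approximately, not exactly,
  likelihood-consistent (see above); rates fitted from cohort forests run
  ~5–10% high at default hazards (0.347 ± 0.019 at a generating 0.326 over
  replicate cohorts). The calibration-path generator avoids this.
- Fish fixed effects only; no random effects, no overdispersion handling.
- The multinomial fate model is intended for the small per-fish counts of
  the study; with near-empty categories it reports degeneracy rather than
  regularizing.
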