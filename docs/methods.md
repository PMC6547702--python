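# Methods

## Design and estimand

The package implements a case-crossover analysis of dispensed drugs
against an acute-onset event.  Only cases enter the analysis; each
contributes a matched pair of observation windows before their index
date:

* case window: offsets 1–7 days before the index date (inclusive);
* control window: offsets 15–21 days;
* wash-out: the gap 8–14, to limit pharmacological carry-over;
* the index day (offset 0) is never part of any window — a same-day
  dispensing is ambiguous between cause and consequence of the event,
  so it is excluded by design.

The extended sensitivity design doubles everything (1–14 / 29–42).
Window offsets are inclusive on both ends.  Exposure is binary per window
(any dispensing of the drug), ignoring counts and quantity; drug identity
is the verbatim code string (ATC 5th level in registry exports) with no
hierarchy roll-up.

Eligibility filters compose conjunctively: hospital-ascertained cases
only (drop out-of-hospital deaths), at least one dispensing within
offsets 1–365 (inclusive), and an optional age dichotomization at 80
years.  After filtering, patients are retained only if they have at
least one dispensing in the case or control window, and drug columns are
kept only if some patient is exposed in some window.

With binary exposure the 1:1 conditional likelihood depends only on the
pair differences `d_i ∈ {−1, 0, 1}^p`:

    ℓ(β) = −Σ_i log(1 + exp(−βᵀ d_i)),

maximized without intercept or stratum bookkeeping — mathematically
identical to the stratified conditional likelihood and an order faster.
`exp(β_j)` is the rate ratio of drug j adjusted for all other drugs in
the model.  Under the rare-event approximation the odds ratio estimated
here equals the hazard rate ratio of the generator (daily event
probabilities are ~1e-4, so the distortion is negligible).

Columns are never standardized before penalization: all covariates are
same-scale binary differences, and leaving them raw preserves the
comparability of β across drugs.  No covariate is exempt from the
penalty; the model adjusts only among drugs.

## Solvers

*Unpenalized MLE* — damped Newton iterations with backtracking on the
exact conditional likelihood; standard errors from the inverse observed
information at the optimum.  Columns whose nonzero differences are
single-signed (all case-only or all control-only discordance) have no
finite MLE (complete separation): they are excluded from the
optimization, reported as ±inf with no CI, and flagged in
`FitResult.degenerate`.  All-zero columns are flagged the same way.

*L1 solver* — minimizes `−ℓ(β) + λ‖β‖₁` by majorization-minimization:
because the logistic curvature satisfies `μ(1−μ) ≤ 1/4`, the fixed matrix
`H₀ = ¼ Dᵀ diag(w) D` dominates the Hessian everywhere, so the quadratic
surrogate built from the exact gradient and `H₀` majorizes the loss and
every surrogate minimization strictly decreases the objective — no line
search is required (a safeguard still aborts if rounding ever violates
monotonicity).  Each surrogate is solved exactly by cyclic coordinate
descent with soft-thresholding, which yields exact zeros, so the selected
support is well defined.  In the regime of this model (|βᵀd| well below
1), `μ(1−μ)` is within a few percent of 1/4 and convergence is close to
Newton.  `H₀` depends only on the data and weights, so it is computed
once and shared across an entire penalty path or CV fold; the inner loop
is compiled (numba).  KKT conditions at the solution satisfy
`|∂ℓ/∂β_j| ≤ λ + tol` for zero coefficients and `= λ·sign(β_j) ± tol`
otherwise (verified in the tests against exhaustive grid search).

*Penalty path and cross-validation* — the path is geometric from
`λ_max = max_j |½ Σ_i w_i d_ij|` (the gradient magnitude at the origin,
the smallest penalty with an all-zero solution) down to
`λ_min_ratio · λ_max`.  The CV criterion is the held-out conditional
log-likelihood — the estimand's native scale — summed over seeded pair
folds; ties break toward the larger (sparser) penalty, since selection
stability is the goal of the enclosing bootstrap procedure.  Path fits
used only for CV scoring run at a relaxed tolerance (1e-5); the
support-defining final fits use the full 1e-8.

Defaults: `tol = 1e-8` (max coefficient change), `max_iter = 10000`,
100 path points, `λ_min_ratio = 1e-3`, 5 folds, `z = 1.959964` for 95%
intervals.

## BOLASSO

Bootstrap samples are drawn by resampling whole informative pairs with
replacement to the original size — the pair is the independent sampling
unit of the conditional likelihood, and resampling never splits a
case/control period from its partner.  Internally the rows are collapsed
to unique difference patterns with multiplicity weights; a bootstrap is
then a multinomial redraw of the weights and CV folds are multinomial
thinnings of them, which is distributionally identical to resampling and
assigning individual pairs but orders of magnitude faster.  One master
seed spawns independent per-bootstrap substreams, so increasing the
bootstrap count extends, never reshuffles, earlier replicates.

Per bootstrap, the penalty is chosen by cross-validated held-out
likelihood (default) or fixed; columns that become single-signed in the
resample are dropped from that fit and counted as not selected (their
penalized MLE direction is infinite).  A drug is selected when its
coefficient is nonzero in at least the consensus fraction of bootstraps;
1.0 is the strict intersection of supports, 0.9 a softer variant — both
are exposed because published applications rarely state their exact rule.
Defaults: 1000 bootstraps (register-scale profile), 100 in the quickstart
profile.

Reported estimates always come from the unpenalized joint refit of the
selected drugs on the original (unresampled) pairs: they are mutually
adjusted and free of shrinkage bias.  The refit Wald CIs are labelled as
such; they do not account for the preceding selection, so a drug selected
by consensus can still have a CI touching 1.

## Fixed-effect combination

Per-country log rate ratios `b_c` with standard errors `se_c` combine
with weights `w_c = 1/se_c²` into `Σ w_c b_c / Σ w_c`, standard error
`(Σ w_c)^{-1/2}`.  All arithmetic is on the log scale; ratio-scale I/O
converts at the boundary.  `se_from_ci(L, U) = (ln U − ln L)/(2z)` is the
exact algebraic inverse of the Wald interval, so printed tables can be
re-combined; since published tables round to two decimals, reproduction
is expected to print precision only (the tests use ±0.01).  Cochran's Q
and I² are computed and logged for every combination but never gate it —
the cross-country analysis is fixed-effect by design.

## Synthetic registry generator

The real inputs are restricted-access national registers, so the
generator emulates their structure with a fully specified stand-in
process; none of its distributions is estimated from real data.

*Dispensing.*  Each drug has a use prevalence.  Among users, acute-mode
drugs dispense as a homogeneous point process (`acute_rate` per
patient-year, uniform integer days) — stationary, hence symmetric between
case and control windows under a null effect.  Chronic-mode drugs
initiate at a uniform random day within observation and refill every
`refill_interval_days` with independent uniform jitter
`± refill_jitter_days` until the end of observation, without stopping.

*Events.*  Day `t` carries discrete hazard
`baseline_hazard × Π_j RR_j^{[drug j dispensed in (t−W, t)]}` with
trigger window `W = 7` days by default — the same look-back as the
analysis case window, so the planted RR equals the estimand (the window
is configurable to study misspecification, which biases toward the
null).  The first event day becomes the index date; events before day 42
are discarded so the longest control window fits inside observation, and
the generator warns when more than half the cohort is lost this way
(degenerate design).  Ages are drawn from a Table-1-like case age
distribution (mode 80–89), sex is 53.6% male, and 17% of events are
recorded as out-of-hospital deaths; demographics are independent of drug
use, since self-matching makes them nuisance.  Dates are 0-based integer
day offsets from a per-country epoch.  Identical configs (including
seed) produce byte-identical tables, and two configs sharing
`planted_effects` emulate two countries with common true effects.

*Persistent-user bias, by construction.*  For a chronically refilled null
drug, prevalence of use grows over calendar time (initiations accumulate,
nobody stops), so looking back from an event a recent initiator can be
exposed in the case window but not yet in the earlier control window,
while the reverse cannot occur.  With a refill interval comparable to the
window spacing (14 days) the periodic schedule makes established users
nearly concordant, so the initiation asymmetry dominates the discordant
counts and inflates n10/n01 above 1 at a true RR of 1 — the upward bias
expected for chronically used drugs in case-crossover contrasts.  The
bias scales with (window separation)/(observation length), which is why
the chronic test bed uses a 3-year window.

*What the generator does not emulate* — and what passing tests therefore
do not establish about real registers: confounding by indication
(prodromal symptoms driving prescribing before the event), reverse
causation, within-class correlated drug use, dosage/DDD, over-the-counter
drugs, institutionalized-patient gaps, therapy discontinuation, calendar
seasonality, and multi-event histories.  The tests establish that the
*estimators* recover what the generating process plants, not that real
associations are causal.

## Desk-scale problem sizes

The validation beds are scaled to a single CPU while preserving the
per-drug information that matters (discordant-pair counts):

* screening bed: 20 000 patients × 40 acute drugs (prevalence 0.5,
  4 dispensings/user-year), baseline hazard 2e-4/day over 4 years →
  ~5 500 first-event cases and ≥350 discordant pairs per drug
  (per-drug log-RR SE ≈ 0.1);
* planted-effect recovery: 5 drugs at RR 2.0, 100 bootstraps,
  consensus 0.9, 30-point penalty path;
* null calibration: 20 replicate pairs of countries at 6 000 patients,
  50 bootstraps each;
* chronic-bias bed: one drug, 14-day refills ± 2, 20 000 patients over
  3 years, 20 replicates.

The register-scale profile (1000 bootstraps, 100-point path, decade-long
observation) is a configuration change, not a code path change.

## Known limitations

* Refit Wald CIs ignore the selection step; a formal post-selection
  interval is out of scope.
* The univariable ratio `n10/n01` is finite-sample biased upward by
  ~`1/n01` (Jensen); with the desk-scale counts this is ≤2%.
* Separated (single-signed) columns are reported as degenerate rather
  than handled by penalized-refit alternatives (e.g. Firth), which are
  out of scope.
* The discrete daily Bernoulli hazard approximates a continuous-time
  proportional hazard; at the default hazards the approximation error in
  the estimand is far below Monte-Carlo noise.
* m:n matched sets, time-varying covariates within windows, dose-response
  exposure, elastic-net and stability selection are out of scope.
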