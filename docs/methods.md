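# Methods

## Model

`ltcmsm` implements a time-homogeneous continuous-time Markov multi-state
model on a user-defined state space. The default structure is the
progressive four-state long-term-care model — State 1 Non-user, State 2
HACC (home and community care), State 3 RAC (residential aged care),
State 4 Death — with allowed moves 1→2, 1→3, 1→4, 2→3, 2→4, 3→4, no
reverse transitions, and Death absorbing. Time is measured in years from a
common baseline (time 0) for every subject, with a 10-year study horizon by
default.

Transition intensities are collected in the generator matrix `Q`
(off-diagonals `q_ij >= 0`, rows summing to zero, absorbing rows zero);
interval transition probabilities are `P(t) = expm(tQ)`. Baseline
covariates `z` scale each intensity proportionally,
`q_ij(z) = q_ij(0) exp(beta_ij' z)`, with coefficients estimated per
transition. Covariates are fixed at their baseline values; the model
notation admits a piecewise-constant time-varying extension
(rebuild `Q` per interval from interval-specific `z`), which is a
documented extension point but not implemented.

Assumptions worth stating plainly: the chain is memoryless (sojourn times
are exponential given the covariates, and the future depends only on the
current state), intensities are constant in time and age enters only as a
baseline covariate, and censoring at the administrative horizon is
non-informative.

## Observation types and likelihood

Each consecutive observation pair of a subject contributes one likelihood
factor, selected by the type of the later observation:

- **snapshot** — state ascertained at a visit; contribution
  `P[a, b](dt)`, integrating over all unobserved paths. For acyclic
  structures `P[s, s](dt) = exp(-q_s dt)` exactly, which the evaluator uses
  so that diagonal snapshot intervals need no matrix exponential.
- **exact_transition** — dated care entry; the subject held the previous
  state for the whole interval, then jumped:
  `exp(-q_a dt) * q_ab` (competing-risks density).
- **exact_death** — dated death. Two semantics exist. If the dataset is
  *fully observed* (administrative emulation: every transition exactly
  recorded), the state before death is the interval's from-state and the
  contribution is the same competing-risks density. Otherwise the pre-death
  state is unknown and the contribution sums over live states,
  `sum_r P[a, r](dt) * q_r,Death` — the standard death-certificate
  convention for panel studies.

The choice is carried by a dataset-level `fully_observed` flag, set by the
exact observation scheme (and inferred on CSV input from the absence of
state changes on snapshot rows). This matters: applying the unknown-state
sum to fully recorded cohorts assigns positive probability to trajectories
whose intermediate care entries would have been recorded, and measurably
biases the fit; applying the direct density to survey panels would ignore
genuinely possible unobserved moves. Each scheme gets the likelihood that
matches its information content.

Ties in observation times within a subject are a data error, reported with
subject and row, never silently resolved. Zero-probability contributions
(an observed move the structure forbids) yield `-inf` with a diagnostic
naming the subject and interval.

## Estimation

Fitting maximises the log-likelihood on the unconstrained scale: log
baseline intensities plus raw coefficients, stacked in a fixed documented
order (log-baselines in transition order, then each transition's betas).
Start values are crude occurrence/exposure rates — observed direct `i→j`
moves divided by person-years spent in `i` — with coefficients at zero;
this is always feasible and, for exactly observed intercept-only data, is
already the maximum. A structurally allowed transition never observed in
the data makes the boundary explicit: fitting raises a diagnostic unless
the transition is frozen at a supplied rate.

Optimisation is BFGS with finite-difference gradients on the objective
scaled per interval (so the gradient tolerance, default 1e-5, is
independent of cohort size); an optimiser report of "precision loss" at a
point with scaled gradient below ten times the tolerance is treated as
converged, anything else is flagged and warned, never silently returned as
converged. The covariance is the inverse of the observed information,
computed by central second differences with relative steps of 1e-4; a
non-positive-definite information leaves the covariance unavailable (with
a warning) while retaining point estimates.

All 95% intervals use the normal 1.96 quantile. Hazard ratios are
`exp(beta_hat +/- 1.96 SE)`. Derived quantities use the delta method with
central-difference gradients, on the log scale for positive quantities
(rate ratios, sojourn times) and the logit scale for probabilities, then
back-transform — keeping intervals inside their admissible range.

## Derived quantities

- Transition rate ratio: `q_num / q_den` at a covariate profile.
- Next-state probability from transient `i`: `q_ij / sum_k q_ik`.
- Mean sojourn time: `1 / (-Q_ii)`. This is the primary reading of the
  published "average length of stay": it is the only reading under which
  the printed 7.95-year non-user stay and the printed 0.28 ten-year
  non-user probability cohere (`exp(-10/7.95) = 0.284`).
- Total length of stay, the alternative windowed reading:
  `integral_0^T P[start, target](t) dt` by adaptive quadrature
  (tolerances 1e-10), or via the fundamental matrix `-inv(Q_TT)` of the
  transient class when `T` is infinite.
- Survival: `1 - P[from, Death](t)`, summing over absorbing states.
- Multi-state frequency table: counts of observed next-entries between
  states, diagonal counting subjects last seen in each state.
- Prevalence goodness of fit: observed counts by last observation carried
  forward versus expected counts `sum_subjects P_subject[1, .](t)`,
  subjects grouped by covariate profile.

Fitted summaries default to the covariate reference profile (all
covariates zero); any profile can be supplied. Text reports round
probabilities, ratios and years to two decimals; CSV output keeps full
precision.

## Synthetic cohorts

The generator emulates a 9007-woman cohort followed for 10 years, with all
subjects starting as non-users. Because only marginal summaries of the real
cohort are published, the default intensities are calibrated from them:
the State-1 total exit rate `1/7.95` split by the next-state probabilities
implied by the published rate ratios 11.08 and 7.72 gives
`q12 = 0.10312`, `q13 = 0.00931`, `q14 = 0.01336`; the State-2 total exit
`1/5.04` split .63/.37 gives `q23 = 0.12500`, `q24 = 0.07341`; and
`q34 = 1/2.51 = 0.39841` (all per year). Baseline covariates are drawn
independently with the published marginals: age uniform on [75, 82]
(median ~78, matching the printed median and range), and indicators with
prevalences 0.567 (outside major cities), 0.459 (widowed), 0.256 (income
difficulty), 0.488 (arthritis), 0.191 (heart problem), 0.096 (diabetes),
0.133 (asthma), 0.123 (falls with injury).

Covariate-effect presets: `none` (inert covariates), `single` (one binary
covariate, prevalence 0.5, true hazard ratio 1.5 on 1→2 — the canonical
recovery test bed), and `table` (the published per-transition hazard
ratios as truth). For the effect presets the baseline log-intensities are
shifted by `-beta' E[z]` so the rate at the cohort-average profile still
equals the calibrated rate; without this, an uncentered age effect would
move every marginal summary far from its calibration target.

Event simulation draws one exponential clock per allowed exit of the
current state and follows the earliest (competing risks — same law as
total-rate-plus-multinomial, simpler invariants). Trajectories are
censored administratively at exactly 10 years; no random loss to
follow-up. A master seed spawns one child stream per subject plus one for
covariates, so cohorts are bit-reproducible and independent of evaluation
order. Observation schemes: `exact` (default; dated events plus a
censoring snapshot), `panel-3yr` and `panel-6mo` (survey-style snapshot
grids, deaths interval-censored onto the next grid point), and `mixed-3yr`
(both).

What the generator does **not** emulate: correlation among covariates
(an age-widowhood association preset would be a natural extension; the
published tables give no joint distribution), survey non-response and the
exclusion cascade of the real cohort, sampling weights, time-varying
intensities (age acts only through its baseline value), and dementia
(absent from the published model). Passing recovery and fidelity tests
therefore demonstrates correctness of the estimator and simulator under
the model's own assumptions — not robustness to the dependence structures,
misclassification or informative observation of real linked data.

## Numerical choices

- Matrix exponential: scipy's scaling-and-squaring Pade implementation on
  the full matrix — robust to near-repeated eigenvalues; the progressive
  (upper-triangular) structure is exploited only in tests. Entries are
  clipped to [0, 1] to remove rounding dust.
- Linear predictors with `|log q0 + beta'z| > 30` raise a numeric-range
  error rather than silently saturating `exp`.
- Likelihood totals are accumulated with exact summation (`math.fsum`), so
  reordering subjects changes nothing, to the last bit.
- Repeated `P(dt)` evaluations during fitting are cached per covariate
  profile and interval length; exact-event and diagonal-snapshot terms use
  closed forms, so fully observed cohorts fit without any matrix
  exponentials.
- Degenerate inputs: `dt <= 0` intervals, observations after absorption,
  non-0/1 indicators and unknown states are collected into a single
  validation report with row numbers; absorbing states are rejected by
  name in sojourn/next-state queries.

## Test and validation scale

Independent oracles: forward-ODE integration of the Kolmogorov equations
(tolerance 1e-8, randomized generators), closed-form competing-risks
densities, a finite-difference oracle for the death density, and a
discretized-chain (`I + hQ`) brute force for the panel likelihood.
Recovery and fidelity use cohorts of 5,000 (estimation), 10,000
(prevalence self-consistency), 20,000–50,000 (simulator fidelity)
subjects — sizes chosen so Monte-Carlo bands are a few per mill to a few
per cent, tight enough to detect calibration errors while keeping the full
suite around a minute or two on one CPU. CI coverage of the recovery
hazard ratio is checked across 10 seeded replicates at the >= 9/10 level
appropriate for that replication count.

## Known limitations

Time-homogeneity is the binding scientific assumption: in a cohort ageing
from 76 to 91, true intensities rise with age, so homogeneous sojourn
estimates are averages over the window. The published 10-year "remaining"
probabilities from HACC/RAC (.19/.10) are not reproducible from any single
homogeneous profile consistent with the published sojourn times — a sign
of covariate averaging or non-homogeneity in the source analysis — and are
deliberately not calibration targets. Hidden-Markov extensions
(misclassified states), frailty, informative censoring and reversible
structures beyond basic correctness are out of scope.
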