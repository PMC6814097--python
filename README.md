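# ltcmsm

Continuous-time Markov multi-state modelling of how older people move into
and through long-term care.

Ageing cohorts progress through levels of formal aged care: living without
services, entry-level home and community care (HACC), permanent residential
aged care (RAC), and death. `ltcmsm` estimates and predicts these
transitions from longitudinally observed cohorts. It is written for
epidemiologists and health-services researchers who have panel or linked
administrative data — timed state observations plus baseline covariates —
and want transition intensities, hazard ratios, sojourn times, transition
probabilities and goodness-of-fit from one consistent model.

## The model

A cohort member occupies one of the ordered states

1. **Non-user** → 2. **HACC** → 3. **RAC** → 4. **Death**

and moves along the forward arrows 1→2, 1→3, 1→4, 2→3, 2→4, 3→4 of a
progressive (no reverse moves) continuous-time Markov chain. The transition
intensities `q_ij` form the generator matrix `Q` (non-negative
off-diagonals, zero row sums), and transition probabilities over an
interval of length `t` are

```
P(t) = Exp(t Q)
```

Baseline covariates `z` act proportionally on each intensity:

```
q_ij(z) = q_ij(0) * exp(beta_ij' z)
```

so `exp(beta_ij)` is the hazard ratio of a covariate on that specific
transition. Fitting is by maximum likelihood on panel-observed or exactly
dated event histories; standard errors come from the observed information,
and derived quantities (rate ratios, next-state probabilities, mean sojourn
times, survival) get delta-method confidence intervals on log or logit
scales. A synthetic-cohort generator — calibrated to published summary
tables of a 9007-woman Australian cohort followed for 10 years — provides
reproducible test beds with known truth, since real linked aged-care data
are access-restricted.

## Worked example

```python
import ltcmsm as L

# a synthetic 2000-woman cohort with exactly dated events, known truth
tm = L.default_true_model(n=2000, seed=42)
trajectories, covariates = L.simulate_cohort(tm)
data = L.observe_cohort(trajectories, covariates, tm.scheme, tm.structure, tm.horizon)

fitted = L.fit(data)  # intercept-only maximum likelihood

trr = L.transition_rate_ratio(fitted, (1, 2), (1, 3))
print(f"TRR non-user->HACC vs non-user->RAC: "
      f"{trr.value:.2f} (95% CI {trr.lower:.2f}-{trr.upper:.2f})")
soj = L.sojourn_summary(fitted, 1)
print(f"Mean years as a non-user: {soj.value:.2f} "
      f"(95% CI {soj.lower:.2f}-{soj.upper:.2f})")
probs = L.next_state_probabilities(fitted, 1)
print("Next state from non-user:", {k: round(v, 2) for k, v in probs.items()})
Q = L.build_generator(fitted.params)
print(f"P(still a non-user after 10 years): "
      f"{L.transition_probability_matrix(Q, 10.0)[0, 0]:.2f}")
```

prints

```
TRR non-user->HACC vs non-user->RAC: 12.21 (95% CI 9.91-15.05)
Mean years as a non-user: 8.19 (95% CI 7.77-8.63)
Next state from non-user: {'HACC': 0.83, 'RAC': 0.07, 'Death': 0.11}
P(still a non-user after 10 years): 0.29
```

Read: in this simulated cohort a non-user is about twelve times more likely
to enter home care than residential care as her next move; she spends on
average about eight years without formal care, and has a 29% chance of
still using no care after ten years. The estimates bracket the generating
truth (11.08, 7.95 years, 0.28) within sampling error at n = 2000.

The same analysis runs from a shell:

```sh
ltcmsm simulate --n 2000 --seed 42 --out cohort/
ltcmsm fit      --data cohort/data.csv --out fitted/
ltcmsm predict  --model fitted/model.json --times 0:10:0.5 --out pred/
ltcmsm report   --data cohort/data.csv --model fitted/model.json --out report/
```

writing the frequency table, summary table, hazard-ratio table,
probability/survival curves and observed-vs-expected prevalence series as
CSV.

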