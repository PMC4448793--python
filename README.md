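# exitchoice

Dynamic exit-route choice in simulated crowd evacuations: which information
do people act on when picking an escape route — static features of the built
environment (exit width, route length) or the dynamic state of the crowd
(queue lengths, queue speeds)?

`exitchoice` is a research pipeline for quantitative behavioural scientists
working on tactical-level pedestrian decision-making. It provides:

- **`envsim`** — a deterministic two-exit evacuation simulator: a central
  room, a top exit feeding the longer corridor, a bottom exit feeding the
  shorter one, and a scripted crowd that splits between the exits and is
  serviced at `c · width` persons/s (so a 1.5x wider exit drains visibly
  faster).
- **`features`** — per-time-step decision features extracted from a
  participant trajectory coupled to a simulation: queue-length advantage
  `q_adv`, queue-flow advantage `f_adv`, width advantage `w_adv`, signed
  shortest-route visibility `s_vis`, distance advantage `d_adv` and a signed
  blocked-in-queue indicator `jam`; plus the outcome summaries *chose the
  shortest route* and *changed their mind*.
- **`choicemodels`** — a 16-member family of logistic per-time-step choice
  models: the log-odds of preferring the top exit are

  ```
  η = p₁ + [S]·p₂·s_vis + [W]·p₃·w_adv + [Q]·p₄·q_adv + [F]·p₆·f_adv
        + p₈·d_adv·1[|d_adv| ≥ p₉] + p₁₀·jam
  ```

  with one model per subset of the information components {Q, F, W, S};
  the constant, gated-proximity and jam terms appear in every model.
- **`evidence`** — Bayesian model selection: stepping-stone estimation of
  the marginal likelihood `P(D|X) = ∫ L(D|θ) π(θ) dθ` under bounded-uniform
  priors, replicated over independent seeds (mean ± sd), Bayes-factor
  comparisons on the `2·log BF` scale (0–6 weak-to-positive, 6–10 strong,
  >10 decisive) and block-wise rankings by Q/F inclusion pattern.
- **`glmstats`** — outcome-level statistics: logit-link binomial GLMs of
  P(shortest route) and P(change) on treatments, age and gender, Wald
  single-parameter tests, age x treatment likelihood-ratio tests, and the
  two-sided exact binomial test.
- **`cohort`** — a synthetic-cohort generator with known generating truth:
  8 experimental conditions x 58 participants, each experiencing an
  independently simulated evacuation, with choices drawn from a known family
  member — so parameter recovery, model recovery and test calibration are
  all checkable without any external data.

A `click` CLI ties the stages together
(`exitchoice simulate | cohort | extract | glm | select | report`), writing
tidy CSVs plus a SHA-256 manifest per stage.

## Worked example

```python
from exitchoice import (
    CohortDesign, generate_cohort, OutcomeTable, fit_binomial_glm,
    wald_single_parameter_test, ModelSpec, replicate_evidence,
    two_log_bayes_factor, evidence_category,
)
from exitchoice.evidence import EvidenceSettings

design = CohortDesign(n_per_condition=20, seed=1)   # 8 conditions x 20
cohort = generate_cohort(design, keep_histories=False)
print(f"cohort: {len(cohort.outcomes)} participants, "
      f"{cohort.mean_rows_per_participant:.1f} decision rows each")

table = OutcomeTable(cohort.outcomes)
fit = fit_binomial_glm(table, "chose_shortest")
print(f"W effect on P(shortest route): {fit.coefficients['W']:+.2f} log-odds, "
      f"Wald p = {wald_single_parameter_test(fit, 'W'):.4f}")

data = cohort.decision_stratum(False)               # rows outside treatment M
settings = EvidenceSettings(n_rungs=12, chain_length=200)
qf = replicate_evidence(data, ModelSpec.from_tag("QF--"), n_rep=5, base_seed=0,
                        settings=settings, stratum="nonM")
w = replicate_evidence(data, ModelSpec.from_tag("--W-"), n_rep=5, base_seed=50,
                       settings=settings, stratum="nonM")
bf = two_log_bayes_factor(qf, w)
print(f"log evidence QF--: {qf.mean:.1f} +- {qf.sd:.1f}")
print(f"log evidence --W-: {w.mean:.1f} +- {w.sd:.1f}")
print(f"2 log BF (QF-- over --W-) = {bf:.1f} ({evidence_category(bf)})")
```

Output:

```
cohort: 160 participants, 21.9 decision rows each
W effect on P(shortest route): -1.07 log-odds, Wald p = 0.0029
log evidence QF--: -383.6 +- 3.5
log evidence --W-: -529.5 +- 3.6
2 log BF (QF-- over --W-) = 291.8 (decisive)
```

Reading it: widening the top exit pulls participants away from the shorter
(bottom) route at the outcome level, but only model selection resolves *why*
— the queue-information model (Q, F) is decisively better supported than the
exit-width model (W), because this cohort's participants were generated from
queue information, and the wider exit influences them only through the
faster-moving queue in front of it.

Model tags name the included components in the order Q, F, W, S with `-`
for an excluded one: `QFWS` is the full model, `QF--` uses only queue
length and flow, `----` is the information-free baseline.

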