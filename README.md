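# idmauc — discrimination of an interval-censored disease marker

`idmauc` studies how well a binary, irreversible disease state predicts
death over time when the disease can only be detected at scheduled
screening visits.  It is aimed at biostatisticians working with
illness-death (three-state) models — e.g. post-operative metastasis
screening, dementia cohorts — who need time-specific discrimination
measures that respect the interval-censored nature of the disease time.

## The model

Subjects follow a progressive Markov illness-death process with states
0 (disease-free), 1 (diseased), 2 (dead), transition intensities
λ₀₁(t), λ₀₂(t), λ₁₂(t) and transition probabilities
P_hl(s,t) = Pr(V(t)=l | V(s)=h).  The disease state is a binary
time-dependent marker X(t).  Two time-specific AUC definitions quantify
its discrimination for survival:

* **incident/dynamic**: cases die exactly at t, controls survive past t.
  For a binary marker,

      AUC^{I/D}(t) = 0.5 + 0.5·(p(t) − π₁(t)),

  where π₁(t) = P₀₁(0,t) / (P₀₀(0,t)+P₀₁(0,t)) is the disease prevalence
  among survivors and p(t) = P₀₁ γ(t) / (P₀₀ + P₀₁ γ(t)) is the disease
  probability among the deaths, with γ(t) = λ₁₂(t)/λ₀₂(t).  γ(t) ≡ 1
  forces AUC ≡ 0.5; γ > 1 pushes it above 0.5.

* **cumulative/dynamic**: the marker is frozen at a prediction time s,
  cases die in (s,t], controls survive past t; the analogous expression
  uses only transition probabilities.

Because disease is screened at visits, its onset is interval-censored
(between the last negative and first positive screen) and the terminal
disease status of subjects whose last screen was negative is unknown.
The package implements three estimation routes that handle this to
different degrees:

1. **Cox model with the observed time-dependent marker** (ignores
   interval censoring; Breslow baseline + Aalen-Johansen probabilities,
   plus a risk-set ROC variant),
2. **piecewise-constant Markov model** fitted by the closed-form panel
   likelihood (change points at 6/30/60/90 months by default, optional
   proportional-death-hazards constraint),
3. **Weibull illness-death model** fitted by the full interval-censored
   likelihood with per-transition rates and shapes.

All three expose the same `IllnessDeathModel` contract, so the plug-in
AUC estimators (`auc_id_estimate`, `auc_cd_estimate`, `auc_curve`) work
uniformly.  A simulator generates the 18 benchmark scenarios (Weibull
hazards with common shape 0.5, rates 0.05/0.05/0.56 per month — death
hazard ratio 11.2; visit spacing 3/6/12 months; administrative or
uniform censoring), and `run_scenario` aggregates bias / empirical SE /
RMSE of every estimator against the true AUC.

## Worked example

```python
import idmauc as m

# true AUC of the generating model (months)
m.true_auc_id(m.SIMULATION_TRUTH, 12.0)        # 0.7063
m.true_auc_cd(m.SIMULATION_TRUTH, 12.0, 72.0)  # 0.5937

# simulate one benchmark dataset and fit the three models
data = m.simulate_scenario(m.scenario("A", seed=11))   # N=1000, 3-monthly visits
cox = m.CoxIDM(m.fit_cox_td(m.build_counting_process(data)))
pwc = m.PwcIDM(m.fit_pwc(data).params)
wb = m.weibull_fit_as_fitted_idm(m.fit_weibull_ic(m.summarize_intervals(data)))

for name, model in [("cox", cox), ("pwc", pwc), ("weibull", wb)]:
    print(name, round(m.auc_id_estimate(model, 12.0).value, 3))
# cox 0.657
# pwc 0.7
# weibull 0.697
```

The Cox estimate sits visibly below the true 0.706 because the marker
only switches at the first positive screen, while the two
interval-censored likelihoods recover the truth closely.  The same
pipeline is available from the shell:

```sh
idmauc truth --grid 12:60:24 --out truth.csv
idmauc simulate --scenario A --seed 11 --out panel.csv,outcomes.csv
idmauc fit weibull --panel panel.csv --outcomes outcomes.csv --out fit.json
idmauc run-scenario --name C --nsim 100 --models cox,pwc --seed 1 --out perf.csv
```

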