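# Methods

## Model and observation scheme

The package assumes a progressive, non-homogeneous Markov illness-death
process: states 0 (disease-free), 1 (diseased), 2 (dead); permitted
transitions 0→1, 0→2, 1→2; state 2 absorbing, disease irreversible.
Time is measured in **months** everywhere inside the library; reporting
layers convert to years (1 year = 12 months).

The disease state is observed only at scheduled visits, so illness
times are interval-censored: the onset lies in the half-open interval
(L, R] between the last negative screen L and the first positive screen
R.  Death/censoring times T* are exact, and a subject whose last screen
before T* was negative has unknown terminal disease status — the
likelihoods integrate over both possibilities (still disease-free, or
ill but never screened afterwards).  Screens are assumed perfect (no
misclassification) and the visit process non-informative.

## True AUC of the generating Weibull model

The generator uses Weibull intensities λ_hl(t) = α_hl k_hl t^(k_hl−1).
Staying probabilities are closed-form; P₀₁(s,t) is a one-dimensional
integral evaluated after the substitution u = w², which removes the
t^(k−1) endpoint singularity exactly at shape 0.5 (the study's common
shape) and softens it for nearby shapes.  Adaptive quadrature
(`scipy.integrate.quad`, absolute tolerance 1e-10) is used wherever the
integral is needed outside hot loops; the values are validated in the
test suite against raw adaptive quadrature of the untransformed
integrand and against Monte Carlo occupancy of simulated latent paths.

Incident/dynamic AUC: AUC(t) = 0.5 + 0.5(p(t) − π₁(t)) with
π₁(t) = P₀₁/(P₀₀+P₀₁) and p(t) = P₀₁γ/(P₀₀+P₀₁γ), γ(t)=λ₁₂/λ₀₂,
all at P(0,t).  At t = 0 the AUC is 0.5 by convention (no disease yet).
Cumulative/dynamic AUC for prediction time s and horizon t:
π₁(s,t) = P₀₁(0,s)P₁₁(s,t)/(P₀₀(0,t)+P₀₁(0,t)) and
p(s,t) = P₀₁(0,s)P₁₂(s,t)/(P₀₀(0,s)P₀₂(s,t)+P₀₁(0,s)P₁₂(s,t)).
The reporting convention is a **constant 5-year prediction window**:
curves and tables evaluate AUC(s, s+60 months).

## Simulator

Latent paths are drawn by inversion under a common shape k:
T₁ = (−ln U₁/(α₀₁+α₀₂))^(1/k); the exit state is 1 with probability
α₀₁/(α₀₁+α₀₂); conditional on illness, T_D = (T₁ᵏ − ln U₂/α₁₂)^(1/k).
Death is censored administratively at y = 120 months or by an
independent Uniform(60, 120) time.  The marker is then discretized on
the grid {0, τ, 2τ, …, y}: the observed illness visit is the first grid
point at or after T₁ ("at/after" inclusive, so an onset exactly on a
visit is detected at that visit), and visits stop at the last grid
point before end of follow-up.  Illness that is never screened before
death/censoring is unobserved, which is precisely the terminal-status
ambiguity the interval-censored likelihoods model.

The default scenario catalogue fixes the generating parameters at the
study conditions (k = 0.5, α₀₁ = α₀₂ = 0.05, α₁₂ = 0.56 per month, i.e.
a disease-vs-no-disease death hazard ratio of 11.2), N ∈ {400, 1000,
2000}, τ ∈ {3, 6, 12} months, and the two censoring schemes.  Each
subject draws from its own counter-based random stream (seed sequence
spawned on the subject index), so datasets are bit-reproducible
regardless of iteration order or parallelism.

## Estimators

**Cox with time-dependent marker.**  The observed marker switches at the
first positive visit; the counting-process representation splits each
subject at R.  With a single binary covariate the Breslow partial
likelihood depends on the data only through per-death-time counts, so
the score equation is solved by a scalar Newton iteration (tolerance
1e-10); a flat likelihood (marker constant in every risk set) keeps
β = 0, a monotone likelihood is flagged as separation and refuses AUC
evaluation.  Ties are handled by the Breslow approximation.  The 0→2
baseline uses Breslow increments, the 0→1 hazard uses Nelson-Aalen
increments treating R as exact, and dΛ₁₂ = e^β dΛ₀₂.  Transition
probabilities are the Aalen-Johansen product-integral over the merged
jump grid, with factors clipped at zero if an increment exceeds one.
When diagnosis coincides with the death time, the death is counted with
x = 1 (the marker value at the last visit); the opposite convention is
available behind a flag.

**Evaluation convention at jump times.**  Aalen-Johansen probabilities
are step functions that jump exactly at visit/death times, and the
incident/dynamic AUC is routinely evaluated at visit times.  Both
plug-in components of the incident/dynamic AUC are therefore evaluated
at the **left limit** t⁻ for jump models: the estimate at time t uses
only information observed strictly before t, matching the incident
definition (cases dying at t carry the marker held just before t).  In
particular, before the first screen no disease has been observed and
the curve equals 0.5 exactly.  Smooth models are unaffected (t⁻ = t).
The cumulative/dynamic AUC conversely evaluates the marker *at* the
prediction time s inclusively — a screen held exactly at s is part of
the marker information at s.

**Piecewise-constant panel likelihood.**  Step hazards on shared change
points (default 6, 30, 60, 90 months) give closed-form interval
transition matrices (with the q₀₁·d·e^(−q₁₂d) limit when
q₀₁+q₀₂ = q₁₂, switched on a relative tolerance of 1e-9).  The panel
likelihood multiplies visit-pair factors P₀₀/P₀₁/P₁₁, an exact-death
factor Σ_l P_hl(v*,T*) λ_l2(T*⁻) summed over the live states, and a
censoring factor Σ_l P_hl(v*,T*).  Hazards are left-continuous: the
value at a change point belongs to the piece ending there, and the
death-time hazard uses the left-limit piece.  Because visit grids are
regular, pair contributions collapse onto a few dozen distinct
intervals whose piece-overlap durations are precomputed once per fit;
one likelihood evaluation is a handful of vectorized exponentials, and
maximization runs on log rates (L-BFGS-B, bounds −16..3, ftol 1e-12).
Rates of pieces without information drift to the lower bound and stay
there.  The optional proportional constraint replaces the free 1→2
rates by λ₀₂,j e^β.  AUC evaluation defaults to the **unconstrained**
fit (three free step hazards); the constrained fit exists mainly for
hazard-ratio reporting.  Standard errors come from a central-difference
Hessian of the log-parameterized likelihood (relative step 1e-4).

A structural caveat of this model class: within a piece the fitted rate
is a person-time-weighted average of the true hazard, and state-1
person-time sits later inside a piece than state-0 person-time.  With
steeply decreasing true hazards this attenuates the fitted death-hazard
ratio relative to the instantaneous ratio, so constrained hazard-ratio
estimates should be read as piece-averaged quantities.

**Weibull interval-censored likelihood.**  Six free parameters (rate and
shape per transition — shapes are not constrained equal even though the
simulator uses a common shape).  Each subject contributes one of four
closed-form-plus-integral terms depending on whether disease was ever
observed and whether the subject died; all integrals share one kernel
P₀₀(L,u) λ₀₁(u) P₁₁(u,T) evaluated on a fixed 15-node Gauss-Legendre
grid after the u = w² substitution, vectorized across subjects.  The
node count is validated against adaptive quadrature (agreement well
below 1e-8 on study-scale intervals), and the four contribution types
are verified to form a proper probability model by summing the
likelihood over every possible observed outcome of a subject (the test
integrates the death-time densities over each inter-visit window and
checks the total equals 1).  Maximization runs on log parameters with a
three-point multi-start (crude occurrence/exposure rates rescaled to
shapes 1, 0.7, 0.5) and keeps the best optimum; the time-dependent
hazard ratio λ₁₂(t)/λ₀₂(t) is constant when the fitted shapes coincide.

## Simulation harness

`run_scenario` simulates a scenario, fits the requested models per
replicate, evaluates the incident/dynamic AUC at 12/36/60 months and
the cumulative/dynamic AUC at (12,72)/(36,96)/(60,120) months, and
aggregates bias (mean − truth), empirical SE (n−1 denominator) and RMSE
against the true generating-model AUC.  Replicate seeds derive from the
run seed through a splittable seed sequence; failed fits are logged and
excluded without aborting the run.  The default problem sizes used by
the acceptance checks — 100 replicates for the Cox and
piecewise-constant comparisons, 50 for the Weibull fit — were chosen so
Monte Carlo error on a bias is a few thousandths, an order of magnitude
below the effects of interest; full-scale runs (nsim = 1000) use the
same code path via the `nsim` argument.

## Numerical and design choices

* An onset time that falls exactly on a visit is detected at that visit;
  a death exactly at a visit keeps that visit in the record.  Illness
  entering the data means T₁ ≤ T*; subjects censored before their onset
  are recorded disease-free.
* The interval summary is lossless for (L, R, T*, δ) and half-open:
  illness occurred strictly after L, at or before R.  A first-ever
  positive screen sets L = 0.
* CSV formats: long panel `id,time,marker`; outcomes `id,tstar,delta`;
  derived intervals `id,L,R,tstar,delta` with an empty field for an
  absent R.
* Probabilities are clipped into [0,1] only to absorb float round-off
  (negative values beyond 1e-8 would fail validation instead).
* All optimizers are deterministic; the only randomness enters through
  the simulator seeds.

## What the synthetic data does and does not cover

The generator reproduces the benchmark study conditions: proportional
Weibull death hazards with a large, constant hazard ratio, perfectly
regular visit grids shared by all subjects, perfect screens, and
censoring independent of the process.  Real screening cohorts violate
several of these — visit schedules drift and depend on symptoms,
screens misclassify, hazards need not be Weibull or proportional (the
Weibull fit's advantage here partly reflects that the data are
generated from its own family).  Passing tests therefore demonstrate
correctness of the estimators and their interval-censoring handling
under the stated conditions, not robustness to informative observation
or model misspecification.  Small samples (a few hundred subjects) make
all three fits noticeably unstable; the piecewise-constant model
additionally needs enough events per piece.
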