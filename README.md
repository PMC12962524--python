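# hte-emulate

Target-trial emulation of an mHealth blood-pressure program, as a tested,
reusable Python pipeline: G-formula outcome regression with a
cross-validated stacking ensemble for average and individual treatment
effects, and a clustering-based procedure for discovering treatment-effect
heterogeneity — together with a synthetic-cohort generator that stands in
for the proprietary checkup/claims data such analyses run on.

It is written for biostatisticians and epidemiologists who want to study,
extend, or stress-test this analysis design (rare treated arm, confounded
uptake, mixed-type covariates with missingness, cluster-based effect-modifier
discovery) with full ground truth available.

## The estimand and the method

For baseline covariates X, program indicator A and binary outcome Y
(uncontrolled hypertension at the one-year checkup: SBP ≥ 140 mmHg or
DBP ≥ 90 mmHg), an outcome model μ̂(a, x) ≈ E[Y | A=a, X=x] is fit by a
Super Learner: candidate learners (GLMs, random forest, neural network,
MARS-style splines, gradient boosting) are combined with non-negative
weights summing to one that minimize cross-validated squared error.  The
G-formula then gives, per person,

    ITE_i = μ̂(1, x_i) − μ̂(0, x_i)          (risk difference; negative = benefit)
    ATE   = mean_i ITE_i
    RR    = mean_i μ̂(1, x_i) / mean_i μ̂(0, x_i)
    NNT   = 1 / |ATE|
    E-value = rr* + sqrt(rr*(rr*−1)),  rr* = max(RR, 1/RR)

with percentile-bootstrap intervals.  Heterogeneity: ITEs are jittered,
standardized to mean 0 / SD 0.1, clustered with Ward linkage (Euclidean
distance, 2–10 clusters) with the cluster count chosen by Beale's F test
at α = 0.01; candidate effect modifiers are covariates whose per-cluster
z-score spread exceeds 0.25 (0.20/0.30 as sensitivity thresholds), and
each cluster is summarized by its CATE, RR, NNT and E-value.

The synthetic generator draws confounded uptake (4.1% treated), a
logistic outcome risk with planted treatment-covariate interactions, and
follow-up pressures consistent with the binary outcome — and returns the
exact per-person risk differences (`OracleEffects`) so recovery can be
scored.  See `docs/methods.md` for assumptions, parameter choices, and
limitations.

## Worked example

Either run the numbered analysis scripts

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_impute_missing.py  --seed 1
python analysis/03_estimate_effects.py --seed 1
python analysis/04_discover_heterogeneity.py --seed 1
python analysis/05_report.py --seed 1      # writes results/report.md
```

or the equivalent CLI one-shot `hte-emulate run --seed 1 --out out/`.
With seed 1 the scripts print (abridged):

```
cohort: n=3092, treated=121 (3.9%), uncontrolled-BP prevalence 31.3%,
        oracle ATE -0.0400, 1806 missing covariate cells
imputation converged in 4 iteration(s); benchmark NRMSE 0.546 (vs 0.565 mean-fill)
ensemble weights: {'glm': 0.696, 'glm_tx_interactions': 0.0,
                   'random_forest': 0.191, 'neural_network': 0.0,
                   'mars': 0.113, 'gradient_boosting': 0.0}
ATE (stack, weight-refit bootstrap): 2.9% (95% CI: 2.4% to 3.3%) higher prevalence
ATE (GLM, full-refit bootstrap):     +3.5% (95% CI: -2.3% to +10.3%)
RR: 1.09 (95% CI: 1.08 to 1.11) | NNT: 34.4 | E-value: 1.41
k = 2 (no_significant_structure=True)
top importance: ['sbp', 'dbp', 'bmi', 'hba1c', 'triglycerides']
```

Reading this: the generator's true ATE is −4.0%, but with only 121
treated people a single cohort draw carries a standard error of ~4
percentage points — this draw lands on the wrong side of zero, and the
honest full-refit interval (−2.3% to +10.3%) says exactly that, while the
weight-refit bootstrap, which holds the fitted learners fixed, is far too
confident.  The two-cluster solution at this scale separates people by
baseline blood pressure (a risk gradient), not by the planted modifiers.
Both observations are the point of the package: estimator *bias* and
modifier *recovery* are established by the multi-seed simulations in
`tests/test_acceptance.py` (20 cohorts of n = 20,000 give |mean ATE
error| < 0.01; planted-modifier cohorts of n = 5,000 recover k = 2 and
both modifiers in ≥ 80% of seeds), not by any single study-scale run.

## Layout

```
src/hte_emulate/   schema, generator, imputation, ensemble, G-computation,
                   heterogeneity, pipeline, CLI
analysis/          numbered stage drivers writing results/
tests/             unit + property + acceptance suites (pytest)
scripts/           acceptance.py
docs/methods.md    model, assumptions, numerical choices, limitations
```
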