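# discboost

Component-wise gradient boosting for **discrete failure time models** with
time-varying effects and hierarchical two-way interactions.

Large disease registries (cancer registries, administrative cohorts) record
survival on a coarse grid — months since diagnosis — with heavy ties, which
discrete-time hazard models handle natively. `discboost` addresses the model
selection problem in that setting: among P baseline covariates and their
P(P−1)/2 pairwise interactions, which covariates matter, which of them have
effects that *change* over follow-up, and which interactions should enter —
while respecting the strong or weak hierarchy principle (an interaction may
enter only if both / at least one of its main effects is in the model).

## Model

The hazard of subject i at grid time t_s is logistic:

λ(t_s; Z_i) = expit( γ_s + Σ_j φ_j z_ij + Σ_j θ_jᵀB(t_s) z_ij + Σ_{j<j'} α_jj' z_ij z_ij' )

with baseline log-odds γ_s, time-independent effects φ_j, time-varying
effects β_j(t) = θ_jᵀB(t) in a reduced cubic B-spline basis (K = 7 functions
with the first dropped, so θ_j = 0 ⇔ a time-independent effect), and
interaction coefficients α_jj'; all effects are log odds ratios. Selection
is by component-wise gradient boosting on the pseudo-observation gradient
U_is = y_is − λ_is with step ν = 0.5: per iteration the baseline is updated
in closed form and the single best-fitting term (by least squares) is
advanced. Nothing is ever expanded into a long-format table, so runtime
scales to registry-size data. Two data-driven stopping rules are provided —
a boosting BIC using trace of the accumulated approximate hat matrix, and a
re-estimation BIC that refits the selected structure by penalized Newton
(P-spline or smoothing-spline penalty, smoothing parameter by TIC) and uses
the penalized-likelihood degrees of freedom. See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
import discboost as db
from discboost import refit as rf
from discboost.boosting import BoostingConfig, run_boosting

# 500 subjects, 20 covariates, 19-month grid; truth: z1..z5 matter,
# z2/z4/z5 with genuinely time-varying effects
spec = db.scenario_preset("highdim", n=500, P=20, seed=42)
data, truth = db.make_dataset(spec)
basis = db.build_reduced_basis(data.grid, K=7)

trace = run_boosting(data, basis, BoostingConfig(m_max=400, stopping="boosting_bic"))
state = trace.final_state()
print(trace.m_stop, [f"z{j+1}" for j in state.selected_main()])

m_stop, fit, _ = rf.reestimation_bic_path(data, basis, trace,
                                          lambda_grid=(0, 0.01, 0.1, 1, 10, 100))
print(m_stop, [f"z{j+1}" for j in trace.state_at(m_stop).selected_main()])

z1 = np.zeros(20); z1[0] = 1.0
curve = rf.hazard_ratio_curve(fit, basis, z1, np.zeros(20))
print(round(curve["estimate"][0], 2), round(curve["lo"][0], 2), round(curve["hi"][0], 2))
```

Output:

```
220 ['z1', 'z2', 'z3', 'z5', 'z12', 'z15', 'z17', 'z20']
60 ['z1', 'z2', 'z3', 'z5']
2.5 2.06 3.04
```

The boosting BIC stops at iteration 220 and keeps four of the five true
signals plus four noise covariates — it is deliberately liberal. The
re-estimation BIC stops at iteration 60 with the same four true signals and
*no* noise (z4's sine effect is the weakest and is missed at this sample
size). The refit then estimates the odds ratio for a unit increase in z1 as
2.50 (95% CI 2.06–3.04), flat over time because z1 was selected as
time-independent; its true value is e¹ ≈ 2.72.

The same pipeline is available from the shell:

```bash
discboost simulate --scenario highdim --n 500 --p 20 --seed 42 --out data.csv
discboost boost --data data.csv --stopping reestimation_bic --hierarchy strong \
                --out trace.json --model-out selected.json
discboost refit --data data.csv --model selected.json --penalty pspline --lam auto --out fit.json
discboost curve --data data.csv --model fit.json \
                --z1 1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0 \
                --z0 0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0 --out curve.csv
```

Input CSVs have columns `id`, `time` (1-based grid index, or raw times with
`time_mode="value"` in the library), `event` (1 = failure, 0 = censored —
code competing events as censored for a cause-specific analysis), then one
column per covariate.

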