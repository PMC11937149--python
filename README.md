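# trialcea

Within-trial cost-effectiveness analysis for cluster-randomised trials,
built for health economists evaluating primary-care interventions from
participant-level data: per-participant cost and QALY construction,
predictive-mean-matching multiple imputation with Rubin's rules,
cluster-adjusted marginal (GEE) models with recycled predictions,
net-benefit and cost-effectiveness acceptability analysis with a
shrinkage-corrected two-stage cluster bootstrap, and a declarative
deterministic-sensitivity engine. A calibrated synthetic-trial generator
makes every stage testable without access to any real trial data.

## The analysis in brief

For participant *i* in practice cluster *j* of arm *k*, the six-month
total healthcare cost is

```
c_ijk = intervention cost + (medications started) − (medications stopped)
        + Σ_item  count_item × unit_cost_item
```

(so totals can be negative when deprescribing savings dominate), and the
effect is QALYs gained by the area-under-the-curve rule,
`e_ijk = h · (u_baseline + u_followup) / 2` with `h = 0.5` years and `u`
the EQ-5D-5L utility index from a pluggable value set. Incremental costs
and QALYs are adjusted arm contrasts from generalized estimating equations
with an exchangeable working correlation over practices — gamma variance /
identity link for costs, gaussian / identity for QALYs, each controlling
for treatment arm and the baseline analogue of the outcome — with
cluster-robust standard errors and adjusted means by recycled predictions
(marginal standardisation). Missing item-level costs and utilities are
multiply imputed by predictive mean matching (M = 10 completed datasets,
5 nearest-predicted-mean donors) and pooled by Rubin's rules.

Cost-effectiveness at willingness-to-pay λ is judged through the net
benefit `nb_ijk = e_ijk · λ − c_ijk`: the intervention is cost-effective
when the incremental net benefit (INB) is positive. The probability of
cost-effectiveness across λ (the CEAC) comes from three methods: a
two-stage non-parametric bootstrap (clusters resampled within arm, then
participants within clusters, with a shrinkage correction so the two
stages do not double-count within-cluster variance), the parametric
normal approximation Φ(INB/SE), and Monte-Carlo simulation of the
incremental estimates.

## Worked example

Simulate a trial at the default emulation scale (≈50 practices, ≈400
older adults with high baseline polypharmacy, right-skewed costs
dominated by inpatient nights, 43% follow-up questionnaire non-response)
and run the full evaluation:

```python
import trialcea as tc

sim = tc.SimConfig(seed=7)                       # generator conditions
cfg = tc.PipelineConfig(seed=7, b_bootstrap=500)  # analysis settings
res = tc.run_pipeline(sim, cfg)

print(f"participants: {res.manifest['n_participants']} in {res.manifest['n_clusters']} practices")
print(f"incremental cost (MI):  {res.mi_cost.delta:8.2f}")
print(f"incremental QALYs (MI): {res.mi_qaly.delta:8.4f}")
print(f"INB at 20,000 per QALY: {res.inb[20000.0].delta:8.2f}")
print(f"dominance: {res.dominance}")
boot = res.ceacs['two_stage_bootstrap']
print(f"P(cost-effective | 20k): {boot.probability_at(20000):.3f}")
```

prints

```
participants: 408 in 50 practices
incremental cost (MI):   -730.11
incremental QALYs (MI):   0.0077
INB at 20,000 per QALY:   899.23
dominance: dominant
P(cost-effective | 20k): 0.820
```

i.e. this simulated intervention saved €730 per participant and gained
0.008 QALYs over six months — cheaper *and* more effective (dominant) —
with an 82% probability of being cost-effective at €20,000 per QALY.
Both incremental estimates carry wide confidence intervals
(`res.mi_cost.ci_low/ci_high`), which is why decisions rest on the CEAC
rather than on significance tests. `res.write_bundle("out/")` writes the
descriptive, incremental, CEAC and manifest files;
`trialcea.scenario_battery` re-runs the pipeline under the deterministic
sensitivity scenarios (halved/doubled intervention cost, ±15% unit
costs, 3-month medication horizon, component exclusions, alternative
families/links, unadjusted models, imputation variants, pandemic-period
covariate or subgroup).

The same stages are available from the shell:

```bash
trialcea simulate --seed 7 --out data/
trialcea report --data data/ --seed 7 --out bundle/
trialcea sensitivity --data data/ --seed 7 --out scenarios.csv
```

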