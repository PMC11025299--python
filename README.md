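# copritest

Simultaneous inference for diagnostic accuracy studies in which several
candidate index tests are evaluated against minimal acceptance criteria for
the co-primary endpoints sensitivity and specificity.

A study succeeds for test *j* only if both endpoints clear their thresholds
(intersection–union principle): reject iff `min(Z_se_j, Z_sp_j) > c`.
Because many candidate tests (markers, cut points, prediction models) are
often evaluated on the same validation data, the critical value `c` must
control the family-wise error rate (FWER) across tests. `copritest`
implements five such procedures, the dual rectangular *comparison* and
*confidence* regions, two synthetic data generators, and a simulation engine
estimating FWER and disjunctive power.

## Procedures

| name | critical value |
| --- | --- |
| `none` | unadjusted normal quantile `z_{1-α}` |
| `bonferroni` | `z_{1-α/m}` (divisor *m*, not 2*m* — co-primary adaptation) |
| `maxt` | equicoordinate quantile of an m-variate normal with the estimated correlation of the binding statistics at the least-favourable configuration |
| `pairs` | stratified subject-level bootstrap of the maximum statistic |
| `wild` | residual bootstrap with per-subject random weights |
| `mbeta` | Bayesian beta-binomial simultaneous posterior lower bounds (no p-values) |

All except `mbeta` provide multiplicity-adjusted p-values. Comparison
regions (per-bound level `α/m` for Bonferroni, or the procedure's joint
critical value) are exactly dual to the test decisions; confidence regions
(`α/(2m)`, or 2m-dimensional quantiles) jointly cover all 2m parameters and
are strictly more conservative.

## Command line

```sh
# analyze a dataset (CSV: 'disease' column, then one 0/1 column per test)
copritest evaluate --data study.csv --config analysis.yaml --out-dir results/

# synthesize a dataset from a generator config
copritest generate --config generator.yaml --seed 7 --out-dir synth/

# run an FWER/power simulation scenario
copritest simulate --config scenario.yaml --seed 1 --out-dir sim/
```

Analysis config keys (all optional): `se0`, `sp0` (acceptance criteria,
default 0.8), `alpha` (one-sided, default 0.025), `shrinkage` (pseudo-count
h, default 0.5), `procedures`, `B`, `seed`, `lfc_pr`, `posterior_draws`,
`weight_dist`. Generator configs carry `setting: lfc` (m, se0, sp0, b,
rho_se, rho_sp, n1, n0) or `setting: biomarker` (l, auc, marker_correlation,
cutpoints, n1, n0). Scenario configs combine a generator, a hypothesis
block, a procedure list and `nsim`. Every command writes a JSON manifest
with seeds and file hashes; results are byte-reproducible given the seed.

## Python API

```python
import copritest as cp

cfg = cp.LfcConfig(m=10, se0=0.8, sp0=0.8, n1=25, n0=75, rho_se=0.5, rho_sp=0.5)
data, truth = cp.generate_lfc_data(cfg, seed=1)
hyp = cp.HypothesisSpec(se0=0.8, sp0=0.8, alpha=0.025)

res = cp.fit_procedure(data, hyp, "maxt")      # decisions, c, adjusted p
reg = cp.comparison_regions(data, hyp, "maxt", result=res)

scn = cp.SimScenario(generator=cfg, hypothesis=hyp,
                     procedures=("none", "bonferroni", "maxt", "pairs"),
                     nsim=2000, base_seed=1)
sim = cp.run_scenario(scn)                     # FWER / power with MC SEs
```

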