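# crbench — are two competing-risks models *significantly* different?

Clinical prediction papers routinely report that model A beat model B by a
few points of some accuracy score, with no statistical evidence that the gap
exceeds what resampling noise produces.  `crbench` is a simulation study in
package form that takes that question seriously for competing-risks survival
data: it compares a classical regression model against a machine learning
ensemble with proper hypothesis tests, on data whose truth is known.

**The contestants.**  Both models predict the cumulative incidence function
of the event of interest (cause 1), `CIF1(t|x) = P(T <= t, cause = 1 | x)`:

- the **Fine-Gray model** — proportional subdistribution hazards,
  `CIF1(t|x) = 1 - exp(-Lambda0(t) e^{beta'x})`, fitted by IPCW-weighted
  partial likelihood (subjects failing from the competing cause stay in the
  risk set with Kaplan-Meier censoring weights `G(t-)/G(T_j-)`);
- a **random survival forest for competing risks** — bootstrap trees split
  by the generalised log-rank statistic for cause 1,

      i_k(x, s) = sum_j [ d_{k,L}(t_j) - d_k(t_j) R_L(t_j)/R(t_j) ] / sigma_hat,

  with Aalen-Johansen curves in the terminal nodes, averaged over the
  ensemble (ntree = 500, nodesize = 15, nsplit = 2, mtry = p).

**The score.**  The IPCW integrated Brier score of the predicted CIF:
`BS(t)` is the censoring-weighted mean squared residual between
`I(T <= t, cause 1)` and `CIF1_hat(t|x)`, and IBS is its time-average over
the event-time grid.  Lower is better; an uninformative `CIF = 0.5` scores
exactly 0.25.

**The verdict machinery.**  The 5x2-fold cross-validated paired t-test and
the combined 5x2-cv F-test.  Five random halvings of the data; each half
trains once and tests once; with fold differences `p_i^(j)` and replication
variances `s_i^2`,

    t = p_1^(1) / sqrt( (1/5) sum_i s_i^2 )      ~ t(5), two-sided
    f = sum_ij (p_i^(j))^2 / (2 sum_i s_i^2)     ~ F(10, 5), reject if f > 4.74

**The arena.**  Synthetic two-cause data with 6 normal + 6 Bernoulli(0.5)
covariates and constant cause-specific hazards `0.01 * exp(eta_k(x))`, under
four structures for `eta_k`: linear (the regression's home turf), quadratic
and interaction (where it is misspecified), and null (no covariate effects —
the type-I-error testbed).  Effects: log 2 per continuous unit, 1.5 per
binary flag; independent exponential censoring (~25%).

## Worked example

```
$ crbench simulate --scenario quadratic -n 400 --seed 7 -o quad400.csv
wrote 400 subjects to quad400.csv (event counts: {0: 76, 1: 168, 2: 156})

$ crbench compare quad400.csv --ntree 100 --seed 3
mean cv IBS  fine-gray: 0.2495   rsf-cr: 0.2067
5x2cv paired t: statistic=4.7556 df=t(5) p=0.0051 -> significant at alpha=0.05
5x2cv combined F: statistic=20.1032 df=F(10,5) p=0.0020 -> significant at alpha=0.05
```

On quadratic data the forest's cross-validated IBS (0.207) is well below
the Fine-Gray model's (0.250 — no better than the uninformative benchmark,
as the squared effects are invisible to a linear-in-x model), and both
tests call the difference significant at the 5% level.

The numbered drivers in `analysis/` run the full study: `01` simulates and
describes one dataset per scenario, `02` runs the benchmark grid
(`results/summary.csv`, `results/replicates.csv`), `03` runs the
type-I-error study under the null.  Desk-scale defaults finish in minutes;
the full published protocol (1000 replicates, 500 trees, n up to 3000) is a
flag change away and runs overnight.  At desk scale (100 replicates of
n=200, 100-tree forests) the study reproduces the qualitative findings:
Fine-Gray wins on linear data (mean cv IBS 0.156 vs 0.195), the forest wins
on quadratic data (0.223 vs 0.267) and edges ahead on interaction data
(0.218 vs 0.233), and both tests' rejection rates rise with n wherever a
real difference exists.  See `docs/methods.md` for conventions that move
absolute IBS levels at the second decimal, and for why the null scenario
does not make the two models exactly exchangeable.

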