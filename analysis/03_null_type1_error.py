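#!/usr/bin/env python
"""Type-I-error study: both tests under the all-effects-zero scenario.

Simulates null-scenario datasets (neither cause depends on the covariates),
runs the 5x2-cv Fine-Gray vs forest comparison per replicate, and reports
the empirical rejection rate of the paired t-test and the combined F-test at
alpha = 0.05, the mean cv IBS of both models (0.25 is the benchmark for an
uninformative predictor), and a chi-square uniformity check of the p-value
samples.

Writes results/null_summary.csv, results/null_pvalues.csv and
results/null_uniformity.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from crbench.forest import ForestConfig
from crbench.study import StudyConfig, run_null_study


def uniformity_check(pvals: pd.DataFrame, bins: int = 10) -> pd.DataFrame:
    rows = []
    for n, grp in pvals.groupby("n"):
        for col in ("t_pvalue", "f_pvalue"):
            counts, _ = np.histogram(grp[col], bins=bins, range=(0, 1))
            chi2, p = stats.chisquare(counts)
            rows.append({"n": n, "test": col.split("_")[0],
                         "chi2": round(chi2, 2), "p_uniform": round(p, 4)})
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sizes", nargs="+", type=int, default=[500])
    ap.add_argument("--seed-blocks", type=int, default=10)
    ap.add_argument("--reps", type=int, default=20)
    ap.add_argument("--ntree", type=int, default=100)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = StudyConfig(
        sizes=tuple(args.sizes),
        seeds=tuple(range(args.seed_blocks)),
        reps_per_seed=args.reps,
        forest=ForestConfig(ntree=args.ntree),
        out_dir=args.out_dir,
    )
    summary, pvals = run_null_study(config)
    uni = uniformity_check(pvals)
    uni.to_csv(args.out_dir / "null_uniformity.csv", index=False)

    print(summary.round(3).to_string(index=False))
    print("\np-value uniformity (chi-square over 10 bins):")
    print(uni.to_string(index=False))
    print("\npct_sig_* are empirical type-I error rates x 100 at alpha=0.05 "
          "IF the two models truly performed alike under the null scenario; "
          "a small systematic performance gap inflates them.")


if __name__ == "__main__":
    main()
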