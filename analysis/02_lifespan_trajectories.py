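#!/usr/bin/env python
"""Fit lifespan hemispheric trajectories and derive the asymmetry
difference-trajectory for a synthetic longitudinal cohort.

Simulates a 500-subject mixed cross-sectional/longitudinal cohort whose
left-hemisphere curve carries a developmental asymmetry component peaking
at 24.3 years, runs the >6 SD gross-error pass, fits the factor-smooth
penalized-spline mixed model, and reports the difference trajectory, its
tests, the age at peak asymmetry, and ICV-adjusted relative change.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cortasym.simulate import simulate_lifespan
from cortasym.trajectories import (
    detect_and_refit_outliers,
    difference_trajectory,
    fit_factor_smooth,
    peak_asymmetry_age,
    relative_change,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

table, truth = simulate_lifespan(
    n_subjects=500, seed=args.seed,
    outlier_spec=[{"n": 2, "offset": 8, "hemi": "L"}],
)
print(f"simulated {len(table)} scans from "
      f"{table.subject_id.nunique()} subjects, ages "
      f"{table.age.min():.1f}-{table.age.max():.1f}")

fit0 = fit_factor_smooth(table)
cleaned, fit, log = detect_and_refit_outliers(table, fit0, sd_threshold=6.0)
print(f"gross-error pass removed {len(log)} scans "
      f"(planted: {int(truth.outlier_flags.outlier_lh.sum())})")

grid = np.linspace(*fit.age_range, 200)
traj = difference_trajectory(fit, grid)
mu_l, se_l = fit.predict(grid, "L")
mu_r, se_r = fit.predict(grid, "R")
pd.DataFrame(
    {"age": grid, "lh": mu_l, "rh": mu_r, "d": traj.d, "se": traj.se,
     "lo": traj.ci_low, "hi": traj.ci_high}
).to_csv(args.out / "trajectory_cluster1.tsv", sep="\t", index=False)
print(f"asymmetry != 0 anywhere: p = {traj.p_nonzero:.3g}")
print(f"asymmetry changes with age: p = {traj.p_change:.3g}")

peak, _ = peak_asymmetry_age(fit)
print(f"age at peak asymmetry (CI-gap criterion): {peak:.1f} years "
      f"(planted peak 24.3)")

fit_icv = fit_factor_smooth(cleaned, include_icv=True)
rel = relative_change(fit_icv, grid)
rel.to_csv(args.out / "relative_change_cluster1.tsv", sep="\t", index=False)
print(f"relative change at max age: LH {rel.rel_L.iloc[-1]:.3f}, "
      f"RH {rel.rel_R.iloc[-1]:.3f} (both scaled to 1 at age "
      f"{grid[0]:.1f})")
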