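#!/usr/bin/env python
"""Association screen: general cognition, handedness, sex, and ICV against
cluster asymmetry.

Simulates the 11-test cognition battery with 10% missingness and planted
effects (a handedness effect on one cluster, a sex effect on another),
builds the general-cognition composite by iterative-PCA imputation + PC1,
and runs the two-model-family screen with Bonferroni correction at
0.01 / (n_clusters x 4).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cortasym.associations import cognition_pc1, fit_associations
from cortasym.simulate import simulate_covariates_battery

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

cluster_ids = [f"c{i}" for i in range(8)]
directions = dict(zip(cluster_ids, ["leftward"] * 4 + ["rightward"] * 4))
table, truth = simulate_covariates_battery(
    n_subjects=5000,
    cluster_ids=cluster_ids,
    cluster_directions=list(directions.values()),
    effects_spec={("c0", "handedness"): -0.06, ("c5", "sex"): 0.05},
    seed=args.seed,
)
print(f"simulated battery for {len(table)} subjects "
      f"({table.filter(regex='^ai_').shape[1]} clusters; "
      f"{(table.handedness == 'left').mean():.1%} left handers)")

pc = cognition_pc1(table, age=table["age"].to_numpy())
print(f"cognition PC1 explains {100 * pc.variance_share:.1f}% of battery "
      f"variance (imputation rank {pc.rank}, {pc.n_iter} iterations); "
      f"corr with age = "
      f"{np.corrcoef(pc.scores, table['age'])[0, 1]:.2f}")

covars = table.drop(columns=[c for c in table.columns
                             if c.startswith("ai_")])
covars["cognition_pc1"] = pc.scores
ai = table[["subject_id"] + [f"ai_{c}" for c in cluster_ids]]
res = fit_associations(ai, covars, directions=directions, alpha_base=0.01)
res.to_csv(args.out / "associations.tsv", sep="\t", index=False)

alpha = res.attrs["bonferroni_alpha"]
hits = res[res.sig_bonferroni]
print(f"{len(res)} tests at Bonferroni alpha = {alpha:.2e}; "
      f"{len(hits)} significant:")
for _, r in hits.iterrows():
    print(f"  {r.cluster_id} ~ {r.predictor}: beta = {r.beta:.3f} "
          f"[{r.ci_low:.3f}, {r.ci_high:.3f}], p = {r.p:.2g}")
print("planted: handedness on c0 (-0.06), sex on c5 (+0.05, rightward "
      "cluster, so the screened sign is negative after inversion)")
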