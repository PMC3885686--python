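#!/usr/bin/env python
"""Identification study: which transformations find the informative genes.

Simulates binary outcomes over a fixed synthetic cohort (10 informative
genes, SNR 2.5, linear and logarithmic effect scenarios), fits
componentwise likelihood-based boosting on every transformed covariate
matrix, and scores the selection path by the mean number of true
positives within at most ten false positives (pAUC10).  Writes per-
replicate values, per-tag summaries and box-plot data under
results/identification/.
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from seqsig.experiments import StudyConfig, make_report, prepare_cohort, run_simulation_study
from seqsig.transforms import TAGS

SEED = 0
SCALE = dict(n_genes=2000, n_samples=200, n_informative=10, n_replicates=10, max_steps=500)

root = Path(__file__).resolve().parents[1] / "results" / "identification"
t0 = time.time()
cohort = None
frames = []
for scenario in ("linear", "logarithmic"):
    cfg = StudyConfig(effect_scale=scenario, tags=TAGS, seed=SEED, **SCALE)
    if cohort is None:
        cohort = prepare_cohort(cfg)
    df = run_simulation_study(cfg, cohort=cohort)
    frames.append(df)
    means = df.groupby("tag")["pauc10"].mean().sort_values(ascending=False)
    print(f"\n{scenario} effects - mean pAUC10 over {SCALE['n_replicates']} replicates:")
    for tag, m in means.items():
        print(f"  {tag:>20s}  {m:.2f}")

import pandas as pd

all_results = pd.concat(frames, ignore_index=True)
cfg = StudyConfig(effect_scale="linear", tags=TAGS, seed=SEED, **SCALE)
make_report(root, cfg, sim_results=all_results)
print(f"\nwrote {root} in {time.time() - t0:.0f}s")
print("expected pattern: standardized and rank-based transformations beat the "
      "naive covariates under linear effects; plain standardization falls "
      "behind the log/rank variants when the true effects are logarithmic")
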