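#!/usr/bin/env python
"""Generate the synthetic cohort used by the downstream analyses.

Draws a correlated, overdispersed RNA-Seq count matrix with gene
metadata, clinical covariates and a time-to-event outcome driven by ten
informative genes (log-scale effects), and writes everything as TSV
under results/data/ together with a JSON manifest of all parameters.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from seqsig.experiments import CONVENTIONS
from seqsig.io import (
    write_clinical_tsv,
    write_counts_tsv,
    write_gene_meta_tsv,
    write_manifest,
    write_survival_outcome_tsv,
)
from seqsig.synthetic_data import (
    SimulationDesign,
    choose_informative_genes,
    generate_clinical,
    generate_counts,
    simulate_survival_outcome,
)

SEED = 0
N_GENES, N_SAMPLES, N_INFORMATIVE = 1000, 200, 10
CENSOR_RATE = 0.3

out = Path(__file__).resolve().parents[1] / "results" / "data"
out.mkdir(parents=True, exist_ok=True)

counts = generate_counts(N_GENES, N_SAMPLES, seed=SEED)
clinical = generate_clinical(N_SAMPLES, seed=SEED + 1)
informative = choose_informative_genes(counts.genes, N_INFORMATIVE, seed=SEED + 2)

pos = {g.gene_id: i for i, g in enumerate(counts.genes)}
idx = np.array([pos[g] for g in informative])
log_cov = np.log1p(counts.counts[idx].astype(float))
beta = np.zeros(N_GENES)
beta[idx] = 1.0 / np.std(log_cov.sum(axis=0))  # unit-variance gene signal
design = SimulationDesign(
    N_SAMPLES, N_GENES, N_INFORMATIVE, 2.5, "logarithmic", informative, beta, SEED
)
outcome = simulate_survival_outcome(counts, clinical, design, censor_rate=CENSOR_RATE, seed=SEED + 3)

write_counts_tsv(counts, out / "counts.tsv")
write_gene_meta_tsv(counts.genes, out / "gene_meta.tsv")
write_clinical_tsv(counts.sample_ids, clinical, out / "clinical.tsv")
write_survival_outcome_tsv(counts.sample_ids, outcome, out / "survival.tsv")
write_manifest(
    {
        "seed": SEED,
        "n_genes": N_GENES,
        "n_samples": N_SAMPLES,
        "informative_genes": informative,
        "effect_size": float(beta[idx][0]),
        "censor_rate_target": CENSOR_RATE,
        "censor_rate_achieved": float(1 - outcome.event.mean()),
        "conventions": CONVENTIONS,
    },
    out / "manifest.json",
)

print(f"cohort: {N_GENES} genes x {N_SAMPLES} samples -> {out}")
print(f"events: {int(outcome.event.sum())} ({outcome.event.mean():.0%}); "
      f"median time {np.median(outcome.time):.2f}")
print(f"informative genes: {', '.join(informative)}")
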