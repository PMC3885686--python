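"""Plain-text readers/writers for the pipeline's tabular formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix
from .synthetic_data import ClinicalTable, CountMatrix, GeneMeta

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "write_gene_meta_tsv",
    "read_gene_meta_tsv",
    "write_binary_outcome_tsv",
    "write_survival_outcome_tsv",
    "write_clinical_tsv",
    "write_manifest",
]


def write_counts_tsv(cm, path) -> None:
    """Genes in rows, one column per sample, gene_id as the index column."""
    values = cm.counts if isinstance(cm, CountMatrix) else cm.values
    df = pd.DataFrame(values, index=cm.gene_ids, columns=cm.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path, gene_meta: list[GeneMeta] | None = None):
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if gene_meta is None:
        gene_meta = [GeneMeta(g, 1, 1.0, 0.0) for g in df.index]
    values = df.to_numpy()
    if np.issubdtype(values.dtype, np.integer):
        return CountMatrix(values, gene_meta, list(df.columns))
    return NormalizedMatrix(values, gene_meta, list(df.columns))


def write_counts_mtx(cm: CountMatrix, prefix) -> None:
    """MatrixMarket sparse counts plus side files for gene and sample ids."""
    from scipy import io as spio
    from scipy import sparse

    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(cm.counts))
    prefix.with_name(prefix.name + "_genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
    prefix.with_name(prefix.name + "_samples.txt").write_text("\n".join(cm.sample_ids) + "\n")


def write_gene_meta_tsv(genes: list[GeneMeta], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "length_bp": [g.length_bp for g in genes],
            "base_mean": [g.base_mean for g in genes],
            "dispersion": [g.dispersion for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_meta_tsv(path) -> list[GeneMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneMeta(str(r.gene_id), int(r.length_bp), float(r.base_mean), float(r.dispersion))
        for r in df.itertuples()
    ]


def write_binary_outcome_tsv(sample_ids, outcome, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "y": outcome.y}).to_csv(path, sep="\t", index=False)


def write_survival_outcome_tsv(sample_ids, outcome, path) -> None:
    pd.DataFrame(
        {"sample_id": sample_ids, "time": outcome.time, "event": outcome.event}
    ).to_csv(path, sep="\t", index=False)


def write_clinical_tsv(sample_ids, clinical: ClinicalTable, path) -> None:
    df = pd.DataFrame(clinical.values, columns=clinical.names)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_manifest(params: dict, path) -> None:
    """Echo every seed and tunable parameter of a run to JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(params, indent=2, default=default) + "\n")
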