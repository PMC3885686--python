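"""Preprocessing chain for raw RNA-Seq counts.

Three steps, applied in order before any covariate transformation:

1. low-count filtering — genes whose maximum count across samples is at
   most 10 carry almost no expression signal and are dropped;
2. median-of-ratios (DESeq-style) normalization — per-sample size
   factors are the median across genes of the ratio of the count to the
   gene's geometric mean, computed over genes with all-positive counts;
3. per-gene truncation of extreme values at median + 3 * IQR, which
   removes the outliers that otherwise inflate gene-gene correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import EmptyMatrixError, InvalidArgumentError, NormalizationError
from .synthetic_data import CountMatrix

__all__ = [
    "SizeFactors",
    "NormalizedMatrix",
    "FilterResult",
    "filter_low_counts",
    "size_factors",
    "normalize",
    "truncate_extremes",
]


@dataclass
class SizeFactors:
    """Per-sample scale factors and the per-gene geometric means behind them."""

    factors: np.ndarray
    reference: np.ndarray  # per-gene geometric means (NaN where undefined)
    usable_genes: np.ndarray  # bool mask of genes entering the medians


@dataclass
class NormalizedMatrix:
    """Genes x samples non-negative reals after size-factor division."""

    values: np.ndarray
    genes: list
    sample_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InvalidArgumentError("normalized values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


class FilterResult(NamedTuple):
    matrix: CountMatrix
    removed_ids: list[str]


def filter_low_counts(counts: CountMatrix, max_threshold: int = 10) -> FilterResult:
    """Drop genes whose maximum count across samples is <= ``max_threshold``.

    The comparison is strict in the sense that a gene reaching
    ``max_threshold + 1`` anywhere is retained; gene order is preserved.
    """
    if max_threshold < 0:
        raise InvalidArgumentError("max_threshold must be >= 0")
    keep = counts.counts.max(axis=1) > max_threshold
    if not np.any(keep):
        raise EmptyMatrixError("low-count filter removed every gene")
    removed = [g.gene_id for g, k in zip(counts.genes, keep) if not k]
    kept = CountMatrix(
        counts.counts[keep],
        [g for g, k in zip(counts.genes, keep) if k],
        list(counts.sample_ids),
    )
    return FilterResult(kept, removed)


def size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For each gene with all-positive counts, the reference is its
    geometric mean across samples; the size factor of a sample is the
    median over those genes of count / reference.  Invariant to gene
    order.
    """
    c = counts.counts.astype(float)
    usable = np.all(c > 0, axis=1)
    if not np.any(usable):
        raise NormalizationError("no gene with all-positive counts; size factors undefined")
    log_geo = np.full(c.shape[0], np.nan)
    log_geo[usable] = np.mean(np.log(c[usable]), axis=1)
    ratios = np.log(c[usable]) - log_geo[usable, None]
    factors = np.exp(np.median(ratios, axis=0))
    reference = np.exp(log_geo)
    return SizeFactors(factors=factors, reference=reference, usable_genes=usable)


def normalize(counts: CountMatrix, sf: SizeFactors | None = None) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    if sf is None:
        sf = size_factors(counts)
    values = counts.counts / sf.factors[None, :]
    return NormalizedMatrix(
        values,
        list(counts.genes),
        list(counts.sample_ids),
        provenance={"size_factors": sf.factors},
    )


def truncate_extremes(x: NormalizedMatrix) -> NormalizedMatrix:
    """Cap each gene at its median plus three interquartile ranges.

    Quartiles use linear interpolation between order statistics.  The
    number of truncated entries is recorded in ``provenance``.
    """
    v = x.values
    if v.shape[1] < 4:
        raise InvalidArgumentError("truncation needs >= 4 samples per gene")
    med = np.median(v, axis=1)
    q1 = np.quantile(v, 0.25, axis=1)
    q3 = np.quantile(v, 0.75, axis=1)
    bound = med + 3.0 * (q3 - q1)
    over = v > bound[:, None]
    out = np.where(over, bound[:, None], v)
    prov = dict(x.provenance)
    prov["n_truncated"] = int(over.sum())
    prov["truncation_bound"] = bound
    return NormalizedMatrix(out, list(x.genes), list(x.sample_ids), provenance=prov)
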