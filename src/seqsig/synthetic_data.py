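"""Synthetic RNA-Seq cohorts with the structure of real tumor data.

Bulk RNA-Seq count matrices show three properties that matter for
penalized regression: per-gene count distributions are heavily skewed,
the per-gene variance grows faster than the mean (negative-binomial
style overdispersion), and rare extreme values can inflate gene-gene
correlation estimates to near 1.  This module generates count matrices,
gene metadata, clinical covariates and binary or time-to-event outcomes
reproducing those properties, so the whole signature-building pipeline
can be exercised end to end without access to patient data.

The generating model is negative binomial per gene (variance
``mu + alpha * mu**2``) with log-normal base means, a Gaussian copula
inducing block-wise gene-gene correlation, per-sample library-size
factors, and a small rate of multiplicative outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import CalibrationError, InvalidArgumentError

__all__ = [
    "GeneMeta",
    "CountMatrix",
    "SimulationDesign",
    "BinaryOutcome",
    "SurvivalOutcome",
    "ClinicalTable",
    "generate_counts",
    "generate_clinical",
    "choose_informative_genes",
    "calibrate_effects",
    "simulate_binary_outcome",
    "simulate_survival_outcome",
]


@dataclass
class GeneMeta:
    """Per-gene generating parameters.

    ``dispersion`` is the negative-binomial alpha so that
    ``var = base_mean + dispersion * base_mean**2``; zero gives Poisson.
    """

    gene_id: str
    length_bp: int
    base_mean: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise InvalidArgumentError(f"length_bp must be >= 1, got {self.length_bp}")
        if self.base_mean <= 0:
            raise InvalidArgumentError(f"base_mean must be > 0, got {self.base_mean}")
        if self.dispersion < 0:
            raise InvalidArgumentError(f"dispersion must be >= 0, got {self.dispersion}")


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts plus gene metadata."""

    counts: np.ndarray
    genes: list[GeneMeta]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        p, n = self.counts.shape
        if p != len(self.genes) or n != len(self.sample_ids):
            raise InvalidArgumentError("counts shape does not match gene/sample metadata")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("gene ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def values(self) -> np.ndarray:
        """Counts as floats; lets counts stand in for a normalized matrix."""
        return self.counts.astype(float)


@dataclass
class SimulationDesign:
    """A single draw of the informative-gene subset and its effect sizes."""

    n_samples: int
    n_genes: int
    n_informative: int
    snr_target: float
    effect_scale: str  # "linear" | "logarithmic"
    informative_ids: list[str]
    beta: np.ndarray  # aligned to the gene order of the matrix; non-zero only on the informative set
    seed: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.effect_scale not in ("linear", "logarithmic"):
            raise InvalidArgumentError(f"unknown effect_scale {self.effect_scale!r}")
        nz = int(np.count_nonzero(self.beta))
        # an all-zero beta is the explicit null design (pure-noise scenario)
        if nz != self.n_informative and nz != 0:
            raise InvalidArgumentError("beta support size must equal n_informative")


@dataclass
class BinaryOutcome:
    y: np.ndarray
    pi: np.ndarray  # generating probabilities, retained for testing


@dataclass
class SurvivalOutcome:
    time: np.ndarray
    event: np.ndarray
    true_linpred: np.ndarray


@dataclass
class ClinicalTable:
    """Mandatory covariates: continuous or dummy-coded, no missing values."""

    values: np.ndarray  # n samples x q covariates
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not self.names:
            self.names = [f"clin_{k}" for k in range(self.values.shape[1])]
        if self.values.shape[1] != len(self.names):
            raise InvalidArgumentError("clinical names do not match columns")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("clinical covariates must not contain missing values")


def _nb_quantile(u: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Quantile of NB(mean mu, var mu + alpha mu^2); Poisson where alpha == 0."""
    out = np.empty(np.broadcast(u, mu).shape)
    alpha = np.broadcast_to(alpha, out.shape)
    mu = np.broadcast_to(mu, out.shape)
    pois = alpha <= 0
    if np.any(pois):
        out[pois] = stats.poisson.ppf(u[pois], mu[pois])
    if np.any(~pois):
        size = 1.0 / alpha[~pois]
        prob = size / (size + mu[~pois])
        out[~pois] = stats.nbinom.ppf(u[~pois], size, prob)
    return out


def generate_counts(
    n_genes: int,
    n_samples: int,
    correlation_block_size: int = 50,
    extreme_value_rate: float = 0.001,
    seed: int = 0,
    *,
    base_mean_log_mu: float = 2.5,
    base_mean_log_sigma: float = 1.8,
    dispersion_log_mu: float = np.log(0.4),
    dispersion_log_sigma: float = 1.0,
    block_rho: float = 0.5,
    size_factor_log_sigma: float = 0.25,
    length_log_mu: float = np.log(2500.0),
    length_log_sigma: float = 0.8,
    dispersions: np.ndarray | None = None,
    base_means: np.ndarray | None = None,
) -> CountMatrix:
    """Draw a correlated, overdispersed count matrix.

    Genes are laid out in consecutive blocks of ``correlation_block_size``;
    within a block the latent Gaussian copula correlation is ``block_rho``.
    A fraction ``extreme_value_rate`` of entries is multiplied by a factor
    uniform on [10, 50] to mimic correlation-inflating outliers.
    Per-sample library-size factors are log-normal so that normalization
    downstream is non-trivial.  Deterministic given ``seed``.
    """
    if n_genes < 2 or n_samples < 2:
        raise InvalidArgumentError("need n_genes >= 2 and n_samples >= 2")
    if not 0 <= extreme_value_rate <= 0.05:
        raise InvalidArgumentError("extreme_value_rate must lie in [0, 0.05]")
    if correlation_block_size < 1:
        raise InvalidArgumentError("correlation_block_size must be >= 1")

    rng = np.random.default_rng(seed)
    if base_means is None:
        base_means = rng.lognormal(base_mean_log_mu, base_mean_log_sigma, size=n_genes)
    else:
        base_means = np.broadcast_to(np.asarray(base_means, float), (n_genes,)).copy()
    if dispersions is None:
        dispersions = rng.lognormal(dispersion_log_mu, dispersion_log_sigma, size=n_genes)
    else:
        dispersions = np.broadcast_to(np.asarray(dispersions, float), (n_genes,)).copy()
    lengths = np.maximum(1, rng.lognormal(length_log_mu, length_log_sigma, size=n_genes)).astype(int)
    size_factors = rng.lognormal(0.0, size_factor_log_sigma, size=n_samples)

    # Gaussian copula: z_gs = sqrt(rho) * f_(block,s) + sqrt(1-rho) * e_gs
    n_blocks = int(np.ceil(n_genes / correlation_block_size))
    block_of_gene = np.repeat(np.arange(n_blocks), correlation_block_size)[:n_genes]
    f = rng.standard_normal((n_blocks, n_samples))
    e = rng.standard_normal((n_genes, n_samples))
    z = np.sqrt(block_rho) * f[block_of_gene] + np.sqrt(1.0 - block_rho) * e
    u = stats.norm.cdf(z)
    # avoid the infinite quantile at u == 1
    u = np.clip(u, 1e-12, 1.0 - 1e-12)

    mu = base_means[:, None] * size_factors[None, :]
    counts = _nb_quantile(u, mu, dispersions[:, None])

    if extreme_value_rate > 0:
        mask = rng.random(counts.shape) < extreme_value_rate
        factors = rng.uniform(10.0, 50.0, size=int(mask.sum()))
        counts[mask] = np.round(counts[mask] * factors)

    genes = [
        GeneMeta(f"g{i:05d}", int(lengths[i]), float(base_means[i]), float(dispersions[i]))
        for i in range(n_genes)
    ]
    sample_ids = [f"s{j:04d}" for j in range(n_samples)]
    return CountMatrix(counts.astype(np.int64), genes, sample_ids)


def generate_clinical(n_samples: int, n_continuous: int = 1, n_binary: int = 1, seed: int = 0) -> ClinicalTable:
    """Standard-normal continuous covariates plus balanced binary dummies."""
    rng = np.random.default_rng(seed)
    cols, names = [], []
    for k in range(n_continuous):
        cols.append(rng.standard_normal(n_samples))
        names.append(f"cont_{k}")
    for k in range(n_binary):
        cols.append(rng.integers(0, 2, size=n_samples).astype(float))
        names.append(f"bin_{k}")
    values = np.column_stack(cols) if cols else np.empty((n_samples, 0))
    return ClinicalTable(values, names)


def choose_informative_genes(genes: list[GeneMeta], n_informative: int, seed: int = 0) -> list[str]:
    """One informative gene per gene-length bin.

    Genes are ordered by length, split into ``n_informative`` contiguous
    near-equal bins (the remainder spread over the first bins), and one
    gene is drawn uniformly from each bin, so true effects cover the
    whole range of gene lengths.
    """
    p = len(genes)
    if not 1 <= n_informative <= p:
        raise InvalidArgumentError(f"need 1 <= n_informative <= {p}, got {n_informative}")
    rng = np.random.default_rng(seed)
    order = sorted(range(p), key=lambda i: (genes[i].length_bp, i))
    base, rem = divmod(p, n_informative)
    chosen: list[str] = []
    start = 0
    for b in range(n_informative):
        size = base + (1 if b < rem else 0)
        idx = order[start + rng.integers(0, size)]
        chosen.append(genes[idx].gene_id)
        start += size
    return chosen


def snr_binary(eta: np.ndarray) -> float:
    """Signal-to-noise ratio of a logistic linear predictor.

    Defined as Var(eta) over the mean Bernoulli conditional variance
    mean(pi * (1 - pi)) with pi = expit(eta).
    """
    eta = np.asarray(eta, float)
    pi = expit(eta)
    noise = float(np.mean(pi * (1.0 - pi)))
    return float(np.var(eta, ddof=1) / noise)


def calibrate_effects(
    x_effective: np.ndarray, snr_target: float, *, center: bool = True, rel_tol: float = 1e-6
) -> float:
    """Common effect size b > 0 achieving a target SNR.

    ``x_effective`` holds the informative covariate rows (genes x samples);
    the linear predictor is ``eta_i = b * sum_j x_ij``, centered by default
    to match the generating model.  Solved by bisection after checking
    SNR(b) is monotone on the bracket.
    """
    if snr_target <= 0:
        raise InvalidArgumentError("snr_target must be positive")
    x = np.atleast_2d(np.asarray(x_effective, float))
    s = x.sum(axis=0)
    if center:
        s = s - s.mean()
    if np.var(s) <= 0:
        raise CalibrationError("informative submatrix is degenerate: constant row sums")

    def snr(b: float) -> float:
        return snr_binary(b * s)

    lo, hi = 0.0, 1e-6
    for _ in range(120):
        if snr(hi) >= snr_target:
            break
        hi *= 2.0
    else:
        raise CalibrationError(f"SNR target {snr_target} not reachable; SNR({hi}) = {snr(hi):.4g}")

    grid = np.linspace(lo, hi, 9)[1:]
    vals = [snr(b) for b in grid]
    if np.any(np.diff(vals) < -1e-9 * max(vals)):
        raise CalibrationError("SNR(b) is not monotone on the bracket")

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if snr(mid) < snr_target:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rel_tol * max(hi, 1e-300):
            break
    return 0.5 * (lo + hi)


def _effective_covariates(values: np.ndarray, effect_scale: str) -> np.ndarray:
    if effect_scale == "linear":
        return values
    if effect_scale == "logarithmic":
        return np.log1p(values)
    raise InvalidArgumentError(f"unknown effect_scale {effect_scale!r}")


def _gene_rows(x, gene_ids_wanted: list[str]) -> np.ndarray:
    all_ids = x.gene_ids if hasattr(x, "gene_ids") else None
    if all_ids is None:
        raise InvalidArgumentError("matrix object must expose gene_ids")
    pos = {g: i for i, g in enumerate(all_ids)}
    missing = [g for g in gene_ids_wanted if g not in pos]
    if missing:
        raise InvalidArgumentError(f"informative gene ids not present in matrix: {missing[:5]}")
    return np.array([pos[g] for g in gene_ids_wanted], dtype=int)


def simulate_binary_outcome(x, design: SimulationDesign, seed: int = 0, center: bool = True) -> BinaryOutcome:
    """Bernoulli outcome from a logistic model on the informative genes.

    Covariates enter the linear predictor on the scale given by
    ``design.effect_scale``: the matrix values themselves (linear) or
    log(value + 1) (logarithmic).  By default the linear predictor is
    centered, which fixes the population prevalence at one half; with
    all-positive covariates and positive effects an uncentered predictor
    would push every subject toward the case group.
    """
    n = np.asarray(x.values).shape[1]
    rows = _gene_rows(x, design.informative_ids)
    cov = _effective_covariates(np.asarray(x.values, float), design.effect_scale)
    beta_inf = design.beta[rows] if rows.size else np.zeros(0)
    eta = beta_inf @ cov[rows] if rows.size else np.zeros(n)
    if center and np.any(beta_inf):
        eta = eta - eta.mean()
    pi = expit(eta)
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < pi).astype(int)
    return BinaryOutcome(y=y, pi=pi)


def simulate_survival_outcome(
    x,
    clinical: ClinicalTable | None,
    design: SimulationDesign,
    baseline_scale: float = 0.1,
    censor_rate: float = 0.3,
    seed: int = 0,
    clinical_beta: np.ndarray | None = None,
) -> SurvivalOutcome:
    """Exponential-baseline proportional-hazards outcome with uniform censoring.

    Event times are Exp(h0 * exp(eta)) with eta combining clinical and
    informative-gene effects; the uniform censoring horizon is tuned so
    the expected censoring fraction matches ``censor_rate``.  The fitters
    downstream never see the baseline hazard.
    """
    if not 0 <= censor_rate <= 0.95:
        raise InvalidArgumentError("censor_rate must lie in [0, 0.95]")
    if baseline_scale <= 0:
        raise InvalidArgumentError("baseline_scale must be positive")
    n = np.asarray(x.values).shape[1]
    rows = _gene_rows(x, design.informative_ids)
    cov = _effective_covariates(np.asarray(x.values, float), design.effect_scale)
    eta = design.beta[rows] @ cov[rows] if rows.size else np.zeros(n)
    if clinical is not None and clinical.values.shape[1] > 0:
        if clinical_beta is None:
            clinical_beta = np.full(clinical.values.shape[1], 0.5)
        eta = eta + clinical.values @ np.asarray(clinical_beta, float)

    rng = np.random.default_rng(seed)
    n = eta.shape[0]
    t_event = rng.exponential(1.0, size=n) / (baseline_scale * np.exp(eta))

    if censor_rate == 0:
        return SurvivalOutcome(time=t_event, event=np.ones(n, dtype=int), true_linpred=eta)

    # expected censoring fraction with C ~ U(0, c): mean_i min(T_i / c, 1),
    # monotone decreasing in c -> bisection on the horizon
    def expected_rate(c: float) -> float:
        return float(np.mean(np.minimum(t_event / c, 1.0)))

    lo, hi = np.min(t_event) * 1e-6, np.max(t_event) * 1e6
    if not expected_rate(hi) <= censor_rate <= expected_rate(lo):
        raise CalibrationError(f"censor_rate {censor_rate} unattainable for these times")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if expected_rate(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    horizon = np.sqrt(lo * hi)

    child = rng.spawn(20)
    for sub in child:
        c = sub.uniform(0.0, horizon, size=n)
        event = (t_event <= c).astype(int)
        if abs(1.0 - event.mean() - censor_rate) <= 0.05:
            time = np.minimum(t_event, c)
            return SurvivalOutcome(time=time, event=event, true_linpred=eta)
    raise CalibrationError(
        f"empirical censoring rate missed target {censor_rate} +/- 0.05 in 20 draws"
    )
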