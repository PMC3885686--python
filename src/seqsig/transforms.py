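"""The ten covariate transformations for RNA-Seq regression modeling.

Normalized counts are skewed, have gene-specific variances that grow
with the mean, and contain extreme values; all three properties distort
variable selection in penalized regression.  The transformations fall
into three families:

* no standardization — ``naive`` (identity), ``log`` (log(x+1)),
  ``vst`` (closed-form asinh variance-stabilizer for the negative-
  binomial variance model v(mu) = mu + alpha*mu^2), ``boxcox``
  (per-gene power transform with lambda picked by QQ-plot correlation);
* standardized variants — each of the above followed by per-gene
  centering and scaling to unit variance (``standardize``,
  ``standardize_log``, ``standardize_vst``, ``standardize_boxcox``);
* non-parametric — ``ranks`` (within-gene ranks 1..n) and ``blom``
  (rank-based normal scores), which force the identical distribution on
  every gene.

Every transformation is fitted on training samples only; the fitted
parameters (means, SDs, dispersion, lambdas, or the training sample
itself for the rank-based maps) are reusable on held-out samples via
:func:`transform_new`, which is what honest prediction-error estimation
requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .errors import ConstantGeneError, InvalidArgumentError, VSTError

__all__ = [
    "TAGS",
    "TransformedMatrix",
    "TransformStats",
    "t_log",
    "fit_vst",
    "apply_vst",
    "fit_boxcox_lambda",
    "apply_boxcox",
    "t_standardize",
    "t_ranks",
    "t_blom",
    "fit_transform",
    "transform_new",
    "apply_transform",
    "transform_stats",
    "BOXCOX_GRID",
    "BLOM_C",
]

TAGS = (
    "naive",
    "log",
    "vst",
    "boxcox",
    "standardize",
    "standardize_log",
    "standardize_vst",
    "standardize_boxcox",
    "ranks",
    "blom",
)

BOXCOX_GRID = np.arange(-2.0, 2.0 + 1e-9, 0.25)
BLOM_C = 3.0 / 8.0
DEFAULT_TIE_NOISE_SCALE = 1e-4  # times (per-gene IQR + 1)
# QQ correlations closer than this are statistically indistinguishable at the
# sample sizes in play; such near-ties resolve toward the identity
BOXCOX_TIE_TOL = 2e-3


@dataclass
class TransformedMatrix:
    values: np.ndarray
    transform_tag: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class TransformStats:
    """Per-gene moments and extreme-value counts before/after a transform."""

    mean_before: np.ndarray
    mean_after: np.ndarray
    var_before: np.ndarray
    var_after: np.ndarray
    skew_before: np.ndarray
    skew_after: np.ndarray
    n_extreme_before: int
    n_extreme_after: int


def _as_values(x) -> np.ndarray:
    v = x.values if hasattr(x, "values") else x
    return np.atleast_2d(np.asarray(v, dtype=float))


def t_log(x) -> TransformedMatrix:
    """log(x + 1); the shift keeps zero counts finite."""
    v = _as_values(x)
    if np.any(v < 0):
        raise InvalidArgumentError("log transform requires non-negative input")
    return TransformedMatrix(np.log1p(v), "log")


def fit_vst(x) -> dict[str, float]:
    """Estimate the common NB dispersion from the cross-gene mean-variance trend.

    Least squares through the origin of (s_g^2 - m_g) on m_g^2, clamped
    at zero; with the variance model v(mu) = mu + alpha*mu^2 this is the
    moment estimator of alpha.
    """
    v = _as_values(x)
    if v.shape[0] < 20:
        raise InvalidArgumentError("VST trend estimation needs >= 20 genes")
    m = v.mean(axis=1)
    s2 = v.var(axis=1, ddof=1)
    denom = float(np.sum(m**4))
    if not np.isfinite(denom) or denom <= 0:
        raise VSTError("degenerate mean-variance trend: all gene means are zero")
    alpha = float(np.sum((s2 - m) * m**2) / denom)
    return {"alpha": max(alpha, 0.0)}


def apply_vst(x, params: dict[str, float]) -> TransformedMatrix:
    """w(x) = (2/sqrt(alpha)) * asinh(sqrt(alpha * x)); 2*sqrt(x) at alpha = 0.

    This is the closed-form integral of 1/sqrt(v(mu)) for the NB
    variance model, so Var(w(X)) is approximately constant in the mean.
    """
    v = _as_values(x)
    if np.any(v < 0):
        raise InvalidArgumentError("VST requires non-negative input")
    alpha = float(params["alpha"])
    if alpha == 0.0:
        out = 2.0 * np.sqrt(v)
    else:
        out = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * v))
    return TransformedMatrix(out, "vst", {"alpha": alpha})


def _boxcox_apply_1d(v: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log1p(v)
    return ((v + 1.0) ** lam - 1.0) / lam


def fit_boxcox_lambda(x) -> dict[str, Any]:
    """Per-gene Box-Cox exponent maximizing QQ-plot normality.

    Candidates are ((x+1)^lambda - 1)/lambda on the grid -2..2 step 0.25
    (log(x+1) at lambda = 0); the winner maximizes the Pearson
    correlation between the sorted transformed values and standard-
    normal quantiles at Blom plotting positions.  Candidates whose
    correlation is within ``BOXCOX_TIE_TOL`` of the maximum are treated
    as tied; ties break toward the lambda closest to 1 (the identity),
    then toward 0.  Constant genes get lambda = 1 and a warning flag.
    """
    v = _as_values(x)
    if np.any(v < 0):
        raise InvalidArgumentError("Box-Cox requires non-negative input")
    p, n = v.shape
    if n < 4:
        raise InvalidArgumentError("Box-Cox selection needs >= 4 samples")
    xs = np.sort(v, axis=1)
    i = np.arange(1, n + 1)
    q = ndtri((i - BLOM_C) / (n - 2 * BLOM_C + 1))
    qc = q - q.mean()
    qn = np.sqrt(np.sum(qc**2))

    constant = xs[:, 0] == xs[:, -1]
    corr = np.full((p, len(BOXCOX_GRID)), -np.inf)
    for k, lam in enumerate(BOXCOX_GRID):
        t = _boxcox_apply_1d(xs, lam)
        tc = t - t.mean(axis=1, keepdims=True)
        tn = np.sqrt(np.sum(tc**2, axis=1))
        ok = (tn > 0) & ~constant
        corr[ok, k] = (tc[ok] @ qc) / (tn[ok] * qn)

    lambdas = np.empty(p)
    for g in range(p):
        if constant[g] or not np.isfinite(corr[g]).any():
            lambdas[g] = 1.0
            constant[g] = True
            continue
        best = corr[g].max()
        ties = np.flatnonzero(corr[g] >= best - BOXCOX_TIE_TOL)
        cand = BOXCOX_GRID[ties]
        cand = cand[np.lexsort((np.abs(cand), np.abs(cand - 1.0)))]
        lambdas[g] = cand[0]
    return {"lambdas": lambdas, "constant_genes": constant}


def apply_boxcox(x, params: dict[str, Any]) -> TransformedMatrix:
    v = _as_values(x)
    lam = np.asarray(params["lambdas"], float)[:, None]
    nonzero = np.where(lam == 0.0, 1.0, lam)
    out = np.where(lam == 0.0, np.log1p(v), ((v + 1.0) ** nonzero - 1.0) / nonzero)
    return TransformedMatrix(out, "boxcox", dict(params))


def t_standardize(x, mean: np.ndarray | None = None, sd: np.ndarray | None = None) -> TransformedMatrix:
    """Per-gene centering and unit-variance scaling (SD with denominator n-1)."""
    v = _as_values(x)
    if mean is None or sd is None:
        mean = v.mean(axis=1)
        sd = v.std(axis=1, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ConstantGeneError(f"constant gene(s) at row index {zero[:5].tolist()}; cannot standardize")
    out = (v - np.asarray(mean)[:, None]) / np.asarray(sd)[:, None]
    return TransformedMatrix(out, "standardize", {"mean": np.asarray(mean), "sd": np.asarray(sd)})


def _tie_noise(v: np.ndarray, seed: int, scale: float) -> np.ndarray:
    """Seeded per-gene jitter, applied only to genes that contain ties."""
    p, n = v.shape
    iqr = np.quantile(v, 0.75, axis=1) - np.quantile(v, 0.25, axis=1)
    sd = scale * (iqr + 1.0)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(v.shape) * sd[:, None]
    vs = np.sort(v, axis=1)
    has_ties = np.any(vs[:, 1:] == vs[:, :-1], axis=1)
    return np.where(has_ties[:, None], v + noise, v)


def _rank_against_train(sorted_train: np.ndarray, v_new: np.ndarray) -> np.ndarray:
    """Midrank of each new value within the (noised) training sample."""
    p = sorted_train.shape[0]
    r = np.empty_like(v_new, dtype=float)
    for g in range(p):
        left = np.searchsorted(sorted_train[g], v_new[g], side="left")
        right = np.searchsorted(sorted_train[g], v_new[g], side="right")
        r[g] = 0.5 * (left + right) + 0.5
    return r


def t_ranks(x, tie_noise_scale: float = DEFAULT_TIE_NOISE_SCALE, seed: int = 0) -> TransformedMatrix:
    """Within-gene ranks 1..n after seeded tie-breaking jitter.

    Every gene ends up with exactly the multiset {1, ..., n}, hence
    identical means (n+1)/2 and variances (n^2 - 1)/12 across genes.
    """
    v = _as_values(x)
    noised = _tie_noise(v, seed, tie_noise_scale)
    ranks = stats.rankdata(noised, axis=1, method="ordinal").astype(float)
    params = {"sorted_train": np.sort(noised, axis=1), "n_train": v.shape[1]}
    return TransformedMatrix(ranks, "ranks", params)


def _blom_scores(r: np.ndarray, n: int, c: float) -> np.ndarray:
    return ndtri((r - c) / (n - 2.0 * c + 1.0))


def t_blom(x, tie_noise_scale: float = DEFAULT_TIE_NOISE_SCALE, seed: int = 0, c: float = BLOM_C) -> TransformedMatrix:
    """Rank-based normal scores Phi^-1((r - c)/(n - 2c + 1)).

    Maps every gene to the same standard-normal-shaped multiset, so all
    genes share their empirical mean (0) and variance exactly.
    """
    rk = t_ranks(x, tie_noise_scale=tie_noise_scale, seed=seed)
    n = rk.params["n_train"]
    scores = _blom_scores(rk.values, n, c)
    params = dict(rk.params)
    params["c"] = c
    return TransformedMatrix(scores, "blom", params)


def fit_transform(tag: str, x, seed: int = 0, tie_noise_scale: float = DEFAULT_TIE_NOISE_SCALE) -> TransformedMatrix:
    """Fit a transformation on ``x`` and return the transformed training matrix.

    The returned object's ``params`` are sufficient to re-apply the
    fitted map to held-out samples with :func:`transform_new`.
    """
    v = _as_values(x)
    if tag == "naive":
        return TransformedMatrix(v.copy(), "naive")
    if tag == "log":
        return t_log(v)
    if tag == "vst":
        return apply_vst(v, fit_vst(v))
    if tag == "boxcox":
        return apply_boxcox(v, fit_boxcox_lambda(v))
    if tag == "standardize":
        return t_standardize(v)
    if tag in ("standardize_log", "standardize_vst", "standardize_boxcox"):
        inner_tag = tag.removeprefix("standardize_")
        inner = fit_transform(inner_tag, v, seed=seed)
        std = t_standardize(inner.values)
        params = dict(inner.params)
        params.update(std.params)
        return TransformedMatrix(std.values, tag, params)
    if tag == "ranks":
        return t_ranks(v, tie_noise_scale=tie_noise_scale, seed=seed)
    if tag == "blom":
        return t_blom(v, tie_noise_scale=tie_noise_scale, seed=seed)
    raise InvalidArgumentError(f"unknown transform tag {tag!r}")


def transform_new(tag: str, params: dict[str, Any], x_new) -> TransformedMatrix:
    """Apply train-fitted parameters to new samples (no refitting)."""
    v = _as_values(x_new)
    if tag == "naive":
        return TransformedMatrix(v.copy(), "naive")
    if tag == "log":
        return t_log(v)
    if tag == "vst":
        return apply_vst(v, params)
    if tag == "boxcox":
        return apply_boxcox(v, params)
    if tag == "standardize":
        return t_standardize(v, mean=params["mean"], sd=params["sd"])
    if tag in ("standardize_log", "standardize_vst", "standardize_boxcox"):
        inner = transform_new(tag.removeprefix("standardize_"), params, v)
        out = t_standardize(inner.values, mean=params["mean"], sd=params["sd"])
        return TransformedMatrix(out.values, tag, dict(params))
    if tag == "ranks":
        r = _rank_against_train(params["sorted_train"], v)
        return TransformedMatrix(r, "ranks", dict(params))
    if tag == "blom":
        r = _rank_against_train(params["sorted_train"], v)
        return TransformedMatrix(_blom_scores(r, params["n_train"], params["c"]), "blom", dict(params))
    raise InvalidArgumentError(f"unknown transform tag {tag!r}")


def apply_transform(tag: str, x, fit_params_from: dict[str, Any] | None = None, seed: int = 0) -> TransformedMatrix:
    """Registry entry point: fit-and-transform, or re-apply fitted parameters."""
    if fit_params_from is not None:
        return transform_new(tag, fit_params_from, x)
    return fit_transform(tag, x, seed=seed)


def _count_extreme(v: np.ndarray) -> int:
    med = np.median(v, axis=1, keepdims=True)
    iqr = np.quantile(v, 0.75, axis=1, keepdims=True) - np.quantile(v, 0.25, axis=1, keepdims=True)
    return int(np.sum(v > med + 3.0 * iqr))


def transform_stats(before, after) -> TransformStats:
    b, a = _as_values(before), _as_values(after)
    return TransformStats(
        mean_before=b.mean(axis=1),
        mean_after=a.mean(axis=1),
        var_before=b.var(axis=1, ddof=1),
        var_after=a.var(axis=1, ddof=1),
        skew_before=stats.skew(b, axis=1),
        skew_after=stats.skew(a, axis=1),
        n_extreme_before=_count_extreme(b),
        n_extreme_after=_count_extreme(a),
    )
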