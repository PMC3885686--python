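"""Evaluation statistics for identification and prediction performance.

Identification is scored along the boosting selection path: at each
step the non-zero penalized support yields a (false positive, true
positive) pair, and the partial area up to ten false positives —
the mean over f = 0..10 of the best TP count reachable with at most f
FPs — summarizes how early the truly informative genes enter.

Prediction performance for time-to-event outcomes uses censoring-
weighted (IPCW) Brier score curves with a Kaplan-Meier estimate of the
censoring distribution fitted on training data, combined across
apparent / out-of-sample / no-information components by the 0.632+
estimator, integrated over time (IPEC), and compared between a
clinical-only and a combined clinical + genomic model via the added
value 1 - IPEC_combined / IPEC_clinical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boostfit import BoostPath, _CoxWorkspace
from .errors import InvalidArgumentError

__all__ = [
    "SelectionCurve",
    "PredErrResult",
    "AddedValueResult",
    "selection_curve",
    "overlap_table",
    "breslow_cumhaz",
    "km_censoring",
    "brier_curves",
    "estimator_632plus",
    "ipec",
    "added_value",
]


@dataclass
class SelectionCurve:
    points: list[tuple[int, int]]  # (false positives, true positives) per step
    pauc10: float
    fp_max: int
    n_informative: int


@dataclass
class PredErrResult:
    time_grid: np.ndarray
    apparent: np.ndarray
    out_of_sample: np.ndarray
    no_information: np.ndarray
    estimate_632plus: np.ndarray
    ipec: float


@dataclass
class AddedValueResult:
    deltas: np.ndarray
    mean: float
    quartiles: tuple[float, float, float]


# ---------------------------------------------------------------------------
# identification


def selection_curve(path: BoostPath, truth: set | np.ndarray, fp_max: int = 10) -> SelectionCurve:
    """Walk a boosting path and score true/false positive selection.

    ``truth`` holds the covariate column indices of the truly
    informative genes.  TP*(f) is the best TP count at any step whose
    support has at most f false positives; the partial area is the mean
    of TP*(f) over f = 0..fp_max.
    """
    truth = set(int(t) for t in np.asarray(list(truth)).ravel())
    if not truth:
        raise InvalidArgumentError("truth set must be non-empty")
    points = []
    best_tp = np.zeros(fp_max + 1)
    for support in path.support_per_step():
        tp = sum(1 for j in support if j in truth)
        fp = len(support) - tp
        points.append((fp, tp))
        if fp <= fp_max:
            best_tp[fp:] = np.maximum(best_tp[fp:], tp)
    pauc = float(best_tp.mean())
    return SelectionCurve(points=points, pauc10=pauc, fp_max=fp_max, n_informative=len(truth))


def overlap_table(selected_sets: dict[str, list[set]], blocks: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Mean (sd) signature sizes and pairwise/block-wise overlaps.

    ``selected_sets`` maps transformation tag to one gene-id set per
    replicate (same replicate count for every tag).  The diagonal gives
    mean (sd) signature size; off-diagonal cells mean (sd) pairwise
    intersection size.  For each block of tags a row/column "all" gives
    the replicate-wise intersection across all tags of the block, and
    cross-block "all" cells the intersection across both blocks' tags.
    """
    tags = list(selected_sets)
    reps = {len(v) for v in selected_sets.values()}
    if len(reps) != 1:
        raise InvalidArgumentError("all tags must have the same replicate count")
    n_rep = reps.pop()

    def mean_sd(sizes):
        a = np.asarray(sizes, float)
        return f"{a.mean():.1f} ({a.std(ddof=1):.1f})" if len(a) > 1 else f"{a.mean():.1f} (0.0)"

    def inter_sizes(tag_list):
        out = []
        for r in range(n_rep):
            s = set(selected_sets[tag_list[0]][r])
            for t in tag_list[1:]:
                s &= set(selected_sets[t][r])
            out.append(len(s))
        return out

    labels = list(tags)
    if blocks:
        labels = labels + [f"all:{b}" for b in blocks]
    table = pd.DataFrame("", index=labels, columns=labels, dtype=object)
    for i, a in enumerate(tags):
        table.loc[a, a] = mean_sd([len(s) for s in selected_sets[a]])
        for b in tags[:i]:
            table.loc[a, b] = mean_sd(inter_sizes([a, b]))
    if blocks:
        block_names = list(blocks)
        for i, ba in enumerate(block_names):
            table.loc[f"all:{ba}", f"all:{ba}"] = mean_sd(inter_sizes(blocks[ba]))
            for bb in block_names[:i]:
                table.loc[f"all:{ba}", f"all:{bb}"] = mean_sd(inter_sizes(blocks[ba] + blocks[bb]))
    return table


# ---------------------------------------------------------------------------
# survival prediction machinery


def breslow_cumhaz(eta_train: np.ndarray, time_train: np.ndarray, event_train: np.ndarray):
    """Breslow cumulative baseline hazard; returns a step-function H0(t)."""
    ws = _CoxWorkspace(time_train, event_train)
    eta = np.asarray(eta_train, float)[ws.order]
    e = np.exp(eta - eta.max())
    s0 = np.cumsum(e[::-1])[::-1] * np.exp(eta.max())
    # one increment per distinct event time: d_k / S0(t_k)
    ev_times = ws.time[ws.event]
    uniq, counts = np.unique(ev_times, return_counts=True)
    first = np.searchsorted(ws.time, uniq, side="left")
    increments = counts / s0[first]
    cum = np.cumsum(increments)

    def h0(t):
        idx = np.searchsorted(uniq, np.asarray(t, float), side="right")
        return np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)

    return h0


def predicted_survival(eta_train, time_train, event_train, eta_new, grid) -> np.ndarray:
    """S_i(t) = exp(-H0(t) * exp(eta_i)) on a time grid; rows = subjects."""
    h0 = breslow_cumhaz(eta_train, time_train, event_train)
    base = h0(grid)[None, :]
    return np.exp(-base * np.exp(np.asarray(eta_new, float))[:, None])


def km_censoring(time: np.ndarray, event: np.ndarray, floor: float = 1e-3):
    """Kaplan-Meier estimate of the censoring survival G(t) = P(C > t)."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), event_observed=1 - np.asarray(event))
    grid_t = kmf.survival_function_.index.values
    grid_s = kmf.survival_function_.iloc[:, 0].values

    def g(t):
        idx = np.searchsorted(grid_t, np.asarray(t, float), side="right") - 1
        s = np.where(idx >= 0, grid_s[np.maximum(idx, 0)], 1.0)
        return np.maximum(s, floor)

    return g


def _ipcw_brier(surv_pred: np.ndarray, time: np.ndarray, event: np.ndarray, grid: np.ndarray, g) -> np.ndarray:
    """IPCW Brier curve; ``surv_pred`` is subjects x grid predicted survival."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    n = time.shape[0]
    out = np.empty(len(grid))
    g_tminus = g(np.maximum(time - 1e-12, 0.0))
    for k, t in enumerate(grid):
        s = surv_pred[:, k]
        died = (time <= t) & (event == 1)
        alive = time > t
        w_died = died / g_tminus
        w_alive = alive / g(t)
        out[k] = float(np.sum(w_died * s**2 + w_alive * (1.0 - s) ** 2) / n)
    return out


def brier_curves(
    eta_train: np.ndarray,
    time_train: np.ndarray,
    event_train: np.ndarray,
    eta_test: np.ndarray,
    time_test: np.ndarray,
    event_test: np.ndarray,
    time_grid: np.ndarray,
) -> dict[str, np.ndarray]:
    """Apparent, out-of-sample and no-information IPCW Brier curves.

    Survival predictions come from the training fit via the Breslow
    baseline; the censoring distribution is Kaplan-Meier on the training
    data.  The no-information curve pairs every training prediction with
    every training outcome.
    """
    grid = np.asarray(time_grid, float)
    if not np.any((time_test <= grid[-1]) & (np.asarray(event_test) == 1)):
        raise InvalidArgumentError("test set has no events inside the time grid")
    g = km_censoring(time_train, event_train)
    s_train = predicted_survival(eta_train, time_train, event_train, eta_train, grid)
    s_test = predicted_survival(eta_train, time_train, event_train, eta_test, grid)

    apparent = _ipcw_brier(s_train, time_train, event_train, grid, g)
    oos = _ipcw_brier(s_test, time_test, event_test, grid, g)

    # no-information: all prediction x outcome pairs; linear-time expansion of
    # (1/n^2) sum_ij w_j(t) (S_i(t) - Y_j(t))^2
    time_tr = np.asarray(time_train, float)
    event_tr = np.asarray(event_train)
    n = time_tr.shape[0]
    g_tminus = g(np.maximum(time_tr - 1e-12, 0.0))
    noinf = np.empty(len(grid))
    for k, t in enumerate(grid):
        s = s_train[:, k]
        m1, m2 = s.mean(), np.mean(s**2)
        died = (time_tr <= t) & (event_tr == 1)
        alive = time_tr > t
        w = died / g_tminus + alive / g(t)
        y = alive.astype(float)
        noinf[k] = float(np.mean(w * (m2 - 2.0 * y * m1 + y**2)))
    return {"apparent": apparent, "out_of_sample": oos, "no_information": noinf}


def estimator_632plus(apparent: np.ndarray, oob: np.ndarray, noinf: np.ndarray) -> np.ndarray:
    """Pointwise 0.632+ combination of apparent and out-of-sample error.

    R = (oob - apparent)/(noinf - apparent) clipped to [0, 1] (zero when
    the no-information error does not exceed the apparent one),
    w = 0.632/(1 - 0.368 R), estimate = (1-w) apparent + w min(oob, noinf).
    """
    apparent = np.asarray(apparent, float)
    oob = np.asarray(oob, float)
    noinf = np.asarray(noinf, float)
    denom = noinf - apparent
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (oob - apparent) / denom, 0.0)
    r = np.clip(r, 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * r)
    return (1.0 - w) * apparent + w * np.minimum(oob, noinf)


def ipec(time_grid: np.ndarray, curve: np.ndarray) -> float:
    """Integrated prediction error: trapezoidal area under the curve."""
    return float(np.trapezoid(np.asarray(curve, float), np.asarray(time_grid, float)))


def pred_err_result(time_grid, components: dict[str, np.ndarray]) -> PredErrResult:
    est = estimator_632plus(components["apparent"], components["out_of_sample"], components["no_information"])
    return PredErrResult(
        time_grid=np.asarray(time_grid, float),
        apparent=components["apparent"],
        out_of_sample=components["out_of_sample"],
        no_information=components["no_information"],
        estimate_632plus=est,
        ipec=ipec(time_grid, est),
    )


def added_value(ipec_clinical: np.ndarray, ipec_combined: np.ndarray) -> AddedValueResult:
    """Delta_k = 1 - IPEC_combined,k / IPEC_clinical,k per resampling split.

    Zero means no improvement over the clinical-only model, negative
    means the combined model predicts worse, and positive values are the
    proportion of the clinical model's prediction error eliminated.
    """
    clin = np.asarray(ipec_clinical, float)
    comb = np.asarray(ipec_combined, float)
    if np.any(clin <= 0):
        raise InvalidArgumentError("clinical IPEC must be positive")
    deltas = 1.0 - comb / clin
    q1, q2, q3 = np.percentile(deltas, [25, 50, 75])
    return AddedValueResult(deltas=deltas, mean=float(deltas.mean()), quartiles=(float(q1), float(q2), float(q3)))
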