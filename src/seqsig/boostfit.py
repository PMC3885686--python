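"""Penalized model fitting: componentwise boosting, ridge, lasso-Cox.

Componentwise likelihood-based boosting starts from a zero coefficient
vector and, at each step, scores every penalized covariate by the
penalized score statistic U_j^2 / (I_j + lambda) at the current fit,
updates the winner by the one-dimensional penalized Newton step
U_j / (I_j + lambda), and refreshes the intercept and any mandatory
(unpenalized) covariates by one unpenalized Newton step.  Supported
response families are logistic and Cox proportional hazards (Breslow
tie handling).  Because the penalty enters through the information, a
covariate with larger variance is effectively penalized less — the
scale sensitivity that motivates transforming RNA-Seq covariates.

The penalty can be given directly or derived from a shrinkage factor
nu in (0, 1] as lambda = (1/nu - 1) * (total null-model weight), so a
standardized covariate's first update is shrunk by about nu; nu = 0.1
mirrors the step factor commonly used in gradient boosting.

The lasso-Cox path is delegated to the coordinate-descent solver in
scikit-survival (glmnet port) with an unpenalized mandatory block via
penalty factors; returned solutions are verified against the KKT
conditions of the L1-penalized partial likelihood here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import DivergenceError, InvalidArgumentError, OptimizationError

__all__ = [
    "BoostConfig",
    "BoostPath",
    "FitResult",
    "boost_fit",
    "ridge_closed_form",
    "ridge_standardized",
    "lasso_cox_fit",
    "cox_newton",
    "cox_partial_loglik",
    "cv_tune",
    "penalty_from_nu",
]


# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass
class BoostConfig:
    family: str  # "logistic" | "cox"
    max_steps: int = 500
    penalty: float | None = None
    nu: float | None = None
    mandatory: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "cox", "gaussian"):
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.max_steps < 0:
            raise InvalidArgumentError("max_steps must be >= 0")
        if self.penalty is not None and self.nu is not None:
            raise InvalidArgumentError("supply exactly one of penalty or nu")
        if self.penalty is None and self.nu is None:
            self.nu = 0.1  # conventional default shrinkage
        if self.nu is not None and not 0 < self.nu <= 1:
            raise InvalidArgumentError("nu must lie in (0, 1]")


@dataclass
class BoostPath:
    """Selected index, update and unpenalized-block state for every step."""

    family: str
    penalized: np.ndarray  # column indices of penalized covariates
    selected: np.ndarray  # per-step selected column (global index)
    updates: np.ndarray  # per-step one-dimensional Newton update
    intercept_path: np.ndarray  # length n_steps + 1 (zeros for cox)
    mandatory: np.ndarray  # column indices of the mandatory block
    mandatory_path: np.ndarray  # (n_steps + 1) x q
    loglik_path: np.ndarray  # length n_steps + 1
    penalty: float
    coef: np.ndarray = field(default=None)  # final full coefficient vector

    @property
    def n_steps(self) -> int:
        return len(self.selected)

    def coef_at(self, m: int) -> tuple[float, np.ndarray]:
        """(intercept, full coefficient vector) after m boosting steps."""
        p = self.coef.shape[0]
        beta = np.zeros(p)
        for j, u in zip(self.selected[:m], self.updates[:m]):
            beta[j] += u
        beta[self.mandatory] = self.mandatory_path[m]
        return float(self.intercept_path[m]), beta

    def support_per_step(self) -> list[np.ndarray]:
        """Non-zero penalized support after each step (index 0 = before any)."""
        vals: dict[int, float] = {}
        out = [np.array([], dtype=int)]
        for j, u in zip(self.selected, self.updates):
            vals[j] = vals.get(j, 0.0) + u
            out.append(np.array(sorted(k for k, v in vals.items() if v != 0.0), dtype=int))
        return out

    @property
    def selected_genes(self) -> np.ndarray:
        """Penalized columns with non-zero final coefficient."""
        pen = self.coef.copy()
        pen_mask = np.zeros_like(pen, dtype=bool)
        pen_mask[self.penalized] = True
        return np.flatnonzero(pen_mask & (pen != 0.0))


@dataclass
class FitResult:
    coef: np.ndarray
    selected: np.ndarray
    tuning: dict
    family: str


# ---------------------------------------------------------------------------
# likelihood machinery


def _logistic_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class _CoxWorkspace:
    """Pre-sorted survival data with Breslow risk-set bookkeeping."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, float)
        event = np.asarray(event)
        if event.sum() < 1:
            raise InvalidArgumentError("Cox fitting needs at least one event")
        self.order = np.argsort(time, kind="stable")
        self.time = time[self.order]
        self.event = event[self.order].astype(bool)
        # risk set of an observation = everything from the first index sharing its time
        self.tie_first = np.searchsorted(self.time, self.time, side="left")
        self.ev_idx = np.flatnonzero(self.event)
        self.ev_first = self.tie_first[self.ev_idx]

    def _rcumsum(self, a: np.ndarray) -> np.ndarray:
        return np.cumsum(a[::-1], axis=0)[::-1]

    def loglik(self, eta_sorted: np.ndarray) -> float:
        e = np.exp(eta_sorted - eta_sorted.max())
        s0 = self._rcumsum(e)[self.ev_first]
        return float(np.sum(eta_sorted[self.ev_idx] - eta_sorted.max() - np.log(s0)))

    def score_info_all(self, z_sorted: np.ndarray, eta_sorted: np.ndarray):
        """Per-covariate score U_j and information I_j at the current fit."""
        e = np.exp(eta_sorted - eta_sorted.max())
        s0 = self._rcumsum(e)[self.ev_first][:, None]
        ez = e[:, None] * z_sorted
        s1 = self._rcumsum(ez)[self.ev_first]
        s2 = self._rcumsum(ez * z_sorted)[self.ev_first]
        mean = s1 / s0
        u = np.sum(z_sorted[self.ev_idx] - mean, axis=0)
        i = np.sum(s2 / s0 - mean**2, axis=0)
        return u, i

    def score_info_block(self, zb_sorted: np.ndarray, eta_sorted: np.ndarray):
        """Score vector and full information matrix for a small block."""
        e = np.exp(eta_sorted - eta_sorted.max())
        s0 = self._rcumsum(e)[self.ev_first][:, None]
        ez = e[:, None] * zb_sorted
        s1 = self._rcumsum(ez)[self.ev_first]
        mean = s1 / s0
        u = np.sum(zb_sorted[self.ev_idx] - mean, axis=0)
        q = zb_sorted.shape[1]
        info = np.zeros((q, q))
        for a in range(q):
            s2 = self._rcumsum(ez * zb_sorted[:, a : a + 1])[self.ev_first]
            info[a] = np.sum(s2 / s0 - mean * mean[:, a : a + 1], axis=0)
        return u, 0.5 * (info + info.T)


def cox_partial_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a linear predictor."""
    ws = _CoxWorkspace(time, event)
    return ws.loglik(np.asarray(eta, float)[ws.order])


def cox_newton(
    z: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 0.0,
) -> np.ndarray:
    """Unpenalized (optionally lightly ridged) Cox fit by Newton-Raphson."""
    z = np.atleast_2d(np.asarray(z, float))
    if z.shape[1] == 0:
        return np.zeros(0)
    ws = _CoxWorkspace(time, event)
    zs = z[ws.order]
    beta = np.zeros(z.shape[1])
    for _ in range(max_iter):
        eta = zs @ beta
        u, info = ws.score_info_block(zs, eta)
        if ridge > 0:
            u = u - ridge * beta
            info = info + ridge * np.eye(len(beta))
        step = np.linalg.solve(info, u)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    if not np.all(np.isfinite(beta)):
        raise DivergenceError("Cox Newton iteration diverged")
    return beta


def penalty_from_nu(nu: float, family: str, response) -> float:
    """lambda = (1/nu - 1) * total null-model weight.

    Logistic: sum of p(1-p) at the null (intercept-only) fit; Cox: the
    number of events, the scale of the null partial-likelihood
    information.  With this choice the first update of a standardized
    covariate is shrunk by roughly nu.
    """
    if family == "logistic":
        y = np.asarray(response, float)
        pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        total_w = y.shape[0] * pbar * (1.0 - pbar)
    elif family == "gaussian":
        total_w = float(np.asarray(response).shape[0])
    else:
        _, event = response
        total_w = float(np.sum(event))
    return (1.0 / nu - 1.0) * total_w


# ---------------------------------------------------------------------------
# componentwise likelihood-based boosting


def boost_fit(z: np.ndarray, response, config: BoostConfig, stop_support: int | None = None) -> BoostPath:
    """Componentwise likelihood-based boosting path.

    ``z`` is samples x covariates; ``config.mandatory`` columns are
    refreshed by one unpenalized Newton step per boosting iteration and
    never counted as selected.  ``response`` is a 0/1 vector for the
    logistic family or a ``(time, event)`` pair for Cox.  Score ties
    break toward the lowest covariate index.  ``stop_support`` ends the
    path early once that many distinct penalized covariates are active
    (the support is non-decreasing, so truncation is exact for any
    statistic that only looks at steps up to a given support size).
    """
    z = np.atleast_2d(np.asarray(z, float))
    if not np.all(np.isfinite(z)):
        raise InvalidArgumentError("covariate matrix contains non-finite values")
    n, p = z.shape
    mandatory = np.asarray(sorted(config.mandatory), dtype=int)
    pen_cols = np.setdiff1d(np.arange(p), mandatory)
    lam = config.penalty if config.penalty is not None else penalty_from_nu(config.nu, config.family, response)

    if config.family == "logistic":
        y = np.asarray(response, float)
        fitter = _LogisticEngine(z, y, mandatory)
    elif config.family == "gaussian":
        y = np.asarray(response, float)
        fitter = _GaussianEngine(z, y, mandatory)
    else:
        time, event = response
        fitter = _CoxEngine(z, time, event, mandatory)

    selected, updates = [], []
    intercepts = [fitter.intercept]
    mand_path = [fitter.gamma.copy()]
    logliks = [fitter.loglik()]
    beta = np.zeros(p)
    active: set[int] = set()

    # candidate models are pure one-parameter updates on the current offset,
    # so the logistic information is the raw weighted second moment; for cox
    # the partial-likelihood score and information are shift-invariant anyway
    zp = z[:, pen_cols]
    for m in range(config.max_steps):
        u, i = fitter.score_info_penalized(zp)
        stat = u**2 / (i + lam)
        k = int(np.argmax(stat))  # argmax takes the lowest index on ties
        j = int(pen_cols[k])
        upd = u[k] / (i[k] + lam)
        beta[j] += upd
        fitter.apply_penalized_update(j, upd)
        fitter.refresh_unpenalized()
        ll = fitter.loglik()
        if not np.isfinite(ll):
            raise DivergenceError(f"non-finite likelihood at boosting step {m + 1}")
        selected.append(j)
        updates.append(upd)
        intercepts.append(fitter.intercept)
        mand_path.append(fitter.gamma.copy())
        logliks.append(ll)
        if beta[j] != 0.0:
            active.add(j)
        elif j in active:
            active.discard(j)
        if stop_support is not None and len(active) >= stop_support:
            break

    coef = beta
    coef[mandatory] = fitter.gamma
    return BoostPath(
        family=config.family,
        penalized=pen_cols,
        selected=np.asarray(selected, dtype=int),
        updates=np.asarray(updates, dtype=float),
        intercept_path=np.asarray(intercepts, dtype=float),
        mandatory=mandatory,
        mandatory_path=np.asarray(mand_path, dtype=float).reshape(len(mand_path), len(mandatory)),
        loglik_path=np.asarray(logliks, dtype=float),
        penalty=float(lam),
        coef=coef,
    )


class _LogisticEngine:
    def __init__(self, z: np.ndarray, y: np.ndarray, mandatory: np.ndarray):
        self.z = z
        self.y = y
        self.mandatory = mandatory
        self.gamma = np.zeros(len(mandatory))
        pbar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        self.intercept = float(np.log(pbar / (1 - pbar)))
        self.eta = np.full(y.shape[0], self.intercept)
        if len(mandatory):
            # start the mandatory block near its null-adjusted fit
            for _ in range(5):
                self.refresh_unpenalized()

    def loglik(self) -> float:
        return _logistic_loglik(self.y, self.eta)

    def score_info_penalized(self, zp: np.ndarray):
        pr = expit(self.eta)
        r = self.y - pr
        w = pr * (1.0 - pr)
        return zp.T @ r, (zp**2).T @ w

    def apply_penalized_update(self, j: int, upd: float) -> None:
        self.eta = self.eta + upd * self.z[:, j]

    def shift_intercept(self, d: float) -> None:
        self.intercept += d
        self.eta = self.eta + d

    def refresh_unpenalized(self) -> None:
        pr = expit(self.eta)
        r = self.y - pr
        w = pr * (1.0 - pr)
        x = np.column_stack([np.ones(self.z.shape[0]), self.z[:, self.mandatory]])
        xtwx = (x * w[:, None]).T @ x
        # tiny ridge keeps the refresh defined under (near-)separation
        step = np.linalg.solve(xtwx + 1e-10 * np.eye(x.shape[1]), x.T @ r)
        self.intercept += float(step[0])
        self.gamma = self.gamma + step[1:]
        self.eta = self.eta + x @ step


class _GaussianEngine:
    """Continuous response with identity link (unit error variance)."""

    def __init__(self, z: np.ndarray, y: np.ndarray, mandatory: np.ndarray):
        self.z = z
        self.y = y
        self.mandatory = mandatory
        self.gamma = np.zeros(len(mandatory))
        self.intercept = float(y.mean())
        self.eta = np.full(y.shape[0], self.intercept)
        if len(mandatory):
            self.refresh_unpenalized()

    def loglik(self) -> float:
        return float(-0.5 * np.sum((self.y - self.eta) ** 2))

    def score_info_penalized(self, zp: np.ndarray):
        r = self.y - self.eta
        return zp.T @ r, np.sum(zp**2, axis=0)

    def apply_penalized_update(self, j: int, upd: float) -> None:
        self.eta = self.eta + upd * self.z[:, j]

    def refresh_unpenalized(self) -> None:
        r = self.y - self.eta
        x = np.column_stack([np.ones(self.z.shape[0]), self.z[:, self.mandatory]])
        step, *_ = np.linalg.lstsq(x, r, rcond=None)
        self.intercept += float(step[0])
        self.gamma = self.gamma + step[1:]
        self.eta = self.eta + x @ step


class _CoxEngine:
    def __init__(self, z: np.ndarray, time, event, mandatory: np.ndarray):
        self.ws = _CoxWorkspace(time, event)
        self.z = z[self.ws.order]
        self.mandatory = mandatory
        self.gamma = np.zeros(len(mandatory))
        self.intercept = 0.0  # the Cox model has no intercept
        self.eta = np.zeros(self.z.shape[0])
        if len(mandatory):
            for _ in range(5):
                self.refresh_unpenalized()

    def loglik(self) -> float:
        return self.ws.loglik(self.eta)

    def score_info_penalized(self, zp: np.ndarray):
        # zp arrives in original sample order and is fixed along the path:
        # sort it once and cache
        if getattr(self, "_zp_src", None) is not zp:
            self._zp_sorted = zp[self.ws.order]
            self._zp_src = zp
        return self.ws.score_info_all(self._zp_sorted, self.eta)

    def apply_penalized_update(self, j: int, upd: float) -> None:
        self.eta = self.eta + upd * self.z[:, j]

    def refresh_unpenalized(self) -> None:
        if not len(self.mandatory):
            return
        zm = self.z[:, self.mandatory]
        u, info = self.ws.score_info_block(zm, self.eta)
        step = np.linalg.solve(info + 1e-10 * np.eye(len(u)), u)
        self.gamma = self.gamma + step
        self.eta = self.eta + zm @ step


# ---------------------------------------------------------------------------
# ridge closed forms


def ridge_closed_form(x: np.ndarray, y: np.ndarray, penalty) -> np.ndarray:
    """(X'X + diag(penalty))^-1 X'y with a scalar or per-covariate penalty."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float)
    p = x.shape[1]
    pen = np.broadcast_to(np.asarray(penalty, float), (p,))
    if np.any(pen < 0):
        raise InvalidArgumentError("ridge penalties must be non-negative")
    gram = x.T @ x + np.diag(pen)
    if np.all(pen == 0) and np.linalg.matrix_rank(x) < p:
        raise np.linalg.LinAlgError("singular system: lambda = 0 with rank-deficient design")
    return np.linalg.solve(gram, x.T @ y)


def ridge_standardized(x: np.ndarray, y: np.ndarray, penalty) -> tuple[np.ndarray, np.ndarray]:
    """Ridge on the column-standardized design; returns (beta_std, scales).

    ``x`` must be column-centered.  The unstandardized-scale solution is
    ``beta_std / scales``.
    """
    x = np.atleast_2d(np.asarray(x, float))
    s = x.std(axis=0, ddof=1)
    if np.any(s == 0):
        raise InvalidArgumentError("cannot standardize a constant column")
    return ridge_closed_form(x / s, y, penalty), s


# ---------------------------------------------------------------------------
# lasso Cox with mandatory covariates


def _coxnet_models(z, time, event, penalty_factor, alphas=None, n_alphas=30, tol=1e-13):
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    y = Surv.from_arrays(np.asarray(event).astype(bool), np.asarray(time, float))
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=None if alphas is None else list(alphas),
        n_alphas=n_alphas,
        alpha_min_ratio=0.05,
        penalty_factor=penalty_factor,
        normalize=False,
        tol=tol,
        max_iter=1_000_000,
    )
    model.fit(np.asarray(z, float), y)
    return model


def check_kkt(z, time, event, coef, alpha, penalty_factor, tol=1e-6) -> float:
    """Max KKT violation of the L1-penalized Cox partial likelihood.

    Stationarity of -(1/n) pl(beta) + alpha * sum_j pf_j |beta_j| (with
    penalty factors rescaled to mean one, the glmnet convention):
    |g_j| <= alpha * pf_j where beta_j = 0, and g_j = -alpha pf_j
    sign(beta_j) otherwise, with g the gradient of -(1/n) pl.
    """
    z = np.asarray(z, float)
    n = z.shape[0]
    ws = _CoxWorkspace(time, event)
    zs = z[ws.order]
    u, _ = ws.score_info_all(zs, zs @ coef)
    g = -u / n
    pf = np.asarray(penalty_factor, float)
    pf = pf * len(pf) / pf.sum()
    viol = np.where(
        coef == 0.0,
        np.maximum(np.abs(g) - alpha * pf, 0.0),
        np.abs(g + alpha * pf * np.sign(coef)),
    )
    return float(viol.max())


def lasso_cox_fit(
    z: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    mandatory: tuple[int, ...] = (),
    alphas=None,
    n_alphas: int = 30,
    kkt_tol: float = 1e-6,
) -> list[FitResult]:
    """L1-penalized Cox path with an unpenalized mandatory block.

    Returns one :class:`FitResult` per penalty value, in decreasing
    penalty order; each solution's KKT conditions are verified.
    """
    z = np.atleast_2d(np.asarray(z, float))
    p = z.shape[1]
    pf = np.ones(p)
    pf[list(mandatory)] = 0.0
    model = _coxnet_models(z, time, event, pf, alphas=alphas, n_alphas=n_alphas)
    results = []
    for k, alpha in enumerate(model.alphas_):
        coef = model.coef_[:, k]
        viol = check_kkt(z, time, event, coef, alpha, pf, tol=kkt_tol)
        # stationarity is checked on the scale of the penalty itself
        if viol > max(kkt_tol, 1e-5) * max(1.0, alpha):
            raise OptimizationError(f"KKT violation {viol:.2e} at alpha = {alpha:.4g}")
        pen_mask = pf > 0
        selected = np.flatnonzero(pen_mask & (coef != 0.0))
        results.append(
            FitResult(coef=coef, selected=selected, tuning={"alpha": float(alpha), "kkt": viol}, family="cox")
        )
    return results


# ---------------------------------------------------------------------------
# cross-validation tuning


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    # global round-robin position: balances classes across folds and reduces
    # to leave-one-out singletons when k equals the sample size
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def cv_tune(
    z: np.ndarray,
    response,
    family: str,
    method: str = "boost",
    folds: int = 10,
    seed: int = 0,
    max_steps: int = 100,
    nu: float = 0.1,
    penalty: float | None = None,
    mandatory: tuple[int, ...] = (),
    alphas=None,
    n_alphas: int = 30,
):
    """Cross-validated stopping step (boosting) or penalty (lasso).

    Folds are stratified by the outcome (y for logistic, the event
    indicator for Cox) and seeded.  The criterion is the mean
    out-of-fold log-likelihood; for Cox the out-of-fold contribution is
    pl(full data) - pl(training fold), evaluated at the fold's
    coefficients.  Ties break toward the smaller model.
    """
    if folds < 2:
        raise InvalidArgumentError("folds must be >= 2")
    z = np.atleast_2d(np.asarray(z, float))
    n = z.shape[0]
    if family == "logistic":
        y = np.asarray(response)
        strat = y
    else:
        time, event = response
        time = np.asarray(time, float)
        event = np.asarray(event)
        strat = event

    rng = np.random.default_rng(seed)
    for attempt in range(10):
        fold_idx = _stratified_folds(strat, folds, rng)
        if family == "logistic":
            break
        ok = all(event[np.setdiff1d(np.arange(n), f)].sum() >= 1 for f in fold_idx)
        if ok:
            break
        warnings.warn(f"fold without events on attempt {attempt + 1}; refolding")
    else:
        raise InvalidArgumentError("could not build folds with events in every training part")

    if method == "boost":
        return _cv_boost(z, response, family, fold_idx, max_steps, nu, penalty, mandatory)
    if method == "lasso":
        if family != "cox":
            raise InvalidArgumentError("lasso tuning is implemented for the cox family")
        return _cv_lasso(z, time, event, fold_idx, mandatory, alphas, n_alphas)
    raise InvalidArgumentError(f"unknown method {method!r}")


def _cv_boost(z, response, family, fold_idx, max_steps, nu, penalty, mandatory):
    n = z.shape[0]
    scores = np.zeros((len(fold_idx), max_steps + 1))
    for f, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n), test)
        z_tr = z[train]
        if family == "logistic":
            y = np.asarray(response)
            resp_tr = y[train]
        else:
            time, event = response
            resp_tr = (time[train], event[train])
        if penalty is not None:
            cfg = BoostConfig(family=family, max_steps=max_steps, penalty=penalty, mandatory=mandatory)
        else:
            cfg = BoostConfig(family=family, max_steps=max_steps, nu=nu, mandatory=mandatory)
        path = boost_fit(z_tr, resp_tr, cfg)

        eta_pen_full = np.zeros(n)
        for m in range(max_steps + 1):
            if 0 < m <= path.n_steps:
                eta_pen_full = eta_pen_full + path.updates[m - 1] * z[:, path.selected[m - 1]]
            mm = min(m, path.n_steps)
            eta_full = eta_pen_full + path.intercept_path[mm]
            if len(path.mandatory):
                eta_full = eta_full + z[:, path.mandatory] @ path.mandatory_path[mm]
            if family == "logistic":
                scores[f, m] = _logistic_loglik(y[test], eta_full[test])
            else:
                scores[f, m] = cox_partial_loglik(eta_full, time, event) - cox_partial_loglik(
                    eta_full[train], time[train], event[train]
                )
    mean_scores = scores.mean(axis=0)
    best = int(np.argmax(mean_scores))  # first (smallest) index wins ties
    return best, mean_scores


def _cv_lasso(z, time, event, fold_idx, mandatory, alphas, n_alphas):
    n = z.shape[0]
    pf = np.ones(z.shape[1])
    pf[list(mandatory)] = 0.0
    if alphas is None:
        full = _coxnet_models(z, time, event, pf, n_alphas=n_alphas, tol=1e-9)
        alphas = np.asarray(full.alphas_)
    alphas = np.asarray(sorted(alphas, reverse=True), float)
    scores = np.zeros((len(fold_idx), len(alphas)))
    for f, test in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n), test)
        # fold fits only rank penalty values; a looser solver tolerance
        # suffices here, the KKT-verified fit is refit afterwards
        model = _coxnet_models(z[train], time[train], event[train], pf, alphas=alphas, tol=1e-9)
        fitted = {round(float(a), 12): model.coef_[:, k] for k, a in enumerate(model.alphas_)}
        for k, a in enumerate(alphas):
            coef = fitted.get(round(float(a), 12))
            if coef is None:
                scores[f, k] = -np.inf
                continue
            eta_full = z @ coef
            scores[f, k] = cox_partial_loglik(eta_full, time, event) - cox_partial_loglik(
                eta_full[train], time[train], event[train]
            )
    mean_scores = scores.mean(axis=0)
    best = int(np.argmax(mean_scores))  # alphas decreasing: first index = sparser model
    return float(alphas[best]), mean_scores
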