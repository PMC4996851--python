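"""Cox proportional-hazards estimation strategies.

Six strategies are implemented on a common Breslow partial-likelihood core:

* ``full`` — Newton-Raphson maximum partial likelihood on all predictors.
* ``be`` — backward elimination: iteratively drop the least significant
  predictor (Wald or likelihood-ratio p-value) while it exceeds a
  significance level; an empty final set means the model predicts one
  survival curve for everybody (a Kaplan-Meier-like estimator).
* ``ridge`` / ``lasso`` / ``elastic`` — maximization of the scaled penalized
  partial log-likelihood

      (2/n) l(beta) - lambda * [ a * ||beta||_1 + (1-a)/2 * ||beta||_2^2 ]

  by outer iteratively-reweighted quadratic approximation and inner cyclic
  coordinate descent with soft-thresholding, warm-started along a decreasing
  lambda path.  Covariates are standardized internally (mean 0, population
  variance 1); returned coefficients are on the original scale.  lambda (and
  for the elastic net the mixing parameter, on a 0..1 grid of step 0.05) is
  chosen to maximize the Verweij-van Houwelingen cross-validated partial
  log-likelihood.
* ``be_ridge`` — backward elimination followed by a CV-tuned ridge refit on
  the selected predictors.

Ties are handled with the Breslow approximation throughout, which keeps the
lambda -> 0 limit of the penalized solver consistent with the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm

from . import _risk
from ._risk import (
    SurvivalOrder,
    breslow_loglik,
    grad_hess_eta,
    loglik_many,
    path_solve,
)
from .censoring import SurvivalOutcome
from .synthetic_cohort import CovariateMatrix

__all__ = [
    "PenaltyConfig",
    "BEConfig",
    "FittedCoxModel",
    "CVResult",
    "cox_partial_loglik",
    "fit_cox_full",
    "wald_pvalues",
    "fit_backward_elimination",
    "lambda_path",
    "fit_coxnet",
    "cv_partial_loglik",
    "kmeans_balanced_folds",
    "fit_method",
    "METHODS",
]

METHODS = ("full", "be", "ridge", "lasso", "elastic", "be_ridge")

#: divergence guard: |beta_j| beyond this flags monotone-likelihood behavior
BETA_BOUND = 50.0

#: relative pad on lambda_max so the zero vector is the exact solution at the
#: top of the path despite floating-point round-off in the gradient
_LAM_MAX_PAD = 1.0 + 1e-9


def _values(X) -> np.ndarray:
    return X.values if isinstance(X, CovariateMatrix) else np.asarray(X, float)


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class PenaltyConfig:
    """Tuning settings for the penalized fits."""

    alpha_mix: float = 0.0
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    k: int = 10
    fold_seed: int = 0
    fold_strategy: str = "random"  # or "kmeans_balanced"
    alpha_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 1.0001, 0.05), 2)
    )

    def __post_init__(self):
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must lie in [0, 1]")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        self.alpha_grid = np.asarray(self.alpha_grid, float)
        if self.alpha_grid.min() < 0 or self.alpha_grid.max() > 1:
            raise ValueError("alpha_grid values must lie in [0, 1]")
        if self.fold_strategy not in ("random", "kmeans_balanced"):
            raise ValueError(f"unknown fold strategy {self.fold_strategy!r}")


@dataclass
class BEConfig:
    alpha_be: float = 0.05
    test: str = "wald"  # or "likelihood_ratio"

    def __post_init__(self):
        if not 0.0 < self.alpha_be < 1.0:
            raise ValueError("alpha_be must lie in (0, 1)")
        if self.test not in ("wald", "likelihood_ratio"):
            raise ValueError(f"unknown BE test {self.test!r}")


@dataclass
class CVResult:
    """Cross-validated partial log-likelihood over the tuning grid."""

    alphas: np.ndarray  # (A,)
    lambdas: np.ndarray  # (A, L), decreasing along axis 1
    values: np.ndarray  # (A, L)
    chosen_alpha_index: int
    chosen_lambda_index: int

    @property
    def chosen_alpha(self) -> float:
        return float(self.alphas[self.chosen_alpha_index])

    @property
    def chosen_lambda(self) -> float:
        return float(self.lambdas[self.chosen_alpha_index, self.chosen_lambda_index])

    def __post_init__(self):
        if self.lambdas.shape != self.values.shape:
            raise ValueError("values must align with the lambda grid")
        a, l = self.chosen_alpha_index, self.chosen_lambda_index
        if self.values[a, l] != np.nanmax(self.values):
            raise ValueError("chosen index must attain the CV maximum")


@dataclass
class FittedCoxModel:
    """One estimation strategy's result.

    ``beta_hat`` always has length p; predictors dropped by selection carry
    exact zeros and ``selected`` False.  ``baseline`` is the Breslow
    cumulative-hazard step function estimated at ``beta_hat``.
    """

    method: str
    beta_hat: np.ndarray
    selected: np.ndarray
    baseline: object = None
    tuning: CVResult | None = None
    converged: bool = True
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.beta_hat = np.asarray(self.beta_hat, float)
        self.selected = np.asarray(self.selected, bool)

    @property
    def constant_prediction(self) -> bool:
        return (not self.selected.any()) or bool(np.all(self.beta_hat == 0.0))

    @property
    def flags(self) -> dict:
        return {
            "constant_prediction": self.constant_prediction,
            "converged": self.converged,
        }

    def linear_predictor(self, X) -> np.ndarray:
        return _values(X) @ self.beta_hat

    def to_json(self) -> str:
        import json

        names = self.names or [f"x{j}" for j in range(self.beta_hat.size)]
        d = {
            "method": self.method,
            "coefficients": dict(zip(names, self.beta_hat.tolist())),
            "selected": dict(zip(names, self.selected.astype(bool).tolist())),
            "flags": self.flags,
        }
        if self.baseline is not None:
            d["baseline"] = {
                "times": np.asarray(self.baseline.times).tolist(),
                "cumulative_hazard": np.asarray(self.baseline.cumhaz).tolist(),
            }
        if self.tuning is not None:
            d["tuning"] = {
                "chosen_lambda": self.tuning.chosen_lambda,
                "chosen_alpha": self.tuning.chosen_alpha,
            }
        return json.dumps(d)


# ---------------------------------------------------------------------------
# partial likelihood and the full model


def cox_partial_loglik(beta, X, outcome: SurvivalOutcome) -> float:
    """Breslow partial log-likelihood l(beta)."""
    V = _values(X)
    order = SurvivalOrder(outcome.time, outcome.status)
    if outcome.n_events == 0:
        raise ValueError("partial likelihood undefined without events")
    eta = (V @ np.asarray(beta, float))[order.order]
    return breslow_loglik(order, eta)


def _neg_hessian(Vs: np.ndarray, order: SurvivalOrder, eta: np.ndarray, u: np.ndarray):
    """Observed information of the Breslow partial likelihood w.r.t. beta.

    -l''(beta) = X' diag(wt) X - M' D M with wt_i = exp(eta_i) * A_i
    (recovered as status - u), M the risk-set means S1/S0 per event group
    and D the event multiplicities.
    """
    wt = order.status - u
    m = eta.max()
    e = np.exp(eta - m)
    s0 = _risk._risk_sums(order, e)
    s1 = _risk._risk_sums(order, Vs * e[:, None])
    M = s1 / s0[:, None]
    d = order.group_events.astype(float)
    return (Vs * wt[:, None]).T @ Vs - (M * d[:, None]).T @ M


def _newton_cox(V: np.ndarray, order: SurvivalOrder, tol: float = 1e-8,
                max_iter: int = 100):
    """Newton-Raphson with step halving; returns (beta, converged, info)."""
    Vs = V[order.order]
    p = V.shape[1]
    beta = np.zeros(p)
    eta = np.zeros(order.n)
    ll, u, _ = grad_hess_eta(order, eta)
    converged = False
    info = None
    for _ in range(max_iter):
        g = Vs.T @ u
        info = _neg_hessian(Vs, order, eta, u)
        if np.max(np.abs(g)) <= tol:
            converged = True
            break
        try:
            with np.errstate(all="raise"):
                step = np.linalg.solve(info, g)
        except (np.linalg.LinAlgError, FloatingPointError):
            converged = False
            break
        if not np.isfinite(step).all() or np.linalg.cond(info) > 1e12:
            converged = False
            break
        # backtracking on the partial log-likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = breslow_loglik(order, Vs @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > BETA_BOUND:
            converged = False  # monotone-likelihood divergence
            break
        eta = Vs @ beta
        ll, u, _ = grad_hess_eta(order, eta)
    return beta, converged, info


def fit_cox_full(X, outcome: SurvivalOutcome) -> FittedCoxModel:
    """Maximum partial-likelihood Cox fit using every predictor."""
    V = _values(X)
    if outcome.n_events == 0:
        raise ValueError("cannot fit a Cox model without events")
    if np.any(V.std(axis=0) == 0):
        raise ValueError("zero-variance covariate column")
    order = SurvivalOrder(outcome.time, outcome.status)
    beta, converged, _ = _newton_cox(V, order)
    from .prediction import breslow_baseline

    names = X.names if isinstance(X, CovariateMatrix) else []
    return FittedCoxModel(
        method="full",
        beta_hat=beta,
        selected=np.ones(V.shape[1], bool),
        baseline=breslow_baseline(V, outcome, beta),
        converged=converged,
        names=list(names),
    )


def wald_pvalues(fit: FittedCoxModel, X, outcome: SurvivalOutcome) -> np.ndarray:
    """Two-sided Wald p-values from the inverse observed information.

    Unselected predictors get NaN; a singular information matrix yields NaN
    p-values with a warning.
    """
    V = _values(X)
    sel = fit.selected
    Vsel = V[:, sel]
    order = SurvivalOrder(outcome.time, outcome.status)
    eta = (Vsel @ fit.beta_hat[sel])[order.order]
    _, u, _ = grad_hess_eta(order, eta)
    info = _neg_hessian(Vsel[order.order], order, eta, u)
    p = np.full(V.shape[1], np.nan)
    try:
        with np.errstate(all="raise"):
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))
        z = fit.beta_hat[sel] / se
        p[sel] = 2.0 * norm.sf(np.abs(z))
    except (np.linalg.LinAlgError, FloatingPointError):
        warnings.warn("singular information matrix; Wald p-values unavailable")
    return p


def fit_backward_elimination(
    X, outcome: SurvivalOutcome, cfg: BEConfig | None = None
) -> FittedCoxModel:
    """Backward elimination: drop the single worst predictor while its
    p-value exceeds ``cfg.alpha_be``, refitting after every drop.

    An empty final set gives ``constant_prediction`` — every individual is
    assigned the same (Kaplan-Meier-like) survival curve.
    """
    cfg = cfg or BEConfig()
    V = _values(X)
    names = list(X.names) if isinstance(X, CovariateMatrix) else []
    p_total = V.shape[1]
    order = SurvivalOrder(outcome.time, outcome.status)
    selected = np.ones(p_total, bool)
    beta_sel = np.zeros(0)
    converged = True
    while selected.any():
        Vsel = V[:, selected]
        beta_sel, conv, info = _newton_cox(Vsel, order)
        converged = conv
        pvals = _subset_pvalues(Vsel, order, beta_sel, info, cfg)
        worst = np.nanargmax(np.where(np.isnan(pvals), np.inf, pvals))
        worst_p = pvals[worst]
        if np.isnan(worst_p):
            worst_p = np.inf  # uninformative predictor: drop it
        if worst_p <= cfg.alpha_be:
            break
        idx = np.flatnonzero(selected)[worst]
        selected[idx] = False
        beta_sel = np.delete(beta_sel, worst)

    beta = np.zeros(p_total)
    beta[selected] = beta_sel
    from .prediction import breslow_baseline

    return FittedCoxModel(
        method=f"be_{cfg.alpha_be}",
        beta_hat=beta,
        selected=selected,
        baseline=breslow_baseline(V, outcome, beta),
        converged=converged,
        names=names,
    )


def _subset_pvalues(Vsel, order, beta_sel, info, cfg: BEConfig) -> np.ndarray:
    if cfg.test == "wald":
        try:
            with np.errstate(all="raise"):
                se = np.sqrt(np.diag(np.linalg.inv(info)))
            return 2.0 * norm.sf(np.abs(beta_sel / se))
        except (np.linalg.LinAlgError, FloatingPointError):
            return np.full(beta_sel.size, np.nan)
    # likelihood-ratio: refit without each variable in turn
    ll_full = breslow_loglik(order, Vsel[order.order] @ beta_sel)
    pvals = np.empty(beta_sel.size)
    for j in range(beta_sel.size):
        Vred = np.delete(Vsel, j, axis=1)
        if Vred.shape[1] == 0:
            ll_red = breslow_loglik(order, np.zeros(order.n))
        else:
            b_red, _, _ = _newton_cox(Vred, order)
            ll_red = breslow_loglik(order, Vred[order.order] @ b_red)
        pvals[j] = chi2.sf(max(0.0, 2.0 * (ll_full - ll_red)), df=1)
    return pvals


# ---------------------------------------------------------------------------
# penalized fits


def _standardize(V: np.ndarray):
    mu = V.mean(axis=0)
    sd = V.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (V - mu) / sd_safe, mu, sd_safe


def _gradient_at_zero(Vs_sorted: np.ndarray, order: SurvivalOrder) -> np.ndarray:
    """(2/n) * gradient of the partial log-likelihood at beta = 0."""
    _, u, _ = grad_hess_eta(order, np.zeros(order.n))
    return 2.0 * (Vs_sorted.T @ u) / order.n


#: default relative depth of the regularization path (n > p convention)
DEFAULT_LAMBDA_MIN_RATIO = 1e-4


def _lambda_grid(lam_max: float, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    """Log-spaced grid from lam_max down to lam_max * lambda_min_ratio.

    The per-step factor is anchored so that the default span holds exactly
    ``n_lambda`` points; a smaller ratio therefore extends the grid downward
    without changing the upper entries.
    """
    log_step = np.log(DEFAULT_LAMBDA_MIN_RATIO) / (n_lambda - 1)
    n_steps = int(np.ceil(np.log(lambda_min_ratio) / log_step - 1e-12))
    return lam_max * np.exp(log_step * np.arange(n_steps + 1))


def lambda_path(
    X,
    outcome: SurvivalOutcome,
    alpha_mix: float,
    n_lambda: int = 100,
    lambda_min_ratio: float = DEFAULT_LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Decreasing log-spaced lambda grid for the penalized objective.

    lambda_max = max_j |(2/n) dl/dbeta_j(0)| / alpha on the standardized
    scale (every coefficient is zero there); the pure-ridge grid uses the
    alpha = 0.001 value of that formula, i.e. an inflation by 1/0.001.
    """
    V = _values(X)
    Vs, _, _ = _standardize(V)
    order = SurvivalOrder(outcome.time, outcome.status)
    g = _gradient_at_zero(Vs[order.order], order)
    denom = alpha_mix if alpha_mix > 0 else 0.001
    lam_max = np.max(np.abs(g)) * _LAM_MAX_PAD / denom
    if lam_max <= 0:
        lam_max = 1.0
    return _lambda_grid(lam_max, n_lambda, lambda_min_ratio)


def _fit_path(V: np.ndarray, time, status, alpha_mix, lambdas,
              tol: float = 1e-9, max_outer: int = 100, max_sweeps: int = 100_000):
    """Path fit on original-scale covariates; coefficients back-transformed."""
    order = SurvivalOrder(time, status)
    Vs, _, sd = _standardize(V)
    B, converged = path_solve(
        np.ascontiguousarray(Vs[order.order]),
        order.time,
        order.status,
        order.group_start,
        order.group_events,
        float(alpha_mix),
        np.asarray(lambdas, float),
        tol,
        max_outer,
        max_sweeps,
    )
    return B / sd[None, :], bool(converged)


def fit_coxnet(X, outcome: SurvivalOutcome, alpha_mix: float, lam: float) -> np.ndarray:
    """Elastic-net penalized Cox coefficients at a single (alpha, lambda).

    Warm-starts from the top of the regularization path down to ``lam``;
    ``lam = 0`` reproduces the unpenalized (full-model) fit.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    V = _values(X)
    top = lambda_path(X, outcome, alpha_mix, n_lambda=2)[0]
    if lam >= top:
        lambdas = np.array([lam])
    elif lam > 0:
        steps = max(int(np.ceil(25 * np.log10(top / lam) / 4.0)), 2)
        lambdas = np.geomspace(top, lam, steps)
    else:
        lambdas = np.append(np.geomspace(top, top * 1e-4, 25), 0.0)
    B, converged = _fit_path(V, outcome.time, outcome.status, alpha_mix, lambdas)
    if not converged:
        warnings.warn("coordinate descent did not fully converge")
    return B[-1]


def _make_random_folds(n, k, n_events_mask, seed):
    rng = np.random.default_rng(seed)
    for _ in range(5):
        folds = rng.permutation(np.arange(n) % k)
        ok = all((n_events_mask & (folds != f)).sum() > 0 for f in range(k))
        if ok:
            return folds
        warnings.warn("fold with zero training events; reshuffling")
    raise ValueError("could not build folds with events in every training set")


def kmeans_balanced_folds(X, k: int = 10, seed: int = 0) -> np.ndarray:
    """Predictor-balanced folds: K-means clusters on standardized predictors,
    then members of each cluster dealt (in random order) across the k folds,
    so every fold receives floor(c/k) or ceil(c/k) members of each cluster."""
    from sklearn.cluster import KMeans

    V = _values(X)
    n = V.shape[0]
    if n < k:
        raise ValueError("need at least k observations")
    Vs, _, _ = _standardize(V)
    rng = np.random.default_rng(seed)
    labels = None
    for attempt in range(10):
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(Vs)
        if np.unique(labels).size == k:
            break
    folds = np.empty(n, dtype=int)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        rng.shuffle(members)
        start = int(rng.integers(k))
        folds[members] = (np.arange(members.size) + start) % k
    return folds


class _CVWork:
    """Per-fold training structures, built once and reused across the
    whole (alpha, lambda) tuning grid."""

    def __init__(self, V: np.ndarray, outcome: SurvivalOutcome, folds: np.ndarray):
        self.V = V
        self.order_all = SurvivalOrder(outcome.time, outcome.status)
        self.folds = []
        for f in np.unique(folds):
            tr = folds != f
            if outcome.status[tr].sum() == 0:
                raise ValueError("fold with zero training events")
            Vtr = V[tr]
            order_tr = SurvivalOrder(outcome.time[tr], outcome.status[tr])
            Vs, _, sd = _standardize(Vtr)
            self.folds.append(
                (Vtr, order_tr, np.ascontiguousarray(Vs[order_tr.order]), sd)
            )

    def cv_curve(self, alpha_mix: float, lambdas: np.ndarray,
                 tol: float = 1e-6, max_outer: int = 3,
                 max_sweeps: int = 2) -> np.ndarray:
        """Verweij-van Houwelingen criterion:
        CV(lambda) = sum_k [ l_all(beta^(-k)) - l_(-k)(beta^(-k)) ].

        Fold fits run in path-tracking mode (a few reweighting passes per
        lambda, riding the warm starts); only the argmax feeds tuning, and
        the final model is refit to full convergence at the chosen point.
        """
        cv = np.zeros(lambdas.size)
        for Vtr, order_tr, Vs_sorted, sd in self.folds:
            Bs, _ = path_solve(
                Vs_sorted,
                order_tr.time,
                order_tr.status,
                order_tr.group_start,
                order_tr.group_events,
                float(alpha_mix),
                lambdas,
                tol,
                max_outer,
                max_sweeps,
            )
            B = Bs / sd[None, :]
            eta_all = self.V @ B.T
            eta_tr = Vtr @ B.T
            cv += loglik_many(self.order_all, eta_all[self.order_all.order])
            cv -= loglik_many(order_tr, eta_tr[order_tr.order])
        return cv


def _cv_for_alpha(V, outcome: SurvivalOutcome, alpha_mix, lambdas, folds):
    return _CVWork(V, outcome, folds).cv_curve(alpha_mix, np.asarray(lambdas, float))


def cv_partial_loglik(
    X,
    outcome: SurvivalOutcome,
    alpha_mix: float,
    lambdas: np.ndarray | None = None,
    k: int = 10,
    folds: np.ndarray | None = None,
    fold_seed: int = 0,
) -> CVResult:
    """Cross-validated partial log-likelihood over a lambda grid (one alpha)."""
    V = _values(X)
    lambdas = (
        lambda_path(X, outcome, alpha_mix) if lambdas is None else np.asarray(lambdas, float)
    )
    if folds is None:
        folds = _make_random_folds(V.shape[0], k, outcome.status == 1, fold_seed)
    cv = _cv_for_alpha(V, outcome, alpha_mix, lambdas, folds)
    return CVResult(
        alphas=np.array([alpha_mix]),
        lambdas=lambdas[None, :],
        values=cv[None, :],
        chosen_alpha_index=0,
        chosen_lambda_index=int(np.argmax(cv)),
    )


def _fit_penalized(V, outcome, names, method, cfg: PenaltyConfig, folds):
    """CV-tuned ridge/lasso/elastic fit on an ndarray of covariates."""
    if folds is None:
        if cfg.fold_strategy == "kmeans_balanced":
            folds = kmeans_balanced_folds(V, cfg.k, cfg.fold_seed)
        else:
            folds = _make_random_folds(
                V.shape[0], cfg.k, outcome.status == 1, cfg.fold_seed
            )
    alphas = {
        "ridge": np.array([0.0]),
        "lasso": np.array([1.0]),
        "elastic": cfg.alpha_grid,
    }[method]
    L = cfg.n_lambda
    work = _CVWork(V, outcome, folds)
    # lambda_max depends on alpha only through a scalar division, so the
    # gradient at zero is computed once
    Vs, _, _ = _standardize(V)
    g = _gradient_at_zero(Vs[work.order_all.order], work.order_all)
    gmax = max(np.max(np.abs(g)) * _LAM_MAX_PAD, 1e-300)
    L_actual = _lambda_grid(1.0, L, cfg.lambda_min_ratio).size
    lam_grid = np.empty((alphas.size, L_actual))
    values = np.empty((alphas.size, L_actual))
    for ai, a in enumerate(alphas):
        lam_max = gmax / (a if a > 0 else 0.001)
        lam_grid[ai] = _lambda_grid(lam_max, L, cfg.lambda_min_ratio)
        values[ai] = work.cv_curve(a, lam_grid[ai])
    ai, li = np.unravel_index(np.argmax(values), values.shape)
    cvres = CVResult(alphas, lam_grid, values, int(ai), int(li))
    # final fit on all data at the chosen point, warm-started down the path
    B, converged = _fit_path(
        V, outcome.time, outcome.status, cvres.chosen_alpha, lam_grid[ai, : li + 1]
    )
    beta = B[-1]
    from .prediction import breslow_baseline

    return FittedCoxModel(
        method=method,
        beta_hat=beta,
        selected=beta != 0.0,
        baseline=breslow_baseline(V, outcome, beta),
        tuning=cvres,
        converged=converged,
        names=list(names),
    )


def fit_method(
    method: str,
    X,
    outcome: SurvivalOutcome,
    penalty_cfg: PenaltyConfig | None = None,
    be_cfg: BEConfig | None = None,
    folds: np.ndarray | None = None,
) -> FittedCoxModel:
    """Dispatch a single estimation strategy by name.

    ``be_ridge`` runs backward elimination, then a CV-tuned ridge restricted
    to the selected predictors; if nothing was selected the result is a
    constant-prediction model.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    V = _values(X)
    names = list(X.names) if isinstance(X, CovariateMatrix) else []
    if method == "full":
        return fit_cox_full(X, outcome)
    if method == "be":
        return fit_backward_elimination(X, outcome, be_cfg)
    cfg = penalty_cfg or PenaltyConfig()
    if method in ("ridge", "lasso", "elastic"):
        return _fit_penalized(V, outcome, names, method, cfg, folds)
    # be_ridge
    be_fit = fit_backward_elimination(X, outcome, be_cfg)
    sel = be_fit.selected
    from .prediction import breslow_baseline

    if not sel.any():
        beta = np.zeros(V.shape[1])
        return FittedCoxModel(
            method="be_ridge",
            beta_hat=beta,
            selected=sel,
            baseline=breslow_baseline(V, outcome, beta),
            converged=be_fit.converged,
            names=names,
        )
    sub = _fit_penalized(V[:, sel], outcome, [n for n, s in zip(names, sel) if s] if names else [], "ridge", cfg, folds)
    beta = np.zeros(V.shape[1])
    beta[sel] = sub.beta_hat
    return FittedCoxModel(
        method="be_ridge",
        beta_hat=beta,
        selected=sel,
        baseline=breslow_baseline(V, outcome, beta),
        tuning=sub.tuning,
        converged=be_fit.converged and sub.converged,
        names=names,
    )
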