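"""Risk-set primitives shared by the Cox solvers and the Breslow baseline.

All quantities use the Breslow convention for tied event times: every
observation with ``t_i >= d`` belongs to the risk set of an event time ``d``,
and tied events at ``d`` share the single risk-set sum.  Simulated follow-up
times are continuous, so ties occur with probability zero, but the grouped
computation keeps the functions well defined on arbitrary input.

The hot loops (per-observation gradient/curvature of the partial
log-likelihood and the cyclic coordinate-descent sweep) are compiled with
numba; everything else is vectorized numpy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "SurvivalOrder",
    "breslow_loglik",
    "loglik_many",
    "grad_hess_eta",
    "cd_sweep",
    "cd_solve",
    "path_solve",
]


class SurvivalOrder:
    """Pre-sorted view of a survival sample.

    Sorting ascending by time once lets every downstream pass run on
    contiguous arrays.  ``group_start``/``group_events`` index the distinct
    event times (groups with at least one event).
    """

    def __init__(self, time: np.ndarray, status: np.ndarray):
        time = np.asarray(time, dtype=np.float64)
        status = np.asarray(status, dtype=np.int64)
        if time.ndim != 1 or time.shape != status.shape:
            raise ValueError("time and status must be 1-d arrays of equal length")
        order = np.argsort(time, kind="stable")
        self.order = order
        self.time = time[order]
        self.status = status[order]
        self.n = time.shape[0]
        # distinct-time group boundaries (first index of each tie group)
        is_new = np.empty(self.n, dtype=bool)
        is_new[0] = True
        is_new[1:] = self.time[1:] != self.time[:-1]
        starts = np.flatnonzero(is_new)
        ends = np.append(starts[1:], self.n)
        d = np.add.reduceat(self.status, starts) if self.n else np.array([], int)
        keep = d > 0
        self.group_start = starts[keep].astype(np.int64)
        self.group_end = ends[keep].astype(np.int64)
        self.group_events = d[keep].astype(np.int64)
        self.event_times = self.time[self.group_start]
        self.n_events = int(self.status.sum())

    def sort(self, arr: np.ndarray) -> np.ndarray:
        """Reorder an observation-aligned array into time order."""
        return np.asarray(arr)[self.order]

    def unsort(self, arr: np.ndarray) -> np.ndarray:
        out = np.empty_like(arr)
        out[self.order] = arr
        return out


def _risk_sums(order: SurvivalOrder, values: np.ndarray) -> np.ndarray:
    """Sum of ``values`` over the risk set of each event group.

    ``values`` is in time order; the risk set of group g is every index
    >= group_start[g] (ties included by construction).
    """
    rev = np.cumsum(values[::-1], axis=0)[::-1]
    return rev[order.group_start]


def breslow_loglik(order: SurvivalOrder, eta_sorted: np.ndarray) -> float:
    """Breslow partial log-likelihood at linear predictor ``eta`` (time order)."""
    if order.group_start.size == 0:
        raise ValueError("partial likelihood undefined without events")
    m = eta_sorted.max()
    s0 = _risk_sums(order, np.exp(eta_sorted - m))
    event_eta = (eta_sorted * (order.status == 1)).sum()
    return float(event_eta - (order.group_events * (np.log(s0) + m)).sum())


def loglik_many(order: SurvivalOrder, eta_sorted: np.ndarray) -> np.ndarray:
    """Vectorized Breslow partial log-likelihood for an n x L matrix of etas."""
    m = eta_sorted.max(axis=0, keepdims=True)
    s0 = _risk_sums(order, np.exp(eta_sorted - m))
    event_eta = eta_sorted[order.status == 1].sum(axis=0)
    return event_eta - (order.group_events[:, None] * (np.log(s0) + m)).sum(axis=0)


@njit(cache=True)
def _grad_hess_eta(time, status, gstart, gevents, eta):  # pragma: no cover - numba
    n = time.shape[0]
    G = gstart.shape[0]
    mx = eta[0]
    for i in range(n):
        if eta[i] > mx:
            mx = eta[i]
    # single exp per observation; all risk-set sums stay on the exp(eta-mx)
    # scale and the shifts cancel in u and w
    e = np.empty(n)
    for i in range(n):
        e[i] = np.exp(eta[i] - mx)
    # suffix sums of exp(eta-mx) -> scaled risk-set S0 per group
    suffix = np.empty(n + 1)
    suffix[n] = 0.0
    for i in range(n - 1, -1, -1):
        suffix[i] = suffix[i + 1] + e[i]
    loglik = 0.0
    # cumulative d/S0 and d/S0^2 on the scaled axis, walked forward over groups
    A = np.zeros(n)
    B = np.zeros(n)
    cumA = 0.0
    cumB = 0.0
    g = 0
    for i in range(n):
        if g < G and i == gstart[g]:
            s0 = suffix[i]
            d = gevents[g]
            loglik += -d * (np.log(s0) + mx)
            cumA += d / s0
            cumB += d / (s0 * s0)
            g += 1
        # gstart is the first index of its tie group, so tied observations
        # (which share the risk set) all receive the updated cumulative sums
        A[i] = cumA
        B[i] = cumB
    u = np.empty(n)
    wdiag = np.empty(n)
    for i in range(n):
        # exp(eta_i) * A_true = e_i * cumA  (the exp(mx) factors cancel)
        ea = e[i] * A[i]
        u[i] = status[i] - ea
        wdiag[i] = ea - e[i] * e[i] * B[i]
        if status[i] == 1:
            loglik += eta[i]
    return loglik, u, wdiag


def grad_hess_eta(order: SurvivalOrder, eta_sorted: np.ndarray):
    """Partial log-likelihood, per-observation score dl/deta and diagonal
    curvature -d2l/deta2, all in time order."""
    return _grad_hess_eta(
        order.time, order.status, order.group_start, order.group_events, eta_sorted
    )


@njit(cache=True)
def cd_sweep(X, w, z, eta, beta, lam_l1, lam_l2, xtx):  # pragma: no cover - numba
    """One cyclic coordinate-descent sweep on the weighted quadratic surrogate.

    Minimizes (1/n) sum_i w_i (z_i - x_i beta)^2 + lam_l1*|beta|_1
    + (lam_l2/2)*|beta|_2^2 in place; returns the largest coefficient change.
    ``eta`` holds X @ beta and is kept in sync.  ``xtx[j] = (2/n) sum w x_ij^2``.
    """
    n, p = X.shape
    max_delta = 0.0
    for j in range(p):
        bj = beta[j]
        # (2/n) sum_i w_i x_ij (z_i - eta_i + x_ij * bj)
        g = 0.0
        for i in range(n):
            g += w[i] * X[i, j] * (z[i] - eta[i])
        g = 2.0 * g / n + xtx[j] * bj
        # soft threshold
        if g > lam_l1:
            num = g - lam_l1
        elif g < -lam_l1:
            num = g + lam_l1
        else:
            num = 0.0
        bnew = num / (xtx[j] + lam_l2)
        diff = bnew - bj
        if diff != 0.0:
            for i in range(n):
                eta[i] += X[i, j] * diff
            beta[j] = bnew
        if abs(diff) > max_delta:
            max_delta = abs(diff)
    return max_delta


@njit(cache=True)
def cd_solve(X, w, z, eta, beta, lam_l1, lam_l2, tol, max_sweeps):  # pragma: no cover
    n, p = X.shape
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        xtx[j] = 2.0 * s / n
    for sweep in range(max_sweeps):
        delta = cd_sweep(X, w, z, eta, beta, lam_l1, lam_l2, xtx)
        if delta < tol:
            return sweep + 1
    return max_sweeps


@njit(cache=True)
def path_solve(
    Xs, time, status, gstart, gevents, alpha, lambdas, tol, max_outer, max_sweeps
):  # pragma: no cover - numba
    """Warm-started elastic-net Cox solve along a decreasing lambda path.

    Outer loop: quadratic (IRLS) approximation of -(2/n) * partial
    log-likelihood at the current linear predictor; inner loop: cyclic
    coordinate descent with soft-thresholding.  All arrays are in time
    order and on the standardized covariate scale.  Returns (B, converged)
    with B of shape (L, p).

    Small ``max_outer``/``max_sweeps`` give a fast path-tracking mode that
    rides the warm starts without fully converging at every lambda
    (appropriate inside cross-validation, where only the location of the
    CV maximum matters); large values give full convergence.
    """
    n, p = Xs.shape
    L = lambdas.shape[0]
    B = np.zeros((L, p))
    beta = np.zeros(p)
    eta = np.zeros(n)
    all_converged = True
    z = np.empty(n)
    xtx = np.empty(p)
    for li in range(L):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        converged = False
        for _ in range(max_outer):
            _, u, w = _grad_hess_eta(time, status, gstart, gevents, eta)
            for i in range(n):
                if w[i] < 1e-12:
                    w[i] = 1e-12  # u is ~0 there too; weight floor only
                z[i] = eta[i] + u[i] / w[i]
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xs[i, j] * Xs[i, j]
                xtx[j] = 2.0 * s / n
            max_move = 0.0
            beta_old = beta.copy()
            for _ in range(max_sweeps):
                delta = cd_sweep(Xs, w, z, eta, beta, l1, l2, xtx)
                if delta < 0.1 * tol:
                    break
            # resync eta against incremental drift
            for i in range(n):
                acc = 0.0
                for j in range(p):
                    acc += Xs[i, j] * beta[j]
                eta[i] = acc
            for j in range(p):
                d = abs(beta[j] - beta_old[j])
                if d > max_move:
                    max_move = d
            if max_move < tol:
                converged = True
                break
        if not converged:
            all_converged = False
        for j in range(p):
            B[li, j] = beta[j]
    return B, all_converged
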