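"""Uniform right-censoring and events-per-variable calibration.

Each individual's follow-up is cut at an independent Uniform(0, delta) draw:
if the simulated event time exceeds the draw the record is censored at the
draw, otherwise the event is observed.  Smaller delta therefore yields fewer
observed events, and delta is the single knob that sets the expected number
of events.  ``calibrate_delta`` solves for the delta that achieves a target
events-per-variable (EPV = expected events / number of candidate
predictors) analytically, by quadrature plus root bracketing, so the solved
delta is deterministic and independent of any simulation seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .synthetic_cohort import CovariateMatrix
from .weibull_truth import WeibullPHModel

__all__ = [
    "SurvivalOutcome",
    "CensoringConfig",
    "apply_uniform_censoring",
    "expected_events",
    "calibrate_delta",
]


@dataclass
class SurvivalOutcome:
    """Per-individual follow-up time (years) and event indicator."""

    time: np.ndarray
    status: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.status = np.asarray(self.status, int)
        if self.time.size == 0:
            raise ValueError("outcome needs at least one record")
        if self.time.shape != self.status.shape:
            raise ValueError("time and status must align")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 (censored) or 1 (event)")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.time, "status": self.status})


@dataclass
class CensoringConfig:
    delta: float
    target_epv: float
    p_candidates: int

    def __post_init__(self):
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        if not self.target_epv > 0:
            raise ValueError("target_epv must be > 0")

    @property
    def target_events(self) -> float:
        return self.target_epv * self.p_candidates


def apply_uniform_censoring(
    times: np.ndarray,
    delta: float,
    seed: int | None = None,
    u: np.ndarray | None = None,
) -> SurvivalOutcome:
    """Censor each time at an independent Uniform(0, delta) draw.

    ``u`` overrides the censoring draws (testing hook); otherwise they come
    from ``default_rng(seed)``.
    """
    times = np.asarray(times, float)
    if not delta > 0:
        raise ValueError("delta must be > 0")
    if u is None:
        u = np.random.default_rng(seed).uniform(0.0, delta, size=times.size)
    else:
        u = np.asarray(u, float)
    event = times <= u
    return SurvivalOutcome(np.where(event, times, u), event.astype(int))


def expected_events(
    model: WeibullPHModel, X: CovariateMatrix | np.ndarray, delta: float
) -> float:
    """Expected observed-event count under Uniform(0, delta) censoring.

    An event is observed iff T_i <= U_i, so its probability is
    E_U[F_i(U)] = (1/delta) * int_0^delta F_i(u) du with
    F_i(u) = 1 - exp(-rate * u^shape * exp(eta_i)).  The integrand summed
    over individuals is evaluated by adaptive quadrature.
    """
    if not delta > 0:
        raise ValueError("delta must be > 0")
    c = model.rate * np.exp(model.linear_predictor(X))

    def total_cdf(u: float) -> float:
        return float(np.sum(-np.expm1(-c * u**model.shape)))

    val, err = quad(total_cdf, 0.0, delta, limit=200)
    if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
        raise ArithmeticError(f"quadrature failed (estimate {val}, error {err})")
    return val / delta


def calibrate_delta(
    model: WeibullPHModel,
    X: CovariateMatrix | np.ndarray,
    target_epv: float,
    p_candidates: int,
) -> CensoringConfig:
    """Solve for the delta achieving ``target_epv * p_candidates`` expected
    events, to within 0.1 event.

    ``expected_events`` is continuous and strictly increasing in delta (its
    derivative is an average of positive densities), so a bracketing root
    search is exact up to tolerance.
    """
    n = X.n if isinstance(X, CovariateMatrix) else np.asarray(X).shape[0]
    target = target_epv * p_candidates
    if target > n:
        raise ValueError(
            f"infeasible target: {target} expected events exceeds cohort size {n}"
        )

    def f(d: float) -> float:
        return expected_events(model, X, d) - target

    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(
                "infeasible target: expected events never reaches the target "
                "within any finite horizon"
            )
    delta = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    achieved = expected_events(model, X, delta)
    if abs(achieved - target) > 0.1:
        raise ArithmeticError(
            f"calibration did not converge: {achieved:.3f} vs target {target:.3f}"
        )
    return CensoringConfig(delta=float(delta), target_epv=target_epv, p_candidates=p_candidates)
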