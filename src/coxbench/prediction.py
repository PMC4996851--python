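"""Survival-probability prediction via the Breslow baseline.

A fitted Cox model only orders individuals; to obtain absolute survival
probabilities the baseline cumulative hazard is estimated by the Breslow
step function

    H0(t) = sum_{event times d <= t} d_count / sum_{i in risk set at d} exp(x_i beta)

and predictions are Shat_i(t) = exp(-H0(t) * exp(x_i beta)).  Before the
first observed event H0 is exactly zero, so every individual is predicted a
survival probability of exactly 1 — the state under which a calibration
slope cannot be computed.  Beyond the last observed event time the last step
value is carried forward (the hazard is never extrapolated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._risk import SurvivalOrder, _risk_sums
from .censoring import SurvivalOutcome

__all__ = [
    "BreslowBaseline",
    "PredictedSurvivalMatrix",
    "breslow_baseline",
    "predict_survival",
]


@dataclass
class BreslowBaseline:
    """Right-continuous step function for the baseline cumulative hazard."""

    times: np.ndarray
    cumhaz: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.cumhaz = np.asarray(self.cumhaz, float)
        if np.any(self.cumhaz < 0) or np.any(np.diff(self.cumhaz) < 0):
            raise ValueError("cumulative hazard must be non-negative, non-decreasing")

    def cumulative_hazard(self, t) -> np.ndarray:
        """H0 at each t: 0 before the first event, last value carried beyond."""
        t = np.atleast_1d(np.asarray(t, float))
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate(([0.0], self.cumhaz))
        return padded[idx]


@dataclass
class PredictedSurvivalMatrix:
    """n x T matrix of predicted survival probabilities with a validity tag.

    validity is ``"constant"`` for a constant-prediction model (all rows
    identical by construction), ``"contains_one"`` when any entry is exactly
    1 (a zero Breslow baseline at that timepoint), otherwise ``"ok"``.
    """

    values: np.ndarray
    timepoints: np.ndarray
    validity: str = "ok"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.timepoints = np.asarray(self.timepoints, float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("survival probabilities must lie in [0, 1]")
        if self.validity not in ("ok", "constant", "contains_one"):
            raise ValueError(f"unknown validity tag {self.validity!r}")

    @property
    def contains_one(self) -> bool:
        return bool(np.any(self.values >= 1.0))

    def save(self, csv_path, meta_path=None) -> None:
        """Write the matrix as CSV (individuals x timepoints) plus an
        optional sidecar JSON carrying the validity tag."""
        import json

        import pandas as pd

        df = pd.DataFrame(
            self.values, columns=[f"t_{t:g}" for t in self.timepoints]
        )
        df.index.name = "individual"
        df.to_csv(csv_path)
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(
                    {"validity": self.validity, "timepoints": self.timepoints.tolist()},
                    fh,
                )


def breslow_baseline(X, outcome: SurvivalOutcome, beta_hat) -> BreslowBaseline:
    """Breslow estimator of the baseline cumulative hazard at ``beta_hat``.

    At beta = 0 this is the Nelson-Aalen estimator.
    """
    V = X.values if hasattr(X, "values") and not isinstance(X, np.ndarray) else np.asarray(X, float)
    beta_hat = np.asarray(beta_hat, float)
    order = SurvivalOrder(outcome.time, outcome.status)
    eta = (V @ beta_hat)[order.order]
    m = eta.max()
    s0 = _risk_sums(order, np.exp(eta - m)) * np.exp(m)
    increments = order.group_events / s0
    return BreslowBaseline(order.event_times, np.cumsum(increments))


def predict_survival(fit, X, timepoints) -> PredictedSurvivalMatrix:
    """Predicted survival probabilities Shat_i(t) = exp(-H0(t) exp(x_i beta))."""
    if fit.baseline is None:
        raise ValueError("fitted model carries no baseline hazard")
    t = np.asarray(timepoints, float)
    H0 = fit.baseline.cumulative_hazard(t)
    eta = fit.linear_predictor(X)
    S = np.exp(-H0[None, :] * np.exp(eta)[:, None])
    if fit.constant_prediction:
        validity = "constant"
    elif np.any(S >= 1.0):
        validity = "contains_one"
    else:
        validity = "ok"
    return PredictedSurvivalMatrix(S, t, validity)
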