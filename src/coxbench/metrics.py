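"""Truth-based comparison statistics.

Because the data-generating model is known, every fitted model can be scored
against the exact survival probabilities it was trying to estimate:

* RMSE(t) = sqrt( (1/n) sum_i (S_i(t) - Shat_i(t))^2 ) — predictive accuracy,
  computable for every fit including degenerate ones.
* Calibration slope alpha1 — the OLS slope of the true log-odds of the event
  on the predicted log-odds, pooled over the evaluation timepoints.  The
  ideal value is 1; alpha1 < 1 indicates overfitting and alpha1 > 1
  under-fitting / over-shrinkage.  It is undefined (NA) when any predicted
  probability equals 0 or 1, or when the predictions are constant.
* Concordance vs truth — the proportion of individual pairs whose predicted
  event-probability ordering matches the true ordering (predicted ties score
  1/2; pairs with tied true probabilities are excluded).  Related to
  Kendall's rank correlation by tau = 2*(concordance - 0.5), and invariant
  to the evaluation timepoint, so it is computed at a single one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prediction import PredictedSurvivalMatrix
from .weibull_truth import TrueSurvivalMatrix

__all__ = [
    "MetricsRecord",
    "rmse",
    "calibration_slope",
    "concordance_true",
    "tau_from_concordance",
    "evaluate_predictions",
]

#: NA reason codes mirroring the usable-replicate accounting rules
NA_CONSTANT = "constant"
NA_CONTAINS_ONE = "contains_one"


@dataclass
class MetricsRecord:
    """Per-replicate scores for one method."""

    method: str
    epv: float
    timepoints: np.ndarray
    rmse_per_timepoint: np.ndarray
    rmse_mean: float
    calibration_slope: float  # NaN when not computable
    slope_na_reason: str | None
    slope_per_timepoint: np.ndarray | None
    concordance: float  # NaN when not computable
    concordance_na_reason: str | None

    @property
    def tau(self) -> float:
        return tau_from_concordance(self.concordance) if np.isfinite(self.concordance) else np.nan

    @property
    def usable(self) -> bool:
        """Counts toward summaries iff slope and concordance are computable."""
        return np.isfinite(self.calibration_slope) and np.isfinite(self.concordance)


def _aligned(S_true, S_hat):
    st = S_true.values if isinstance(S_true, TrueSurvivalMatrix) else np.asarray(S_true, float)
    sh = S_hat.values if isinstance(S_hat, PredictedSurvivalMatrix) else np.asarray(S_hat, float)
    if st.shape != sh.shape:
        raise ValueError(f"shape mismatch: true {st.shape} vs predicted {sh.shape}")
    if isinstance(S_true, TrueSurvivalMatrix) and isinstance(S_hat, PredictedSurvivalMatrix):
        if not np.array_equal(S_true.timepoints, S_hat.timepoints):
            raise ValueError("timepoints of true and predicted matrices differ")
    return st, sh


def rmse(S_true, S_hat) -> np.ndarray:
    """Root mean squared error per timepoint (column)."""
    st, sh = _aligned(S_true, S_hat)
    return np.sqrt(np.mean((st - sh) ** 2, axis=0))


def _log_odds_event(S: np.ndarray) -> np.ndarray:
    """log[(1 - S)/S], the log-odds of the event by time t."""
    return np.log1p(-S) - np.log(S)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


def calibration_slope(S_true, S_hat, per_timepoint: bool = False):
    """OLS slope of true on predicted event log-odds, pooled over timepoints.

    Returns ``(slope, reason)``; slope is NaN with reason ``contains_one``
    when any predicted probability is 0 or 1 (the log-odds diverge) and NaN
    with reason ``constant`` when the predicted log-odds have zero variance.
    With ``per_timepoint=True`` a third element carries one slope per
    timepoint (NaN where undefined).
    """
    st, sh = _aligned(S_true, S_hat)
    # exact 0/1 only: a probability of exactly 1 arises from a zero baseline
    # hazard (timepoint before the first event); near-1 values from extreme
    # linear predictors still have finite, computable log-odds
    bad = (sh >= 1.0) | (sh <= 0.0)
    if bad.any():
        out = (np.nan, NA_CONTAINS_ONE)
        return (*out, np.full(st.shape[1], np.nan)) if per_timepoint else out
    # constant = no between-individual variation at any timepoint; variation
    # across timepoints alone carries no discrimination
    if np.all(sh.max(axis=0) == sh.min(axis=0)):
        out = (np.nan, NA_CONSTANT)
        return (*out, np.full(st.shape[1], np.nan)) if per_timepoint else out
    x = _log_odds_event(sh).ravel()
    y = _log_odds_event(st).ravel()
    slope = _ols_slope(x, y)
    if not per_timepoint:
        return slope, None
    per_t = np.array(
        [
            _ols_slope(_log_odds_event(sh[:, j]), _log_odds_event(st[:, j]))
            if np.ptp(sh[:, j]) > 0
            else np.nan
            for j in range(st.shape[1])
        ]
    )
    return slope, None, per_t


def concordance_true(S_true, S_hat, timepoint_index: int = 0):
    """Pairwise agreement between predicted and true event-probability order.

    Over all unordered pairs with distinct true probabilities: 1 if the
    predicted ordering matches, 1/2 if the predictions are tied, 0 otherwise.
    Returns ``(concordance, reason)``; NA(constant) when all predictions tie.
    """
    st, sh = _aligned(S_true, S_hat)
    s = st[:, timepoint_index]
    p = sh[:, timepoint_index]
    if np.ptp(p) == 0.0:
        return np.nan, NA_CONSTANT
    ds = np.sign(s[:, None] - s[None, :])
    dp = np.sign(p[:, None] - p[None, :])
    iu = np.triu_indices(s.size, k=1)
    ds, dp = ds[iu], dp[iu]
    informative = ds != 0
    n_pairs = int(informative.sum())
    if n_pairs == 0:
        return np.nan, NA_CONSTANT
    agree = (ds[informative] == dp[informative]).sum()
    ties = (dp[informative] == 0).sum()
    return float((agree + 0.5 * ties) / n_pairs), None


def tau_from_concordance(c: float) -> float:
    """Kendall-type rank correlation: tau = 2*(concordance - 0.5)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    return 2.0 * (c - 0.5)


def evaluate_predictions(
    method: str,
    epv: float,
    S_true: TrueSurvivalMatrix,
    S_hat: PredictedSurvivalMatrix,
) -> MetricsRecord:
    """Score one fitted model's predictions against the truth.

    A constant-prediction model gets NA slope and NA concordance; any
    predicted probability of exactly 1 additionally rules out the slope.
    RMSE is computed in every case.
    """
    r = rmse(S_true, S_hat)
    slope, slope_reason, per_t = calibration_slope(S_true, S_hat, per_timepoint=True)
    conc, conc_reason = concordance_true(S_true, S_hat)
    return MetricsRecord(
        method=method,
        epv=epv,
        timepoints=np.asarray(S_true.timepoints, float),
        rmse_per_timepoint=r,
        rmse_mean=float(r.mean()),
        calibration_slope=slope,
        slope_na_reason=slope_reason,
        slope_per_timepoint=per_t,
        concordance=conc,
        concordance_na_reason=conc_reason,
    )
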