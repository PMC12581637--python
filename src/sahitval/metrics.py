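"""Discrimination and calibration statistics for external model validation.

Implements, from first principles, the standard performance battery for a
transported risk model:

* :func:`auc` — concordance probability (Mann-Whitney form, ties count 1/2),
  identical to the trapezoidal area under the empirical ROC curve.
* :func:`auc_ci` — DeLong asymptotic interval by default; seeded percentile
  bootstrap as an alternative.
* :func:`brier` — mean squared error of the predicted probabilities.
* :func:`fit_logistic_1d` — Newton-Raphson maximum likelihood for a
  one-covariate (or intercept-only) logistic model with an optional fixed
  offset. This is the recalibration engine behind the calibration intercept
  ("intercept-in-the-large": slope fixed at 1 by passing the linear
  predictor as offset) and the calibration slope (free intercept and slope
  on the linear predictor).
* :func:`calibration_curve` — equal-frequency (quantile) reliability bins.
* :func:`validation_report` — one model's full metric panel on one cohort.

Sign conventions: calibration intercept > 0 means observed risk exceeds
predicted on average (the model under-estimates); calibration slope < 1
means predictions are too extreme (over-fitting when transported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "MetricError",
    "UndefinedMetricError",
    "EstimateCI",
    "LogisticFit",
    "CalibrationBin",
    "ValidationReport",
    "auc",
    "auc_ci",
    "brier",
    "fit_logistic_1d",
    "recalibration_fit",
    "calibration_intercept",
    "calibration_slope",
    "calibration_curve",
    "estimated_calibration_index",
    "validation_report",
]


class MetricError(Exception):
    """Invalid input to a metric (length mismatch, empty data, ...)."""


class UndefinedMetricError(MetricError):
    """The metric does not exist for this input (e.g. single-class AUC)."""


def _check_xy(p, y) -> Tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.ndim != 1 or y.ndim != 1:
        raise MetricError("inputs must be one-dimensional")
    if p.shape != y.shape:
        raise MetricError(f"length mismatch: {p.shape[0]} probabilities vs {y.shape[0]} outcomes")
    if p.size == 0:
        raise MetricError("empty input")
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise MetricError("outcomes must be binary 0/1")
    return p, y


def auc(probabilities, outcomes) -> float:
    """Concordance probability: over all (event, non-event) pairs, the
    fraction where the event received the higher prediction, ties 1/2."""
    p, y = _check_xy(probabilities, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC undefined: need at least one event and one non-event")
    ranks = stats.rankdata(p)  # midranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(p: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """(AUC, DeLong variance) via the midrank formulation."""
    pos = p[y == 1]
    neg = p[y == 0]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    # structural components (placements)
    v10 = (all_ranks[:m] - pos_ranks) / n           # P(X > Y | X = x_i), ties 1/2
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m     # P(X > Y | Y = y_j)
    a = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return a, s10 / m + s01 / n


def auc_ci(
    probabilities,
    outcomes,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Two-sided AUC confidence interval, clipped to [0, 1].

    ``method="delong"`` (default) uses the DeLong asymptotic variance;
    ``method="bootstrap"`` a percentile bootstrap (``n_boot`` resamples,
    seeded through ``rng``).
    """
    p, y = _check_xy(probabilities, outcomes)
    point = auc(p, y)
    if not 0 < level < 1:
        raise MetricError(f"level={level} outside (0, 1)")
    if method == "delong":
        _, var = _delong_variance(p, y)
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * math.sqrt(max(var, 0.0))
        lo, hi = point - half, point + half
    elif method == "bootstrap":
        if rng is None:
            rng = np.random.default_rng(0)
        n = p.size
        vals = []
        attempts = 0
        while len(vals) < n_boot and attempts < 10 * n_boot:
            attempts += 1
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if yb.min() == yb.max():
                continue  # resample lost one class
            vals.append(auc(p[idx], yb))
        alpha = 1 - level
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    else:
        raise MetricError(f"unknown AUC CI method {method!r}")
    lo = min(max(float(lo), 0.0), point)
    hi = max(min(float(hi), 1.0), point)
    return lo, hi


def brier(probabilities, outcomes) -> float:
    """Brier score: mean (p_i - y_i)^2; 0 is perfect, < 0.25 conventionally useful."""
    p, y = _check_xy(probabilities, outcomes)
    return float(np.mean((p - y) ** 2))


@dataclass
class LogisticFit:
    """Result of a Newton-Raphson logistic MLE fit."""

    coef: np.ndarray          # (intercept,) or (intercept, slope)
    se: np.ndarray            # Wald standard errors from observed information
    cov: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    message: str = ""


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: sum y*eta - log(1+exp(eta))
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic_1d(
    x: Optional[Sequence],
    y,
    offset: Optional[Sequence] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood fit of ``logit P(y=1) = alpha [+ beta*x] + offset``.

    ``x=None`` fits intercept-only. Newton-Raphson starting at 0 with
    step-halving on likelihood decrease; convergence at score norm < ``tol``.
    Perfect separation leaves the likelihood unbounded: the fit is returned
    with ``converged=False`` and a warning message rather than raising.
    """
    y = np.asarray(y).astype(float)
    if y.size == 0:
        raise MetricError("empty input")
    if y.min() == y.max():
        raise MetricError("outcomes must include both classes")
    if x is None:
        X = np.ones((y.size, 1))
    else:
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise MetricError("x/y length mismatch")
        if not np.all(np.isfinite(x)):
            raise MetricError("non-finite covariate")
        X = np.column_stack([np.ones(y.size), x])
    off = np.zeros(y.size) if offset is None else np.asarray(offset, dtype=float)
    if off.shape != y.shape:
        raise MetricError("offset length mismatch")

    theta = np.zeros(X.shape[1])
    ll = _loglik(X @ theta + off, y)
    converged = False
    msg = ""
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ theta + off
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            msg = "singular information matrix (separation or constant covariate)"
            break
        # step-halving if the likelihood worsens beyond rounding noise
        noise = 1e-10 + 1e-12 * abs(ll)
        new = theta + step
        ll_new = _loglik(X @ new + off, y)
        halvings = 0
        while ll_new < ll - noise and halvings < 30:
            step *= 0.5
            new = theta + step
            ll_new = _loglik(X @ new + off, y)
            halvings += 1
        theta, ll = new, ll_new
        if np.abs(theta).max() > 50:
            msg = "coefficients diverging: likely complete separation"
            break
    else:
        msg = msg or f"no convergence in {max_iter} iterations"

    eta = X @ theta + off
    mu = expit(eta)
    # unbounded likelihood: the fit classifies perfectly at extreme
    # coefficients, so the score vanishes without a finite MLE existing
    if converged and np.abs(theta).max() > 10 and np.array_equal(mu > 0.5, y > 0.5):
        converged = False
        msg = "complete separation: likelihood unbounded, coefficients not an MLE"
    w = np.clip(mu * (1 - mu), 1e-300, None)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        se = np.full(X.shape[1], np.nan)
    return LogisticFit(
        coef=theta, se=se, cov=cov, converged=converged, n_iter=it, loglik=ll, message=msg
    )


@dataclass
class EstimateCI:
    """Point estimate with Wald standard error and two-sided CI."""

    value: float
    se: float
    low: float
    high: float

    @classmethod
    def from_fit(cls, fit: LogisticFit, index: int, level: float) -> "EstimateCI":
        z = stats.norm.ppf(0.5 + level / 2)
        v, s = float(fit.coef[index]), float(fit.se[index])
        return cls(value=v, se=s, low=v - z * s, high=v + z * s)


def calibration_intercept(lp, outcomes, level: float = 0.95) -> EstimateCI:
    """Calibration intercept-in-the-large: ``logit P(y=1) = a + offset(LP)``.

    ``a > 0`` means observed risk exceeds predicted on average (the model
    systematically under-estimates); 0 is perfect mean calibration.
    """
    lp = np.asarray(lp, dtype=float)
    fit = fit_logistic_1d(None, outcomes, offset=lp, )
    return EstimateCI.from_fit(fit, 0, level)


def recalibration_fit(lp, outcomes) -> LogisticFit:
    """Joint logistic recalibration ``logit P(y=1) = a + b*LP`` (Cox form)."""
    lp = np.asarray(lp, dtype=float)
    if lp.size and lp.min() == lp.max():
        raise UndefinedMetricError("calibration slope undefined for a constant linear predictor")
    return fit_logistic_1d(lp, outcomes)


def calibration_slope(lp, outcomes, level: float = 0.95) -> EstimateCI:
    """Calibration slope ``b`` from the joint recalibration fit.

    1 is perfect; ``b < 1`` indicates predictions too extreme (over-fitting
    of the source model relative to this cohort).
    """
    return EstimateCI.from_fit(recalibration_fit(lp, outcomes), 1, level)


@dataclass
class CalibrationBin:
    mean_predicted: float
    observed_rate: float
    count: int


def calibration_curve(probabilities, outcomes, n_bins: int = 10) -> List[CalibrationBin]:
    """Equal-frequency reliability curve.

    Quantile bin edges over the predicted probabilities; bins whose edges
    coincide (heavy ties) are merged. Bin counts always partition n.
    """
    p, y = _check_xy(probabilities, outcomes)
    if n_bins < 2:
        raise MetricError("n_bins must be >= 2")
    if n_bins > p.size:
        raise MetricError(f"n_bins={n_bins} exceeds n={p.size}")
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all probabilities identical: one bin
        return [CalibrationBin(float(p.mean()), float(y.mean()), int(p.size))]
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 2)
    bins = []
    for b in range(edges.size - 1):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        bins.append(CalibrationBin(float(p[mask].mean()), float(y[mask].mean()), cnt))
    return bins


def estimated_calibration_index(probabilities, outcomes, n_bins: int = 10) -> float:
    """Mean squared distance between predictions and the interpolated
    quantile calibration curve.

    Non-canonical summary (no standard closed form exists under this name);
    provided for descriptive plots only and deliberately excluded from any
    headline metric panel.
    """
    p, y = _check_xy(probabilities, outcomes)
    bins = calibration_curve(p, y, min(n_bins, max(2, p.size)))
    xs = np.array([b.mean_predicted for b in bins])
    ys = np.array([b.observed_rate for b in bins])
    smoothed = np.interp(p, xs, ys)
    return float(np.mean((p - smoothed) ** 2))


def roc_points(probabilities, outcomes):
    """Empirical ROC curve: (fpr, tpr, threshold) at every distinct
    predicted probability, descending. Trapezoidal area equals :func:`auc`
    when there are no ties; with ties both use the 1/2 convention."""
    p, y = _check_xy(probabilities, outcomes)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("ROC undefined: need both classes")
    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(p_sorted))[0], p_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = distinct + 1 - tps
    fpr = np.r_[0.0, fps / n0]
    tpr = np.r_[0.0, tps / n1]
    thresholds = np.r_[np.inf, p_sorted[distinct]]
    return fpr, tpr, thresholds


@dataclass
class ValidationReport:
    """Full metric panel for one model on one cohort."""

    outcome: str
    tier: str
    cohort_label: str
    n: int
    events: int
    auc: EstimateCI
    cal_intercept: EstimateCI
    cal_slope: EstimateCI
    brier: float
    curve: List[CalibrationBin] = field(default_factory=list)
    level: float = 0.95
    auc_ci_method: str = "delong"

    def row(self) -> dict:
        """Flat dict matching the TSV report layout (unrounded)."""
        return {
            "model": f"{self.outcome}_{self.tier}",
            "tier": self.tier,
            "outcome": self.outcome,
            "cohort": self.cohort_label,
            "n": self.n,
            "events": self.events,
            "auc": self.auc.value,
            "auc_lo": self.auc.low,
            "auc_hi": self.auc.high,
            "cal_int": self.cal_intercept.value,
            "cal_int_lo": self.cal_intercept.low,
            "cal_int_hi": self.cal_intercept.high,
            "cal_slope": self.cal_slope.value,
            "cal_slope_lo": self.cal_slope.low,
            "cal_slope_hi": self.cal_slope.high,
            "brier": self.brier,
        }


def validation_report(
    probabilities,
    lp,
    outcomes,
    outcome: str,
    tier: str,
    cohort_label: str = "full",
    level: float = 0.95,
    n_bins: int = 10,
    auc_ci_method: str = "delong",
    rng: Optional[np.random.Generator] = None,
) -> ValidationReport:
    """Assemble the full panel. Values stay unrounded; rounding happens only
    at serialisation."""
    p, y = _check_xy(probabilities, outcomes)
    lp = np.asarray(lp, dtype=float)
    if lp.shape != p.shape:
        raise MetricError("lp/probability length mismatch")
    point = auc(p, y)
    lo, hi = auc_ci(p, y, level=level, method=auc_ci_method, rng=rng)
    return ValidationReport(
        outcome=outcome,
        tier=tier,
        cohort_label=cohort_label,
        n=int(p.size),
        events=int(np.asarray(y).sum()),
        auc=EstimateCI(value=point, se=float("nan"), low=lo, high=hi),
        cal_intercept=calibration_intercept(lp, y, level=level),
        cal_slope=calibration_slope(lp, y, level=level),
        brier=brier(p, y),
        curve=calibration_curve(p, y, n_bins=min(n_bins, p.size)),
        level=level,
        auc_ci_method=auc_ci_method,
    )
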