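"""Interval estimates for determinant selection.

Three families of estimates are computed, matching what the dual-panel
relevance plot displays:

* item means with very wide (default 99.99%) t-based confidence intervals,
* item-target Pearson correlations with (default 95%) Fisher-z intervals,
* per-target explained variance R^2 with intervals obtained by inverting
  the noncentral-F distribution of the observed F statistic.

Missing data are handled pairwise-complete for means and correlations and
complete-case for R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .data_io import QuestionnaireDataset

DEFAULT_MEAN_LEVEL = 0.9999
DEFAULT_ASSOC_LEVEL = 0.95
DEFAULT_RSQ_LEVEL = 0.95

#: Tolerance for degeneracy / tie comparisons.
EPS = 1e-12
#: Bisection tolerance on the noncentrality parameter in the R^2 interval.
NCP_TOL = 1e-8


class EstimationError(ValueError):
    """Raised when an estimate's preconditions are not met."""


class DegenerateCorrelationError(EstimationError):
    """Raised when |r| = 1 is passed to the Fisher z transform."""


@dataclass(frozen=True)
class EstimateWithCI:
    """A point estimate with a confidence interval at a stated level."""

    point: float
    lower: float
    upper: float
    confidence_level: float
    n_used: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.confidence_level < 1:
            raise EstimationError(f"confidence_level must be in (0,1), got {self.confidence_level}")
        if not self.lower <= self.point + EPS or not self.point <= self.upper + EPS:
            raise EstimationError(
                f"interval [{self.lower}, {self.upper}] does not contain point {self.point}"
            )
        if self.n_used < 1:
            raise EstimationError("n_used must be positive")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class AssociationEstimate:
    """Pearson correlation between one item and one target, with CI."""

    item_id: str
    target_id: str
    estimate: EstimateWithCI

    def __post_init__(self) -> None:
        e = self.estimate
        if not (-1 - EPS <= e.lower <= e.point <= e.upper <= 1 + EPS):
            raise EstimationError("correlation estimate outside [-1, 1]")


@dataclass(frozen=True)
class VarianceExplainedEstimate:
    """R^2 of a target on all determinant items jointly, with CI."""

    target_id: str
    estimate: EstimateWithCI

    def __post_init__(self) -> None:
        e = self.estimate
        if not (0 - EPS <= e.lower <= e.point <= e.upper <= 1 + EPS):
            raise EstimationError("R^2 estimate outside [0, 1]")


# ---------------------------------------------------------------------------
# means


def mean_ci_bounds(
    x: np.ndarray, confidence_level: float = DEFAULT_MEAN_LEVEL, axis: int = -1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized t interval for the mean along ``axis`` (no missing values).

    Returns ``(mean, lower, upper)`` arrays.  This is the computational core
    of :func:`mean_ci`, exposed separately so that simulation studies (e.g.,
    coverage checks over millions of replicate samples) stay vectorized.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 2:
        raise EstimationError(f"need at least 2 observations, got {n}")
    m = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    tq = stats.t.ppf(0.5 + confidence_level / 2.0, n - 1)
    half = tq * sd / np.sqrt(n)
    return m, m - half, m + half


def mean_ci(x: Sequence[float], confidence_level: float = DEFAULT_MEAN_LEVEL) -> EstimateWithCI:
    """Mean of the non-missing values of ``x`` with a t-based interval.

    Zero sample variance yields a zero-width interval flagged degenerate
    rather than an error (constant columns do occur in survey data).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = int(x.size)
    if n < 2:
        raise EstimationError(f"mean_ci needs at least 2 non-missing values, got {n}")
    if x.std(ddof=1) <= EPS:
        m = float(x.mean())
        return EstimateWithCI(m, m, m, confidence_level, n, degenerate=True)
    m, lo, hi = mean_ci_bounds(x, confidence_level)
    return EstimateWithCI(float(m), float(lo), float(hi), confidence_level, n)


# ---------------------------------------------------------------------------
# correlations


def fisher_z(r: float) -> float:
    """Fisher z transform arctanh(r); defined only for |r| < 1."""
    r = float(r)
    if abs(r) >= 1:
        raise DegenerateCorrelationError(f"|r| must be < 1 for the Fisher z transform, got {r}")
    return float(np.arctanh(r))


def inverse_fisher_z(z: float) -> float:
    """Inverse Fisher z transform tanh(z)."""
    return float(np.tanh(z))


def cor_ci_bounds(
    x: np.ndarray, y: np.ndarray, confidence_level: float = DEFAULT_ASSOC_LEVEL
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Pearson r with Fisher-z interval along the last axis.

    ``x`` and ``y`` are equal-shape arrays of complete samples; returns
    ``(r, lower, upper)`` with bounds clamped to [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[-1]
    if n < 4:
        raise EstimationError(f"need at least 4 paired observations, got {n}")
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    r = np.clip((xc * yc).sum(axis=-1) / denom, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    q = stats.norm.ppf(0.5 + confidence_level / 2.0)
    half = q / np.sqrt(n - 3)
    lo = np.tanh(z - half)
    hi = np.tanh(z + half)
    return r, np.clip(lo, -1.0, 1.0), np.clip(hi, -1.0, 1.0)


def cor_ci(
    x: Sequence[float], y: Sequence[float], confidence_level: float = DEFAULT_ASSOC_LEVEL
) -> EstimateWithCI:
    """Pearson correlation over pairwise-complete cases with Fisher-z CI.

    The interval is ``tanh(arctanh(r) +/- z_{1-alpha/2}/sqrt(n-3))`` clamped
    to [-1, 1].  Exactly collinear inputs (|r| = 1) return a zero-width
    interval flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EstimationError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 4:
        raise EstimationError(
            f"cor_ci needs at least 4 pairwise-complete observations, got {n}"
        )
    if x.std(ddof=1) <= EPS or y.std(ddof=1) <= EPS:
        raise EstimationError("zero variance in x or y; correlation undefined")
    r, lo, hi = cor_ci_bounds(x, y, confidence_level)
    r = float(r)
    if abs(r) >= 1 - EPS:
        r = float(np.sign(r))
        return EstimateWithCI(r, r, r, confidence_level, n, degenerate=True)
    return EstimateWithCI(r, float(lo), float(hi), confidence_level, n)


# ---------------------------------------------------------------------------
# explained variance


def _lambda_to_rsq(lam: float, n: int) -> float:
    # Noncentrality lambda = n * f^2 with f^2 = R^2 / (1 - R^2).
    return lam / (lam + n)


def _solve_ncp(f_obs: float, df1: int, df2: int, prob: float) -> float:
    """Noncentrality lambda with ncf.cdf(f_obs; df1, df2, lambda) = prob.

    The cdf is strictly decreasing in lambda.  Returns 0 when even a central
    F leaves less than ``prob`` below f_obs.
    """

    def g(lam: float) -> float:
        return stats.ncf.cdf(f_obs, df1, df2, lam) - prob

    if g(0.0) <= 0:
        return 0.0
    hi = max(8.0, 4.0 * df1 * f_obs)
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - pathological
            raise EstimationError("failed to bracket the noncentrality parameter")
    return float(optimize.brentq(g, 0.0, hi, xtol=NCP_TOL))


def rsq_ci(
    dataset: QuestionnaireDataset,
    determinant_ids: Sequence[str],
    target_id: str,
    confidence_level: float = DEFAULT_RSQ_LEVEL,
) -> VarianceExplainedEstimate:
    """R^2 of ``target_id`` on all ``determinant_ids`` with a CI.

    The point estimate is the ordinary-least-squares R^2 over complete
    cases.  Interval bounds come from inverting the noncentral-F
    distribution of the observed F statistic over its noncentrality
    parameter, mapped back to the R^2 scale via lambda = n R^2/(1 - R^2),
    with the lower bound floored at 0.
    """
    dataset.require_columns(list(determinant_ids) + [target_id])
    if not determinant_ids:
        raise EstimationError("at least one determinant is required")
    cols = {d: dataset.numeric_column(d) for d in determinant_ids}
    yfull = dataset.numeric_column(target_id)
    frame = pd.DataFrame(cols)
    frame["_y"] = yfull
    frame = frame.dropna()
    k = len(determinant_ids)
    n = len(frame)
    if n <= k + 1:
        raise EstimationError(
            f"need more than {k + 1} complete cases for {k} determinants, got {n}"
        )
    X = sm.add_constant(frame[list(determinant_ids)].to_numpy())
    if np.linalg.matrix_rank(X) < k + 1:
        raise EstimationError("rank-deficient predictor matrix (collinear determinants)")
    fit = sm.OLS(frame["_y"].to_numpy(), X).fit()
    r2 = float(fit.rsquared)
    df1, df2 = k, n - k - 1
    alpha = 1.0 - confidence_level
    if r2 >= 1 - EPS:
        est = EstimateWithCI(1.0, 1.0, 1.0, confidence_level, n, degenerate=True)
        return VarianceExplainedEstimate(target_id, est)
    r2 = max(r2, 0.0)
    f_obs = (r2 / df1) / ((1.0 - r2) / df2)
    lam_lower = _solve_ncp(f_obs, df1, df2, 1.0 - alpha / 2.0)
    lam_upper = _solve_ncp(f_obs, df1, df2, alpha / 2.0)
    lo = max(0.0, _lambda_to_rsq(lam_lower, n))
    hi = min(1.0, _lambda_to_rsq(lam_upper, n))
    est = EstimateWithCI(r2, min(lo, r2), max(hi, r2), confidence_level, n)
    return VarianceExplainedEstimate(target_id, est)


# ---------------------------------------------------------------------------
# joint estimation


@dataclass
class EstimationResults:
    """All estimates the relevance plot needs, plus per-item failures."""

    determinant_ids: list[str]
    target_ids: list[str]
    means: dict[str, EstimateWithCI] = field(default_factory=dict)
    associations: list[AssociationEstimate] = field(default_factory=list)
    rsq: dict[str, VarianceExplainedEstimate] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def association(self, item_id: str, target_id: str) -> AssociationEstimate | None:
        for a in self.associations:
            if a.item_id == item_id and a.target_id == target_id:
                return a
        return None

    def associations_for_item(self, item_id: str) -> list[AssociationEstimate]:
        return [a for a in self.associations if a.item_id == item_id]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per estimate (kind, item, target, point, CI, level, n)."""
        rows = []
        for item, est in self.means.items():
            rows.append(("mean", item, "", est))
        for a in self.associations:
            rows.append(("association", a.item_id, a.target_id, a.estimate))
        for target, v in self.rsq.items():
            rows.append(("rsq", "", target, v.estimate))
        return pd.DataFrame(
            [
                {
                    "kind": kind,
                    "item": item,
                    "target": target,
                    "point": e.point,
                    "lower": e.lower,
                    "upper": e.upper,
                    "level": e.confidence_level,
                    "n": e.n_used,
                }
                for kind, item, target, e in rows
            ]
        )


def estimate_all(
    dataset: QuestionnaireDataset,
    determinant_ids: Sequence[str],
    target_ids: Sequence[str] = (),
    conf_means: float = DEFAULT_MEAN_LEVEL,
    conf_assoc: float = DEFAULT_ASSOC_LEVEL,
    conf_rsq: float = DEFAULT_RSQ_LEVEL,
) -> EstimationResults:
    """Compute every estimate the relevance plot displays.

    One mean per determinant at ``conf_means``, one correlation per
    (determinant, target) pair at ``conf_assoc``, and one R^2 per target at
    ``conf_rsq``.  A determinant whose estimation fails (e.g., all missing)
    is recorded in ``failures`` and skipped, never fatal.
    """
    determinant_ids = list(determinant_ids)
    target_ids = list(target_ids)
    dataset.require_columns(determinant_ids + target_ids)
    overlap = sorted(set(determinant_ids) & set(target_ids))
    if overlap:
        raise EstimationError(f"ids appear as both determinant and target: {overlap}")
    if len(set(determinant_ids)) != len(determinant_ids):
        raise EstimationError("duplicate determinant ids")

    res = EstimationResults(determinant_ids, target_ids)
    target_cols = {t: dataset.numeric_column(t) for t in target_ids}
    for item in determinant_ids:
        x = dataset.numeric_column(item)
        try:
            res.means[item] = mean_ci(x, conf_means)
        except EstimationError as exc:
            res.failures[item] = f"mean: {exc}"
            continue
        for t in target_ids:
            try:
                est = cor_ci(x, target_cols[t], conf_assoc)
            except EstimationError as exc:
                res.failures[item] = f"association with {t}: {exc}"
                continue
            res.associations.append(AssociationEstimate(item, t, est))

    usable = [d for d in determinant_ids if d in res.means]
    for t in target_ids:
        if not usable:
            break
        try:
            res.rsq[t] = rsq_ci(dataset, usable, t, conf_rsq)
        except EstimationError as exc:
            res.failures[t] = f"rsq: {exc}"
    return res
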