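"""Evaluation metrics for binding-affinity regression.

Implements the four metrics of the standard DTA evaluation protocol:

* concordance index (CI) — the fraction of comparable affinity pairs whose
  predicted ordering agrees with the observed ordering, with ties in the
  prediction counted as one half;
* mean squared error (MSE);
* Pearson correlation coefficient (R);
* rm² — the external-validation index r² · (1 − √(r² − r0²)), where r0² is
  the squared correlation of the least-squares fit of observed on predicted
  through the origin.  A model is conventionally deemed acceptable when
  rm² ≥ 0.5.

All functions are pure and operate on 1-D array-likes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "step",
    "concordance_index",
    "mse",
    "pearson_r",
    "rm2",
    "MetricsReport",
    "compute_report",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for this input."""


def step(m: float) -> float:
    """Three-case step function h(m): 1 if m > 0, 0.5 if m == 0, 0 if m < 0."""
    if not np.isfinite(m):
        raise ValueError("step() requires a finite argument")
    if m > 0:
        return 1.0
    if m < 0:
        return 0.0
    return 0.5


def _validate_pair(pred, true, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {p.size}")
    if not (np.isfinite(p).all() and np.isfinite(t).all()):
        raise ValueError("non-finite values in input")
    return p, t


def concordance_index(pred, true) -> float:
    """CI = (1/Z) Σ_{δx > δy} h(px − py) over ordered comparable pairs.

    Z is the number of pairs whose true affinities differ; pairs tied in the
    true affinity are not comparable and are excluded.  Ties in the
    prediction contribute h(0) = 0.5.
    """
    p, t = _validate_pair(pred, true)
    # pairwise sign matrices; n is small enough for O(n^2) vectorization here,
    # and callers evaluating large test sets subsample or accept the cost
    dt = t[:, None] - t[None, :]
    dp = p[:, None] - p[None, :]
    comparable = dt > 0  # ordered pairs (x, y) with δx > δy
    z = int(comparable.sum())
    if z == 0:
        raise UndefinedMetricError("all true affinities are tied; CI undefined")
    h = np.where(dp > 0, 1.0, np.where(dp < 0, 0.0, 0.5))
    return float(h[comparable].sum() / z)


def mse(pred, true) -> float:
    """Mean squared error between predictions and observations."""
    p, t = _validate_pair(pred, true, min_n=1)
    return float(np.mean((t - p) ** 2))


def pearson_r(pred, true) -> float:
    """Pearson correlation cov(p, δ) / (σ(p) σ(δ))."""
    p, t = _validate_pair(pred, true)
    sp, st = p.std(), t.std()
    if sp == 0 or st == 0:
        raise UndefinedMetricError("zero variance; Pearson R undefined")
    cov = np.mean((p - p.mean()) * (t - t.mean()))
    return float(cov / (sp * st))


def rm2(pred, true) -> float:
    """rm² = r² (1 − √(r² − r0²)).

    r² is the squared Pearson correlation between observed and predicted
    values; r0² is the squared correlation coefficient of the least-squares
    regression of the observed values on the predicted values constrained
    through the origin (slope k = Σ y·p / Σ p²).  When numerical noise makes
    r² − r0² marginally negative the radicand is clamped at zero.
    """
    p, t = _validate_pair(pred, true)
    r = pearson_r(p, t)
    r2 = r * r
    sum_p2 = float(np.sum(p * p))
    if sum_p2 == 0:
        raise UndefinedMetricError("all predictions zero; origin fit undefined")
    k = float(np.sum(t * p)) / sum_p2
    ss_res = float(np.sum((t - k * p) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedMetricError("zero variance in observations")
    r02 = 1.0 - ss_res / ss_tot
    radicand = r2 - r02
    if radicand < 1e-12:  # noise floor: r0² can exceed r² by rounding error
        if radicand < -1e-9:
            warnings.warn(
                f"r² − r0² = {radicand:.3g} < 0; clamping radicand to zero",
                RuntimeWarning,
                stacklevel=2,
            )
        radicand = 0.0
    return float(r2 * (1.0 - np.sqrt(radicand)))


@dataclass(frozen=True)
class MetricsReport:
    """The four evaluation metrics for one prediction set."""

    ci: float | None
    mse: float
    pearson_r: float | None
    rm2: float | None
    n: int

    @property
    def acceptable(self) -> bool:
        """rm² ≥ 0.5 acceptability flag."""
        return self.rm2 is not None and self.rm2 >= 0.5

    def to_dict(self) -> dict:
        return {
            "ci": self.ci,
            "mse": self.mse,
            "pearson_r": self.pearson_r,
            "rm2": self.rm2,
            "n": self.n,
            "acceptable": self.acceptable,
        }


def compute_report(pred, true) -> MetricsReport:
    """All four metrics; degenerate inputs surface as None fields.

    MSE is always defined for non-empty input; CI, R and rm² can be
    undefined (e.g. constant predictions or constant truths) and are then
    reported as None rather than raising, so that evaluation of a degenerate
    checkpoint still yields a report.
    """
    p = np.asarray(pred, dtype=float).ravel()

    def _try(fn):
        try:
            return fn(pred, true)
        except UndefinedMetricError:
            return None

    return MetricsReport(
        ci=_try(concordance_index),
        mse=mse(pred, true),
        pearson_r=_try(pearson_r),
        rm2=_try(rm2),
        n=int(p.size),
    )
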