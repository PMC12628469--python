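"""ROC machinery for diagnostic markers.

Covers threshold sweeps over the observed marker values, the tie-corrected
Mann-Whitney AUC, DeLong variance and Wald confidence intervals, stratified
bootstrap confidence intervals, and Youden-optimal operating points.

Both test directions are supported: ``lower_positive`` declares a case
test-positive when marker <= t (e.g. OHI for MGMT methylation) and
``higher_positive`` when marker >= t (e.g. TWI).  Candidate thresholds are
the observed marker values themselves, with inclusive boundaries, matching
how clinical cut-offs such as "OHI <= 0.606" are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateLabelsError, EmptyInputError, ValidationError

__all__ = [
    "ROCResult",
    "OperatingPoint",
    "DeLongResult",
    "roc_points",
    "delong_ci",
    "youden_optimal",
    "bootstrap_auc_ci",
    "auc_mann_whitney",
]

DIRECTIONS = ("higher_positive", "lower_positive")


@dataclass(frozen=True)
class OperatingPoint:
    """A single threshold with its sensitivity, specificity and Youden's J."""

    threshold: float
    sens: float
    spec: float

    @property
    def youden(self) -> float:
        return self.sens + self.spec - 1.0


@dataclass(frozen=True)
class ROCResult:
    """Threshold sweep over the observed marker values plus the AUC.

    ``thresholds`` are the sorted distinct marker values; ``sens``/``spec``
    are evaluated with the positivity rule implied by ``direction`` at each
    threshold (inclusive).  ``auc_ci`` is attached by :func:`delong_ci` or
    :func:`bootstrap_auc_ci`; it is ``None`` straight out of
    :func:`roc_points`.
    """

    direction: str
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    auc_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class DeLongResult:
    auc: float
    variance: float
    ci: tuple[float, float]


def _validate(marker, label, direction):
    marker = np.asarray(marker, dtype=float)
    label = np.asarray(label, dtype=bool)
    if marker.size == 0:
        raise EmptyInputError("marker array is empty")
    if marker.shape != label.shape:
        raise ValidationError("marker and label must have equal length")
    if np.any(~np.isfinite(marker)):
        raise ValidationError("marker values must be finite (no missing values)")
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    n_pos = int(label.sum())
    n_neg = int(label.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"need both classes present (got {n_pos} positive, {n_neg} negative)"
        )
    return marker, label, n_pos, n_neg


def auc_mann_whitney(marker, label, direction="higher_positive") -> float:
    """Tie-corrected Mann-Whitney AUC.

    AUC = [#concordant + 0.5 * #tied] / (n_pos * n_neg) over all
    positive-negative pairs, where concordance respects ``direction``.
    """
    marker, label, n_pos, n_neg = _validate(marker, label, direction)
    pos = marker[label]
    neg = marker[~label]
    if direction == "lower_positive":
        pos, neg = -pos, -neg
    # pairwise comparison is fine at cohort scale; keeps ties exact
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0)
    ties = np.count_nonzero(diff == 0)
    return (wins + 0.5 * ties) / (n_pos * n_neg)


def roc_points(marker, label, direction="higher_positive") -> ROCResult:
    """Sensitivity/specificity at every distinct observed marker value.

    For ``lower_positive`` a case is test-positive iff marker <= t; for
    ``higher_positive`` iff marker >= t.  The AUC is the tie-corrected
    Mann-Whitney statistic, which equals the trapezoidal area under the
    empirical ROC polygon.
    """
    marker, label, n_pos, n_neg = _validate(marker, label, direction)
    thresholds = np.unique(marker)
    pos = marker[label]
    neg = marker[~label]
    if direction == "lower_positive":
        sens = np.array([(pos <= t).mean() for t in thresholds])
        spec = np.array([(neg > t).mean() for t in thresholds])
    else:
        sens = np.array([(pos >= t).mean() for t in thresholds])
        spec = np.array([(neg < t).mean() for t in thresholds])
    auc = auc_mann_whitney(marker, label, direction)
    return ROCResult(
        direction=direction,
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _placements(marker, label, direction):
    """DeLong placement values: per-positive and per-negative mean concordance."""
    pos = marker[label]
    neg = marker[~label]
    if direction == "lower_positive":
        pos, neg = -pos, -neg
    diff = pos[:, None] - neg[None, :]
    conc = (diff > 0) + 0.5 * (diff == 0)
    v_pos = conc.mean(axis=1)  # one per positive case
    v_neg = conc.mean(axis=0)  # one per negative case
    return v_pos, v_neg


def delong_ci(marker, label, direction="higher_positive", level=0.95) -> DeLongResult:
    """AUC with DeLong variance and a Wald confidence interval clipped to [0, 1].

    The variance is S_pos/n_pos + S_neg/n_neg with the sample variances of
    the placement values.  Perfect separation gives variance 0 and a
    zero-width interval at the point estimate.
    """
    marker, label, n_pos, n_neg = _validate(marker, label, direction)
    if n_pos < 2 or n_neg < 2:
        raise ValidationError("DeLong variance needs at least 2 cases per class")
    v_pos, v_neg = _placements(marker, label, direction)
    auc = float(v_pos.mean())
    variance = float(np.var(v_pos, ddof=1) / n_pos + np.var(v_neg, ddof=1) / n_neg)
    if variance <= 0.0:
        return DeLongResult(auc, 0.0, (auc, auc))
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variance)
    lo = float(np.clip(auc - half, 0.0, 1.0))
    hi = float(np.clip(auc + half, 0.0, 1.0))
    return DeLongResult(auc, variance, (lo, hi))


def youden_optimal(r: ROCResult) -> OperatingPoint:
    """Observed threshold maximizing Youden's J = sens + spec - 1.

    Ties in J are broken by higher specificity; remaining ties by the less
    inclusive threshold (smaller for ``lower_positive``, larger for
    ``higher_positive``).
    """
    j = r.sens + r.spec - 1.0
    best = None
    order = range(len(r.thresholds))
    if r.direction == "higher_positive":
        order = reversed(list(order))  # larger threshold wins remaining ties
    for i in order:
        cand = (j[i], r.spec[i])
        if best is None or cand > (j[best], r.spec[best]):
            best = i
        elif cand == (j[best], r.spec[best]) and r.direction == "lower_positive":
            if r.thresholds[i] < r.thresholds[best]:
                best = i
    return OperatingPoint(
        threshold=float(r.thresholds[best]),
        sens=float(r.sens[best]),
        spec=float(r.spec[best]),
    )


def bootstrap_auc_ci(
    marker,
    label,
    direction="higher_positive",
    n_boot=2000,
    seed=0,
    level=0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC with stratified case resampling.

    Resampling within each class guarantees both classes are present in every
    replicate; deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    marker, label, n_pos, n_neg = _validate(marker, label, direction)
    pos = marker[label]
    neg = marker[~label]
    if direction == "lower_positive":
        pos, neg = -pos, -neg
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, n_pos, n_pos)]
        q = neg[rng.integers(0, n_neg, n_neg)]
        diff = p[:, None] - q[None, :]
        aucs[b] = (np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / (
            n_pos * n_neg
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(lo), float(hi))
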