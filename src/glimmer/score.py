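"""The GLIMMER score: MGMT dichotomization, scoring, classification, evaluation.

The score assigns one point for a low organ hemoglobin index (OHI <= 0.606)
and one point for a high tissue water index (TWI >= 0.501); a total of >= 1
point predicts MGMT promoter methylation.  The MGMT reference standard is the
mean pyrosequencing methylation percentage dichotomized at <= 8%
(unmethylated).  All boundaries are inclusive exactly as stated.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import nan
from typing import Sequence

import numpy as np

from . import roc
from .errors import DegenerateLabelsError, ValidationError

__all__ = [
    "METHYLATED",
    "UNMETHYLATED",
    "ScoreDefinition",
    "ConfusionCounts",
    "DiagnosticPerformance",
    "dichotomize_mgmt",
    "glimmer_score",
    "classify",
    "evaluate",
    "derive_score_definition",
    "round_half_up",
]

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"


@dataclass(frozen=True)
class ScoreDefinition:
    """Cut-offs defining the two-point score and the MGMT reference rule.

    One point for OHI <= ``ohi_cutoff``, one for TWI >= ``twi_cutoff``;
    predicted methylated when the score reaches ``positive_score_min``.
    ``mgmt_cutoff_pct`` dichotomizes the pyrosequencing percentage
    (unmethylated when <= cutoff).
    """

    ohi_cutoff: float = 0.606
    twi_cutoff: float = 0.501
    positive_score_min: int = 1
    mgmt_cutoff_pct: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ohi_cutoff <= 1.0 and 0.0 <= self.twi_cutoff <= 1.0):
            raise ValidationError("index cut-offs must lie in [0, 1]")
        if self.positive_score_min not in (1, 2):
            raise ValidationError("positive_score_min must be 1 or 2")
        if not (0.0 < self.mgmt_cutoff_pct < 100.0):
            raise ValidationError("mgmt_cutoff_pct must lie in (0, 100)")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with methylated as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValidationError("confusion table must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int) -> float:
    """Ratio with an explicit not-a-value marker for zero denominators."""
    return num / den if den > 0 else nan


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion-matrix-derived diagnostic metrics.

    Undefined ratios (zero denominator, e.g. PPV with no positive
    predictions) are reported as NaN, never silently as 0.  ``display()``
    applies the reporting convention: percentages rounded half-up to one
    decimal, Youden to two decimals; the raw values stay available on the
    object itself.
    """

    counts: ConfusionCounts

    @property
    def sensitivity(self) -> float:
        return _ratio(self.counts.tp, self.counts.tp + self.counts.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.counts.tn, self.counts.tn + self.counts.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.counts.tp, self.counts.tp + self.counts.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.counts.tn, self.counts.tn + self.counts.fn)

    @property
    def accuracy(self) -> float:
        return _ratio(self.counts.tp + self.counts.tn, self.counts.total)

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def display(self) -> dict[str, float]:
        """Rounded presentation values: percentages to 1 dp, Youden to 2 dp."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            v = getattr(self, name)
            out[f"{name}_pct"] = nan if np.isnan(v) else round_half_up(100.0 * v, 1)
        j = self.youden
        out["youden"] = nan if np.isnan(j) else round_half_up(j, 2)
        return out

    def as_dict(self) -> dict:
        c = self.counts
        return {
            "counts": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "youden": self.youden,
            "display": self.display(),
        }


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero at the given decimal place (93.75 -> 93.8)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def dichotomize_mgmt(mean_pct: float, defn: ScoreDefinition = ScoreDefinition()) -> str:
    """Dichotomize a mean pyrosequencing methylation percentage.

    Unmethylated iff mean_pct <= cutoff (default 8%, inclusive), else
    methylated.
    """
    if not (0.0 <= mean_pct <= 100.0):
        raise ValidationError(f"methylation percentage must lie in [0, 100], got {mean_pct}")
    return UNMETHYLATED if mean_pct <= defn.mgmt_cutoff_pct else METHYLATED


def glimmer_score(ohi: float, twi: float, defn: ScoreDefinition = ScoreDefinition()) -> int:
    """Two-point composite score: [OHI <= cutoff] + [TWI >= cutoff].

    Monotone: decreasing OHI or increasing TWI never decreases the score.
    Accepts scalars or arrays (returns an integer array for array input).
    """
    ohi_arr = np.asarray(ohi, dtype=float)
    twi_arr = np.asarray(twi, dtype=float)
    if np.any(~np.isfinite(ohi_arr)) or np.any(~np.isfinite(twi_arr)):
        raise ValidationError("index values must be finite")
    score = (ohi_arr <= defn.ohi_cutoff).astype(int) + (twi_arr >= defn.twi_cutoff).astype(int)
    return int(score) if score.ndim == 0 else score


def classify(score, defn: ScoreDefinition = ScoreDefinition()):
    """Predicted MGMT status from the score: methylated iff score >= positive_score_min."""
    score_arr = np.asarray(score)
    if np.any((score_arr < 0) | (score_arr > 2)):
        raise ValidationError("score values must lie in {0, 1, 2}")
    pred = np.where(score_arr >= defn.positive_score_min, METHYLATED, UNMETHYLATED)
    return str(pred) if pred.ndim == 0 else pred


def evaluate(predicted: Sequence[str], truth: Sequence[str]) -> DiagnosticPerformance:
    """Diagnostic performance of predicted vs true MGMT status (positive = methylated)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValidationError("predicted and truth must be equal-length, non-empty")
    for arr, label in ((predicted, "predicted"), (truth, "truth")):
        bad = set(arr.tolist()) - {METHYLATED, UNMETHYLATED}
        if bad:
            raise ValidationError(f"unrecognized {label} status values: {sorted(bad)}")
    p = predicted == METHYLATED
    t = truth == METHYLATED
    counts = ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )
    return DiagnosticPerformance(counts)


def derive_score_definition(
    ohi, twi, truth, base: ScoreDefinition = ScoreDefinition()
) -> ScoreDefinition:
    """Data-driven cut-offs: Youden-optimal thresholds from per-index ROC sweeps.

    OHI is swept with the lower-positive rule and TWI with the higher-positive
    rule against the dichotomized MGMT truth, mirroring how the printed
    cut-offs were obtained from ROC analysis.
    """
    truth_bool = np.asarray(truth) == METHYLATED
    if truth_bool.all() or not truth_bool.any():
        raise DegenerateLabelsError("cut-off derivation needs both MGMT classes")
    ohi_pt = roc.youden_optimal(roc.roc_points(ohi, truth_bool, "lower_positive"))
    twi_pt = roc.youden_optimal(roc.roc_points(twi, truth_bool, "higher_positive"))
    return ScoreDefinition(
        ohi_cutoff=ohi_pt.threshold,
        twi_cutoff=twi_pt.threshold,
        positive_score_min=base.positive_score_min,
        mgmt_cutoff_pct=base.mgmt_cutoff_pct,
    )
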