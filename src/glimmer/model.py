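"""The GLIMMER analysis as a model/results pair.

:class:`GlimmerModel` is constructed from a cohort table (a validated pandas
DataFrame) and fitting options; :meth:`GlimmerModel.fit` runs the full
analysis chain — MGMT dichotomization, per-index ROC with confidence
intervals, cut-off selection (fixed or Youden-derived), composite scoring
and classification, overall and subgroup diagnostic performance, the
score-level AUC, the two-predictor logistic model, the score-group
comparison of methylation percentages, and exploratory ROC for alternate
molecular labels — and returns a :class:`GlimmerResults` object carrying
every estimate with its uncertainty, a ``summary()`` table and
machine-readable export.

The functional pipeline entry points (:func:`run_full_analysis`,
:func:`apply_subgroup_filter`) are thin wrappers over the model objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata
from typing import Mapping

import numpy as np
import pandas as pd

from . import assoc, roc, score as score_mod
from .errors import (
    ConfigError,
    DegenerateLabelsError,
    EmptySubgroupError,
    ValidationError,
)
from .io import read_cohort, validate_cohort, write_cohort
from .score import (
    METHYLATED,
    UNMETHYLATED,
    DiagnosticPerformance,
    ScoreDefinition,
    derive_score_definition,
    round_half_up,
)

logger = logging.getLogger("glimmer")

__all__ = [
    "GlimmerModel",
    "GlimmerResults",
    "AnalysisConfig",
    "run_full_analysis",
    "apply_subgroup_filter",
    "parse_subgroup_spec",
    "write_report",
]

DEFAULT_SUBGROUP = {"idh_status": "wildtype", "who_grade": "4"}
DEFAULT_DIRECTIONS = {
    "ohi": "lower_positive",
    "nir": "lower_positive",
    "twi": "higher_positive",
    "sto2": "higher_positive",
}
DEFAULT_EXPLORATORY = {"idh_status": "wildtype", "tert_status": "mutant"}


def parse_subgroup_spec(spec) -> dict[str, str]:
    """Parse ``"idh_status=wildtype,who_grade=4"`` into a filter mapping."""
    if spec is None:
        return {}
    if isinstance(spec, Mapping):
        return {str(k): str(v) for k, v in spec.items()}
    out: dict[str, str] = {}
    for clause in str(spec).split(","):
        clause = clause.strip()
        if not clause:
            continue
        if "=" not in clause:
            raise ConfigError(f"subgroup clause {clause!r} must be field=value")
        k, v = clause.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def apply_subgroup_filter(cohort: pd.DataFrame, spec) -> pd.DataFrame:
    """Rows satisfying every equality clause of ``spec``; order preserved.

    Comparison is string-typed so numeric columns (WHO grade) match their
    textual filter values.
    """
    clauses = parse_subgroup_spec(spec)
    mask = pd.Series(True, index=cohort.index)
    for fld, val in clauses.items():
        if fld not in cohort.columns:
            raise ConfigError(f"unknown subgroup filter field {fld!r}")
        mask &= cohort[fld].astype(str) == val
    return cohort.loc[mask]


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run (CLI/config-file twin of the model)."""

    cohort_path: str | None = None
    ohi_cutoff: float | None = None
    twi_cutoff: float | None = None
    derive_cutoffs: bool = False
    mgmt_cutoff_pct: float = 8.0
    positive_score_min: int = 1
    ci_method: str = "delong"
    n_boot: int = 2000
    seed: int = 0
    subgroup: str | Mapping | None = field(default_factory=lambda: dict(DEFAULT_SUBGROUP))
    exploratory_labels: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EXPLORATORY)
    )
    report_json: str | None = None
    report_md: str | None = None


def _roc_block(marker, truth, direction, ci_method, n_boot, seed) -> dict:
    """Per-marker ROC summary: AUC + CI + Youden-optimal operating point."""
    r = roc.roc_points(marker, truth, direction)
    if ci_method == "bootstrap":
        ci = roc.bootstrap_auc_ci(marker, truth, direction, n_boot=n_boot, seed=seed)
    else:
        try:
            ci = roc.delong_ci(marker, truth, direction).ci
        except ValidationError:
            ci = (float("nan"), float("nan"))
    op = roc.youden_optimal(r)
    return {
        "direction": direction,
        "auc": r.auc,
        "auc_ci": list(ci),
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
        "optimal_threshold": op.threshold,
        "optimal_sens": op.sens,
        "optimal_spec": op.spec,
        "optimal_youden": op.youden,
    }


class GlimmerModel:
    """Two-threshold optical-score analysis of a glioma cohort.

    Parameters
    ----------
    cohort
        Cohort table with the documented schema; validated on construction
        (``mgmt_status`` derived from the methylation percentage if absent).
    score_definition
        Fixed cut-offs.  Defaults to the published rule (OHI <= 0.606,
        TWI >= 0.501, score >= 1 positive, MGMT cut 8%); ignored for the two
        index cut-offs when ``fit(derive_cutoffs=True)``.
    subgroup
        Equality-filter specification for the prespecified subgroup
        (default: IDH-wild-type WHO grade 4).
    ci_method
        ``"delong"`` or ``"bootstrap"`` for AUC confidence intervals.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        score_definition: ScoreDefinition | None = None,
        subgroup=None,
        ci_method: str = "delong",
        n_boot: int = 2000,
        seed: int = 0,
        exploratory_labels: Mapping[str, str] | None = None,
    ) -> None:
        if ci_method not in ("delong", "bootstrap"):
            raise ConfigError(f"unknown CI method {ci_method!r}")
        self.score_definition = score_definition or ScoreDefinition()
        self.cohort = validate_cohort(cohort, self.score_definition)
        self.subgroup = DEFAULT_SUBGROUP if subgroup is None else parse_subgroup_spec(subgroup)
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.seed = seed
        self.exploratory_labels = (
            dict(DEFAULT_EXPLORATORY) if exploratory_labels is None else dict(exploratory_labels)
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GlimmerModel":
        defn = kwargs.get("score_definition") or ScoreDefinition()
        return cls(read_cohort(path, defn), **kwargs)

    # ------------------------------------------------------------------

    def fit(self, derive_cutoffs: bool = False) -> "GlimmerResults":
        df = self.cohort
        defn = self.score_definition
        truth_str = df["mgmt_status"].to_numpy()
        truth = truth_str == METHYLATED
        logger.info("cohort: %d cases (%d methylated, %d unmethylated)",
                    len(df), int(truth.sum()), int((~truth).sum()))

        index_roc: dict[str, dict] = {}
        for marker, direction in DEFAULT_DIRECTIONS.items():
            try:
                index_roc[marker] = _roc_block(
                    df[marker].to_numpy(), truth, direction,
                    self.ci_method, self.n_boot, self.seed,
                )
            except DegenerateLabelsError as exc:
                index_roc[marker] = {"error": str(exc)}
        logger.info("per-index ROC complete")

        if derive_cutoffs:
            defn = derive_score_definition(
                df["ohi"].to_numpy(), df["twi"].to_numpy(), truth_str, base=defn
            )
            logger.info("derived cut-offs: OHI <= %.4g, TWI >= %.4g",
                        defn.ohi_cutoff, defn.twi_cutoff)

        scores = score_mod.glimmer_score(df["ohi"].to_numpy(), df["twi"].to_numpy(), defn)
        predicted = score_mod.classify(scores, defn)
        overall = score_mod.evaluate(predicted, truth_str)

        # subgroup re-evaluation; failures degrade gracefully
        subgroup_perf = None
        subgroup_error = None
        sub_n = 0
        try:
            sub = apply_subgroup_filter(df, self.subgroup)
            sub_n = len(sub)
            if sub_n == 0:
                raise EmptySubgroupError(f"subgroup filter {self.subgroup} matched no cases")
            sub_scores = score_mod.glimmer_score(
                sub["ohi"].to_numpy(), sub["twi"].to_numpy(), defn
            )
            sub_pred = score_mod.classify(sub_scores, defn)
            subgroup_perf = score_mod.evaluate(sub_pred, sub["mgmt_status"].to_numpy())
            logger.info("subgroup %s: %d cases", self.subgroup, sub_n)
        except (EmptySubgroupError, ConfigError, DegenerateLabelsError) as exc:
            subgroup_error = str(exc)
            logger.warning("subgroup evaluation skipped: %s", subgroup_error)

        # three-level score treated as an ordinal marker
        try:
            score_auc = roc.auc_mann_whitney(scores, truth, "higher_positive")
            if self.ci_method == "bootstrap":
                score_auc_ci = roc.bootstrap_auc_ci(
                    scores, truth, "higher_positive", n_boot=self.n_boot, seed=self.seed
                )
            else:
                score_auc_ci = roc.delong_ci(scores, truth, "higher_positive").ci
        except (DegenerateLabelsError, ValidationError):
            score_auc, score_auc_ci = float("nan"), (float("nan"), float("nan"))

        subgroup_score_auc = None
        if subgroup_perf is not None:
            try:
                subgroup_score_auc = roc.auc_mann_whitney(
                    sub_scores, sub["mgmt_status"].to_numpy() == METHYLATED, "higher_positive"
                )
            except DegenerateLabelsError:
                pass

        logistic = None
        logistic_error = None
        try:
            logistic = assoc.fit_logistic(
                df["ohi"].to_numpy(), df["twi"].to_numpy(), truth
            )
        except (DegenerateLabelsError, ValidationError) as exc:
            logistic_error = str(exc)

        # methylation % by score group (>= positive_score_min vs below)
        group_hi = df.loc[scores >= defn.positive_score_min, "mgmt_mean_pct"].to_numpy()
        group_lo = df.loc[scores < defn.positive_score_min, "mgmt_mean_pct"].to_numpy()
        score_group_test = None
        if group_hi.size >= 2 and group_lo.size >= 2:
            t, dof, p = assoc.welch_t(group_hi, group_lo)
            score_group_test = {
                "mean_high": float(group_hi.mean()),
                "sd_high": float(group_hi.std(ddof=1)),
                "mean_low": float(group_lo.mean()),
                "sd_low": float(group_lo.std(ddof=1)),
                "n_high": int(group_hi.size),
                "n_low": int(group_lo.size),
                "t": t,
                "df": dof,
                "p": p,
            }

        exploratory: dict[str, dict] = {}
        for label_col, positive_value in self.exploratory_labels.items():
            exploratory[label_col] = self._exploratory_roc(df, label_col, positive_value)

        return GlimmerResults(
            model=self,
            score_definition=defn,
            derived_cutoffs=derive_cutoffs,
            n=len(df),
            n_methylated=int(truth.sum()),
            n_unmethylated=int((~truth).sum()),
            index_roc=index_roc,
            scores=scores,
            predicted=predicted,
            overall=overall,
            subgroup_perf=subgroup_perf,
            subgroup_error=subgroup_error,
            subgroup_n=sub_n,
            score_auc=float(score_auc),
            score_auc_ci=(float(score_auc_ci[0]), float(score_auc_ci[1])),
            subgroup_score_auc=subgroup_score_auc,
            logistic=logistic,
            logistic_error=logistic_error,
            score_group_test=score_group_test,
            exploratory=exploratory,
        )

    def _exploratory_roc(self, df, label_col, positive_value) -> dict:
        """Per-index AUC against an alternate molecular label.

        Cases with unknown label are dropped; each marker's direction is
        auto-oriented to keep the training AUC >= 0.5, and the chosen
        direction is reported alongside.
        """
        known = df[df[label_col].astype(str).isin(["unknown", "nan"]) == False]  # noqa: E712
        label = known[label_col].astype(str) == str(positive_value)
        out: dict[str, object] = {"positive_value": positive_value, "n": int(len(known))}
        if len(known) == 0 or label.all() or not label.any():
            out["error"] = "degenerate or empty label"
            return out
        for marker in DEFAULT_DIRECTIONS:
            auc_hi = roc.auc_mann_whitney(
                known[marker].to_numpy(), label.to_numpy(), "higher_positive"
            )
            direction = "higher_positive" if auc_hi >= 0.5 else "lower_positive"
            out[marker] = {
                "auc": auc_hi if auc_hi >= 0.5 else 1.0 - auc_hi,
                "direction": direction,
            }
        return out


@dataclass
class GlimmerResults:
    """Fitted-analysis container with summary and export helpers.

    All stored metrics are raw (unrounded); the reporting convention
    (percentages to one decimal, AUC-like values to two, round-half-up) is
    applied only in ``summary()`` and the ``display`` blocks of
    ``to_dict()``.
    """

    model: GlimmerModel
    score_definition: ScoreDefinition
    derived_cutoffs: bool
    n: int
    n_methylated: int
    n_unmethylated: int
    index_roc: dict
    scores: np.ndarray
    predicted: np.ndarray
    overall: DiagnosticPerformance
    subgroup_perf: DiagnosticPerformance | None
    subgroup_error: str | None
    subgroup_n: int
    score_auc: float
    score_auc_ci: tuple[float, float]
    subgroup_score_auc: float | None
    logistic: assoc.LogisticModel | None
    logistic_error: str | None
    score_group_test: dict | None
    exploratory: dict

    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        """Machine-readable report; every displayed number appears unrounded here."""
        d = {
            "cohort": {
                "n": self.n,
                "n_methylated": self.n_methylated,
                "n_unmethylated": self.n_unmethylated,
                "prevalence_methylated": self.n_methylated / self.n,
            },
            "score_definition": {
                "ohi_cutoff": self.score_definition.ohi_cutoff,
                "twi_cutoff": self.score_definition.twi_cutoff,
                "positive_score_min": self.score_definition.positive_score_min,
                "mgmt_cutoff_pct": self.score_definition.mgmt_cutoff_pct,
                "derived_from_data": self.derived_cutoffs,
            },
            "index_roc": self.index_roc,
            "overall_performance": self.overall.as_dict(),
            "score_auc": self.score_auc,
            "score_auc_ci": list(self.score_auc_ci),
            "score_auc_display": round_half_up(self.score_auc, 2)
            if np.isfinite(self.score_auc)
            else None,
            "subgroup": {
                "filter": dict(self.model.subgroup),
                "n": self.subgroup_n,
                "performance": self.subgroup_perf.as_dict() if self.subgroup_perf else None,
                "score_auc": self.subgroup_score_auc,
                "error": self.subgroup_error,
            },
            "logistic_model": self.logistic.as_dict() if self.logistic else None,
            "logistic_error": self.logistic_error,
            "score_group_comparison": self.score_group_test,
            "exploratory_roc": self.exploratory,
            "provenance": {
                "package": "glimmer-hsi",
                "version": _package_version(),
                "seed": self.model.seed,
                "ci_method": self.model.ci_method,
                "n_boot": self.model.n_boot,
            },
        }
        return d

    def to_json(self, path=None, timestamp: bool = False) -> str:
        """Serialize the report; the optional timestamp sits outside the
        deterministic portion and is excluded by default."""
        d = self.to_dict()
        if timestamp:
            d["provenance"]["timestamp"] = datetime.now(timezone.utc).isoformat()
        text = json.dumps(d, indent=2, default=_json_default, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        """Human-readable summary table with the display rounding rules."""
        defn = self.score_definition
        lines = [
            "GLIMMER score analysis",
            "=" * 58,
            f"Cases: {self.n} ({self.n_methylated} methylated, "
            f"{self.n_unmethylated} unmethylated; prevalence "
            f"{round_half_up(100 * self.n_methylated / self.n, 1)}%)",
            f"Rule: 1 point if OHI <= {defn.ohi_cutoff:.3f}, "
            f"1 point if TWI >= {defn.twi_cutoff:.3f}; "
            f"score >= {defn.positive_score_min} predicts methylated"
            + ("  [cut-offs derived from data]" if self.derived_cutoffs else ""),
            "",
            "Per-index ROC vs MGMT status",
            "-" * 58,
        ]
        for marker, blk in self.index_roc.items():
            if "error" in blk:
                lines.append(f"  {marker.upper():>5}: {blk['error']}")
                continue
            lo, hi = blk["auc_ci"]
            lines.append(
                f"  {marker.upper():>5}: AUC {round_half_up(blk['auc'], 2):.2f} "
                f"(95% CI {lo:.2f}-{hi:.2f}), optimal cut-off "
                f"{blk['optimal_threshold']:.3f} "
                f"(sens {round_half_up(100 * blk['optimal_sens'], 1)}%, "
                f"spec {round_half_up(100 * blk['optimal_spec'], 1)}%)"
            )
        disp = self.overall.display()
        c = self.overall.counts
        lines += [
            "",
            "Overall GLIMMER performance",
            "-" * 58,
            f"  Confusion: TP {c.tp}  FP {c.fp}  TN {c.tn}  FN {c.fn}",
            f"  Sensitivity {disp['sensitivity_pct']}%  Specificity {disp['specificity_pct']}%",
            f"  PPV {disp['ppv_pct']}%  NPV {disp['npv_pct']}%",
            f"  Accuracy {disp['accuracy_pct']}%  Youden {disp['youden']:.2f}",
            f"  Score AUC {round_half_up(self.score_auc, 2):.2f} "
            f"(95% CI {self.score_auc_ci[0]:.2f}-{self.score_auc_ci[1]:.2f})",
        ]
        if self.subgroup_perf is not None:
            sd = self.subgroup_perf.display()
            sc = self.subgroup_perf.counts
            lines += [
                "",
                f"Subgroup {self.model.subgroup} (n = {self.subgroup_n})",
                "-" * 58,
                f"  Confusion: TP {sc.tp}  FP {sc.fp}  TN {sc.tn}  FN {sc.fn}",
                f"  Sensitivity {sd['sensitivity_pct']}%  Specificity {sd['specificity_pct']}%",
                f"  Accuracy {sd['accuracy_pct']}%  Youden {sd['youden']:.2f}",
            ]
        elif self.subgroup_error:
            lines += ["", f"Subgroup analysis skipped: {self.subgroup_error}"]
        if self.score_group_test:
            g = self.score_group_test
            lines += [
                "",
                "Methylation % by score group",
                "-" * 58,
                f"  score >= {defn.positive_score_min}: "
                f"{round_half_up(g['mean_high'], 1)} ± {round_half_up(g['sd_high'], 1)}% "
                f"(n = {g['n_high']})",
                f"  score <  {defn.positive_score_min}: "
                f"{round_half_up(g['mean_low'], 1)} ± {round_half_up(g['sd_low'], 1)}% "
                f"(n = {g['n_low']})",
                f"  Welch t = {g['t']:.2f}, df = {g['df']:.1f}, "
                + ("p < 0.001" if g["p"] < 0.001 else f"p = {g['p']:.3f}"),
            ]
        if self.logistic is not None:
            m = self.logistic
            lines += [
                "",
                "Logistic model (MGMT ~ OHI + TWI)",
                "-" * 58,
                f"  OHI: beta {m.beta_ohi:+.2f} ± {m.se_ohi:.2f} (p = {m.p_ohi:.3f})",
                f"  TWI: beta {m.beta_twi:+.2f} ± {m.se_twi:.2f} (p = {m.p_twi:.3f})",
                f"  Model AUC {round_half_up(m.model_auc, 2):.2f} "
                f"(95% CI {m.model_auc_ci[0]:.2f}-{m.model_auc_ci[1]:.2f})"
                + ("" if m.converged else "  [quasi-separation flagged]"),
            ]
        for label_col, blk in self.exploratory.items():
            if "error" in blk:
                continue
            lines += ["", f"Exploratory ROC vs {label_col} = {blk['positive_value']}", "-" * 58]
            for marker in DEFAULT_DIRECTIONS:
                sub = blk[marker]
                lines.append(
                    f"  {marker.upper():>5}: AUC {round_half_up(sub['auc'], 2):.2f} "
                    f"({sub['direction']})"
                )
        return "\n".join(lines)

    def to_markdown(self, path=None) -> str:
        text = "```\n" + self.summary() + "\n```\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _package_version() -> str:
    try:
        return metadata.version("glimmer-hsi")
    except metadata.PackageNotFoundError:
        return "unknown"


def run_full_analysis(cfg: AnalysisConfig, cohort: pd.DataFrame | None = None) -> GlimmerResults:
    """Execute the full pipeline from an :class:`AnalysisConfig`.

    ``cohort`` may be passed directly; otherwise it is read from
    ``cfg.cohort_path``.  Reports are written when output paths are set.
    """
    if cohort is None:
        if cfg.cohort_path is None:
            raise ConfigError("either a cohort table or cohort_path is required")
        cohort = read_cohort(cfg.cohort_path)
    defn = ScoreDefinition(
        ohi_cutoff=cfg.ohi_cutoff if cfg.ohi_cutoff is not None else 0.606,
        twi_cutoff=cfg.twi_cutoff if cfg.twi_cutoff is not None else 0.501,
        positive_score_min=cfg.positive_score_min,
        mgmt_cutoff_pct=cfg.mgmt_cutoff_pct,
    )
    model = GlimmerModel(
        cohort,
        score_definition=defn,
        subgroup=cfg.subgroup,
        ci_method=cfg.ci_method,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        exploratory_labels=cfg.exploratory_labels,
    )
    results = model.fit(derive_cutoffs=cfg.derive_cutoffs)
    write_report(results, cfg.report_json, cfg.report_md)
    return results


def write_report(results: GlimmerResults, json_path=None, md_path=None) -> None:
    if json_path:
        results.to_json(json_path)
        logger.info("wrote JSON report to %s", json_path)
    if md_path:
        results.to_markdown(md_path)
        logger.info("wrote Markdown report to %s", md_path)
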