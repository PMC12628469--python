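"""Continuous-variable association analyses.

A two-predictor logistic regression (OHI + TWI) for MGMT methylation with a
DeLong confidence interval on the model AUC, the Welch two-sample t-test for
comparing methylation percentages between score groups, and Fisher's exact
test for categorical contrasts.  The model fit and the classical tests are
delegated to statsmodels/scipy; the surrounding contracts (separation
flagging, named errors, the AUC attachment) are the package's own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from . import roc
from .errors import DegenerateLabelsError, ValidationError

__all__ = ["LogisticModel", "fit_logistic", "welch_t", "fisher_exact"]

SEPARATION_COEF_LIMIT = 25.0


@dataclass(frozen=True)
class LogisticModel:
    """Two-predictor logistic regression summary.

    Coefficients are per-unit-index log-odds; ``se_*`` are Wald standard
    errors from the inverse observed information.  ``model_auc`` is the AUC
    of the fitted probabilities against the truth, with its DeLong CI.
    A fit is flagged ``converged=False`` (quasi-separation) when any
    coefficient magnitude exceeds 25; the coefficients are still reported.
    """

    intercept: float
    beta_ohi: float
    beta_twi: float
    se_intercept: float
    se_ohi: float
    se_twi: float
    z_ohi: float
    z_twi: float
    p_ohi: float
    p_twi: float
    converged: bool
    n_iter: int
    model_auc: float
    model_auc_ci: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "beta_ohi": self.beta_ohi,
            "beta_twi": self.beta_twi,
            "se_intercept": self.se_intercept,
            "se_ohi": self.se_ohi,
            "se_twi": self.se_twi,
            "z_ohi": self.z_ohi,
            "z_twi": self.z_twi,
            "p_ohi": self.p_ohi,
            "p_twi": self.p_twi,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "model_auc": self.model_auc,
            "model_auc_ci": list(self.model_auc_ci),
        }

    def coefficient_report(self) -> str:
        """'est +/- se' lines matching the conventional coefficient format."""
        return (
            f"OHI: beta = {self.beta_ohi:+.2f} ± {self.se_ohi:.2f} (p = {self.p_ohi:.3f})\n"
            f"TWI: beta = {self.beta_twi:+.2f} ± {self.se_twi:.2f} (p = {self.p_twi:.3f})"
        )


def fit_logistic(ohi, twi, truth) -> LogisticModel:
    """Maximum-likelihood logistic fit of MGMT status on OHI and TWI.

    Newton iterations with an intercept; gradient tolerance 1e-8, at most 100
    iterations.  ``truth`` is boolean (or coercible) with methylated = True.
    """
    ohi = np.asarray(ohi, dtype=float)
    twi = np.asarray(twi, dtype=float)
    y = np.asarray(truth, dtype=bool).astype(float)
    if not (ohi.shape == twi.shape == y.shape):
        raise ValidationError("ohi, twi and truth must have equal length")
    if y.size < 3:
        raise ValidationError("logistic fit requires at least 3 cases")
    if y.min() == y.max():
        raise DegenerateLabelsError("logistic fit needs both classes present")
    x = sm.add_constant(np.column_stack([ohi, twi]))
    model = sm.Logit(y, x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings; we flag it ourselves
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
        params = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        zvals = np.asarray(res.tvalues, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        newton_converged = bool(res.mle_retvals.get("converged", False))
        n_iter = int(res.mle_retvals.get("iterations", 0))
        probs = np.asarray(res.predict(x), dtype=float)
    except np.linalg.LinAlgError:
        # complete separation: the information matrix is singular at the
        # Newton iterates; fall back to a quasi-Newton optimum with a
        # pseudo-inverse covariance so estimates can still be reported
        params, se, zvals, pvals, probs, n_iter = _bfgs_fallback(x, y)
        newton_converged = False
    separated = bool(np.any(np.abs(params) > SEPARATION_COEF_LIMIT))
    converged = newton_converged and not separated
    if separated or not newton_converged:
        warnings.warn(
            "quasi-separation detected; coefficient estimates unreliable",
            stacklevel=2,
        )
    dl = roc.delong_ci(probs, y.astype(bool), "higher_positive")
    return LogisticModel(
        intercept=float(params[0]),
        beta_ohi=float(params[1]),
        beta_twi=float(params[2]),
        se_intercept=float(se[0]),
        se_ohi=float(se[1]),
        se_twi=float(se[2]),
        z_ohi=float(zvals[1]),
        z_twi=float(zvals[2]),
        p_ohi=float(pvals[1]),
        p_twi=float(pvals[2]),
        converged=converged,
        n_iter=n_iter,
        model_auc=dl.auc,
        model_auc_ci=dl.ci,
    )


def _bfgs_fallback(x, y):
    """Quasi-Newton logistic fit used when the observed information is singular.

    Minimizes the negative log-likelihood directly and derives standard
    errors from the Moore-Penrose pseudo-inverse of the information matrix;
    under separation these are astronomically large, which is the honest
    answer.
    """
    from scipy.optimize import minimize

    def nll(beta):
        eta = x @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(x @ beta)))
        return x.T @ (p - y)

    opt = minimize(nll, np.zeros(x.shape[1]), jac=grad, method="BFGS",
                   options={"maxiter": 500})
    params = opt.x
    p = 1.0 / (1.0 + np.exp(-(x @ params)))
    w = np.clip(p * (1.0 - p), 1e-300, None)
    info = x.T @ (w[:, None] * x)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return params, se, z, pvals, p, int(opt.nit)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test with Satterthwaite degrees of freedom.

    Returns (t, df, two-sided p).  Chosen over the pooled-variance Student
    test because the score groups' spreads differ markedly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fisher_exact(table, method: str = "point_probability") -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    The default sums hypergeometric probabilities of all same-margin tables
    whose point probability does not exceed the observed one (with a small
    relative tolerance for float ties); ``method='doubling'`` instead doubles
    the smaller one-sided tail (capped at 1).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or np.any(table != np.round(table)):
        raise ValidationError("table must be 2x2 with non-negative integers")
    if table.sum() < 1:
        raise ValidationError("table must contain at least one observation")
    table = table.astype(int)
    if method == "point_probability":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "doubling":
        p_less = stats.fisher_exact(table, alternative="less")[1]
        p_greater = stats.fisher_exact(table, alternative="greater")[1]
        return float(min(1.0, 2.0 * min(p_less, p_greater)))
    raise ValidationError(f"unknown method {method!r}")
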