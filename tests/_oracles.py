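"""Independent oracles shared across test modules.

Each function recomputes a quantity by a route deliberately different from
the implementation it checks: trapezoid geometry for the Mann-Whitney AUC,
exhaustive hypergeometric enumeration for the Fisher exact p-value, and a
direct inverse-logit simulation for logistic-regression recovery.
"""

import numpy as np
from scipy.stats import hypergeom


def trapezoid_auc(r):
    """Area under the empirical ROC polygon by the trapezoid rule."""
    fpr = 1.0 - r.spec
    tpr = r.sens
    pts = sorted(zip(fpr, tpr))
    xs = [0.0] + [p[0] for p in pts] + [1.0]
    ys = [0.0] + [p[1] for p in pts] + [1.0]
    return float(np.trapezoid(ys, xs))


def enumerate_fisher_two_sided(table):
    """Brute-force two-sided p: sum hypergeometric probabilities of all
    same-margin tables whose point probability <= observed (+1e-7 rel tol)."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = hypergeom.pmf(x, n, r1, c1)
        if p_x <= p_obs * (1 + 1e-7):
            total += p_x
    return min(total, 1.0)


def simulate_logistic(n, beta0, beta_ohi, beta_twi, seed):
    """Draw (ohi, twi, y) from a logistic model with known coefficients."""
    rng = np.random.default_rng(seed)
    ohi = rng.uniform(0, 1, n)
    twi = rng.uniform(0, 1, n)
    eta = beta0 + beta_ohi * ohi + beta_twi * twi
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return ohi, twi, y
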