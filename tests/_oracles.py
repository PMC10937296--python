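"""Independent reference implementations used only to check the package.

Each oracle deliberately takes the most direct route — quadrature,
enumeration or a closed form — and shares no code with the implementation
under test.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import special


def agq_binomial_loglik(beta, sigma, X, group_codes, m, n, nodes=25):
    """Adaptive Gauss-Hermite marginal log-likelihood for a binomial
    logit GLMM with a single random-intercept factor.

    Each group's integral over its random effect is centred at the
    conditional mode and scaled by the conditional curvature before
    applying the Gauss-Hermite rule.
    """
    xk, wk = hermgauss(nodes)
    m = np.asarray(m, float)
    n = np.asarray(n, float)
    eta_fix = np.asarray(X) @ np.asarray(beta)
    total = float(
        np.sum(special.gammaln(n + 1) - special.gammaln(m + 1) - special.gammaln(n - m + 1))
    )
    for g in np.unique(group_codes):
        idx = group_codes == g
        ef, mg, ng = eta_fix[idx], m[idx], n[idx]

        def logjoint(u):
            eta = ef + u
            return float(
                np.sum(mg * eta - ng * np.logaddexp(0.0, eta)) - u * u / (2 * sigma**2)
            )

        u, curv = 0.0, None
        for _ in range(200):
            p = special.expit(ef + u)
            g1 = float(np.sum(mg - ng * p)) - u / sigma**2
            curv = -float(np.sum(ng * p * (1 - p))) - 1 / sigma**2
            step = -g1 / curv
            u += step
            if abs(step) < 1e-13:
                break
        sd = 1.0 / np.sqrt(-curv)
        z = u + np.sqrt(2.0) * sd * xk
        logf = np.array([logjoint(zz) for zz in z]) - 0.5 * np.log(2 * np.pi * sigma**2)
        total += float(
            special.logsumexp(np.log(wk) + xk**2 + logf) + np.log(np.sqrt(2.0) * sd)
        )
    return total


def balanced_oneway_ml(y, group_codes):
    """Closed-form ML variance estimates for a balanced one-way layout.

    Within-group contrasts give sigma_e^2 = SSW / (n - g); the group
    means give sigma_b^2 = sum (ybar_g - ybar)^2 / g - sigma_e^2 / k
    (valid at an interior optimum).
    """
    y = np.asarray(y, float)
    codes = np.asarray(group_codes)
    groups = np.unique(codes)
    g = len(groups)
    k = len(y) // g
    means = np.array([y[codes == c].mean() for c in groups])
    ssw = float(sum(((y[codes == c] - y[codes == c].mean()) ** 2).sum() for c in groups))
    s2e = ssw / (len(y) - g)
    s2b = float(((means - means.mean()) ** 2).sum()) / g - s2e / k
    return s2b, s2e


def bh_stepup_bruteforce(p):
    """BH q-values straight from the step-up definition (no NaNs)."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        # q_i = min over all thresholds t >= p_i of t * m / #(p <= t)
        candidates = p[p >= p[i]]
        q[i] = min(min(t * m / (p <= t).sum() for t in candidates), 1.0)
    return q


def hdi_bruteforce(values, mass):
    """Shortest window by exhaustive search over all sorted windows."""
    s = np.sort(np.asarray(values, float))
    k = int(np.ceil(mass * len(s)))
    best = None
    for i in range(len(s) - k + 1):
        width = s[i + k - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + k - 1])
    return best[1], best[2]


def spearman_bruteforce(x, y):
    """rho = 1 - 6 sum d^2 / (n (n^2-1)) for untied data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    d2 = float(((rx - ry) ** 2).sum())
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def annotate_bruteforce(pos, gene_windows, priority):
    """Winning class for one position by a linear scan over all windows.

    ``gene_windows``: list of (class, start, end, gene_id) 1-based
    inclusive intervals.  Returns the highest-priority class that
    contains the position, or None.
    """
    hits = [cls for cls, s, e, _ in gene_windows if s <= pos <= e]
    for cls in priority:
        if cls in hits:
            return cls
    return None
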