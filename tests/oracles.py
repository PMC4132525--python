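"""Independent reference computations used to validate the package.

Everything here is deliberately naive — explicit loops, literal
formulas, generic quadrature — and shares no code with the
implementation under test.
"""
from __future__ import annotations

import numpy as np
from scipy import integrate, stats
from scipy.special import expit


def brute_force_pair_H(X: np.ndarray, i: int, j: int) -> float:
    """H_ij by explicitly counting Guttman errors row by row."""
    n = len(X)
    p = X.mean(axis=0)
    # harder item = lower popularity; ties to the lower index
    if (p[i] < p[j]) or (p[i] == p[j] and i < j):
        h, e = i, j
    else:
        h, e = j, i
    F = sum(1 for row in X if row[h] == 1 and row[e] == 0)
    E = n * p[h] * (1.0 - p[e])
    return 1.0 - F / E


def covariance_form_pair_H(X: np.ndarray, i: int, j: int) -> float:
    """H_ij as population covariance over its maximum under a perfect
    Guttman pattern."""
    p = X.mean(axis=0)
    cov = np.mean(X[:, i] * X[:, j]) - p[i] * p[j]
    p_h, p_e = (p[i], p[j]) if (p[i] < p[j]) or (p[i] == p[j] and i < j) else (p[j], p[i])
    return cov / (p_h * (1.0 - p_e))


def brute_force_scale_H(X: np.ndarray) -> float:
    """Scale H from summed observed and expected Guttman error counts."""
    n, k = X.shape
    p = X.mean(axis=0)
    F_sum = E_sum = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            if (p[i] < p[j]) or (p[i] == p[j] and i < j):
                h, e = i, j
            else:
                h, e = j, i
            F_sum += sum(1 for row in X if row[h] == 1 and row[e] == 0)
            E_sum += n * p[h] * (1.0 - p[e])
    return 1.0 - F_sum / E_sum


def brute_force_item_H(X: np.ndarray, i: int) -> float:
    n, k = X.shape
    p = X.mean(axis=0)
    F_sum = E_sum = 0.0
    for j in range(k):
        if j == i:
            continue
        if (p[i] < p[j]) or (p[i] == p[j] and i < j):
            h, e = i, j
        else:
            h, e = j, i
        F_sum += sum(1 for row in X if row[h] == 1 and row[e] == 0)
        E_sum += n * p[h] * (1.0 - p[e])
    return 1.0 - F_sum / E_sum


def quad_popularity(a: float, b: float) -> float:
    """Marginal 2PL item popularity by adaptive quadrature over N(0,1)."""
    val, _ = integrate.quad(
        lambda t: expit(a * (t - b)) * stats.norm.pdf(t), -np.inf, np.inf
    )
    return val


def quad_item_cross(a1, b1, a2, b2) -> float:
    """E[P_1(theta) P_2(theta)] by quadrature."""
    val, _ = integrate.quad(
        lambda t: expit(a1 * (t - b1)) * expit(a2 * (t - b2)) * stats.norm.pdf(t),
        -np.inf,
        np.inf,
    )
    return val


def quad_item_theta_cov(a, b) -> float:
    """cov(X_i, theta) = E[theta P_i(theta)] by quadrature."""
    val, _ = integrate.quad(
        lambda t: t * expit(a * (t - b)) * stats.norm.pdf(t), -np.inf, np.inf
    )
    return val


def model_corr_sum_logexp(item_params, lam, sigma) -> float:
    """Model-implied Pearson corr between the item sum score and log
    expenditure (log E = mu + lam*theta + sigma*eps)."""
    ps = [quad_popularity(a, b) for a, b in item_params]
    cov_s_theta = sum(quad_item_theta_cov(a, b) for a, b in item_params)
    var_s = sum(p * (1 - p) for p in ps)
    k = len(item_params)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            a1, b1 = item_params[i]
            a2, b2 = item_params[j]
            var_s += quad_item_cross(a1, b1, a2, b2) - ps[i] * ps[j]
    var_logexp = lam**2 + sigma**2
    return lam * cov_s_theta / np.sqrt(var_s * var_logexp)


def model_tetrachoric(a1, b1, a2, b2, grid=4001) -> float:
    """True tetrachoric correlation implied by a 2PL pair: the latent
    bivariate-normal correlation whose orthant probabilities match the
    model's cell probabilities, solved on the observed margins."""
    from scipy.optimize import brentq
    from scipy.stats import multivariate_normal, norm

    p1 = quad_popularity(a1, b1)
    p2 = quad_popularity(a2, b2)
    p11 = quad_item_cross(a1, b1, a2, b2)
    t1, t2 = norm.ppf(1 - p1), norm.ppf(1 - p2)

    def f(rho):
        mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        # P(X > t1, Y > t2)
        both = 1 - norm.cdf(t1) - norm.cdf(t2) + mvn.cdf([t1, t2])
        return both - p11

    return brentq(f, -0.999, 0.999, xtol=1e-8)


def greedy_merge_groups(rest_scores: np.ndarray, minsize: int):
    """Reference rest-score grouping: merge adjacent score values low to
    high until each group reaches minsize; fold an undersized tail into
    the last group.  Returns a list of sets of rest-score values."""
    values = sorted(set(int(r) for r in rest_scores))
    counts = {v: int(np.sum(rest_scores == v)) for v in values}
    groups, current, total = [], [], 0
    for v in values:
        current.append(v)
        total += counts[v]
        if total >= minsize:
            groups.append(current)
            current, total = [], 0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    return [set(g) for g in groups]


def cronbach_oracle(X: np.ndarray, weights: np.ndarray) -> float:
    """Spreadsheet-style term-by-term Cronbach's alpha of weighted items."""
    n, k = X.shape
    Y = np.array([[w * x for w, x in zip(weights, row)] for row in X])
    item_vars = []
    for col in range(k):
        y = Y[:, col]
        mean = sum(y) / n
        item_vars.append(sum((v - mean) ** 2 for v in y) / (n - 1))
    totals = [sum(row) for row in Y]
    mt = sum(totals) / n
    var_total = sum((t - mt) ** 2 for t in totals) / (n - 1)
    return (k / (k - 1)) * (1.0 - sum(item_vars) / var_total)
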