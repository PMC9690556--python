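"""Independent oracles used by the tests.

These deliberately re-derive quantities through a different route than the
package (plain-numpy IRLS, closed-form 2x2 odds ratios, brute-force greedy
matching, cell-frequency plug-in) so that agreement is informative.
"""

import numpy as np


def irls_logistic(X, y, tol=1e-12, max_iter=100):
    """Plain Newton/IRLS logistic regression with intercept.

    Returns the coefficient vector (intercept first).
    """
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def or_2x2(a, b, c, d):
    """Odds ratio of a 2x2 table: (treated-event, treated-nonevent,
    control-event, control-nonevent)."""
    return (a * d) / (b * c)


def greedy_match(logit_ps, z, caliper):
    """Reference greedy 1:1 matcher: treated in descending ps, nearest
    available control, ties by index.  Quadratic and readable."""
    z = np.asarray(z) == 1
    treated = sorted(np.flatnonzero(z), key=lambda i: (-logit_ps[i], i))
    controls = list(np.flatnonzero(~z))
    pairs = []
    for t in treated:
        best, best_d = None, np.inf
        for c in controls:
            d = abs(logit_ps[c] - logit_ps[t])
            if d < best_d - 1e-15:
                best, best_d = c, d
        if best is not None and best_d <= caliper:
            pairs.append((t, best))
            controls.remove(best)
    return pairs


def plugin_mor_saturated(w, z, y):
    """Nonparametric plug-in marginal OR for one binary covariate:
    p_a = sum_w P(W=w) * P(Y=1 | Z=a, W=w), by direct cell frequencies."""
    w = np.asarray(w)
    z = np.asarray(z)
    y = np.asarray(y, dtype=float)
    p = {a: 0.0 for a in (0, 1)}
    for wv in (0, 1):
        pw = np.mean(w == wv)
        for a in (0, 1):
            cell = (w == wv) & (z == a)
            p[a] += pw * y[cell].mean()
    odds = lambda q: q / (1 - q)
    return odds(p[1]) / odds(p[0]), p[1], p[0]


def iptw_two_stratum(pw1, e0, e1, r0z0, r0z1, r1z0, r1z1):
    """Closed-form IPTW marginal OR for a two-stratum population.

    pw1: P(W=1); e_w: P(Z=1|W=w); r_wz: P(Y=1|W=w,Z=z).  Horvitz-Thompson
    weighting recovers p_a = sum_w P(W=w) r_{w,a} exactly.
    """
    p1 = (1 - pw1) * r0z1 + pw1 * r1z1
    p0 = (1 - pw1) * r0z0 + pw1 * r1z0
    return (p1 / (1 - p1)) / (p0 / (1 - p0))
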