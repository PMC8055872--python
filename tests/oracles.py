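"""Independent brute-force reference implementations used only by tests.

These deliberately use naive loops / explicit histograms so they share no
code path with the package implementations they check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def sampen_bruteforce(x, m: int, r: float):
    """Exhaustive O(N^2) SampEn: ordered pair counts over templates
    i = 1..N-m at lengths m and m+1, Chebyshev distance, strict < r.

    Returns (h, B, A) with h = -ln(A/B), NaN if either count is zero.
    """
    x = [float(v) for v in x]
    n = len(x)
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            dm = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if dm < r:
                b += 1
                if max(dm, abs(x[i + m] - x[j + m])) < r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan"), b, a
    return -math.log(a / b), b, a


def te_bruteforce(sx, sy, tau: int, dx: int, dy: int):
    """Plug-in transfer entropy X->Y by materializing the full joint
    histogram over (y_{t+tau}, y-past tuple, x-past tuple)."""
    sx = [int(v) for v in sx]
    sy = [int(v) for v in sy]
    L = len(sx)
    t0 = (max(dx, dy) - 1) * tau
    configs = []
    for t in range(t0, L - tau):
        yp = tuple(sy[t - k * tau] for k in range(dy))
        xp = tuple(sx[t - k * tau] for k in range(dx))
        configs.append((sy[t + tau], yp, xp))
    n = len(configs)
    joint = Counter(configs)
    c_yp_xp = Counter((yp, xp) for _, yp, xp in configs)
    c_yf_yp = Counter((yf, yp) for yf, yp, _ in configs)
    c_yp = Counter(yp for _, yp, _ in configs)
    te = 0.0
    for (yf, yp, xp), cnt in joint.items():
        p = cnt / n
        cond_full = cnt / c_yp_xp[(yp, xp)]
        cond_y = c_yf_yp[(yf, yp)] / c_yp[yp]
        te += p * math.log(cond_full / cond_y)
    return te


def auc_mannwhitney(scores, labels):
    """AUC as the Mann-Whitney pair statistic: (concordant + ties/2) /
    (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1.0
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def ancova_lstsq(values, group, age):
    """Extra-sum-of-squares ANCOVA via normal equations / lstsq only.

    Returns (F, eta_sq, dfn, dfd) for the group indicator in
    value ~ 1 + group + age.
    """
    y = np.asarray(values, float)
    g = np.asarray([1.0 if v == sorted(set(group))[1] else 0.0 for v in group])
    a = np.asarray(age, float)
    n = len(y)
    X_full = np.column_stack([np.ones(n), g, a])
    X_red = np.column_stack([np.ones(n), a])
    rss = lambda X: float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
    rss_full, rss_red = rss(X_full), rss(X_red)
    ss_group = rss_red - rss_full
    dfd = n - X_full.shape[1]
    F = (ss_group / 1.0) / (rss_full / dfd)
    eta = ss_group / (ss_group + rss_full)
    return F, eta, 1, dfd
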