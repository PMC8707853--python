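"""Independent brute-force oracles used by the test suite.

Every oracle here is written with explicit loops / from-first-principles
linear algebra, deliberately sharing no code with the package paths it
checks.
"""

import numpy as np


def nipals_pls1(X, y, n_factors):
    """Plain NIPALS PLS1 with explicit loops; returns a prediction closure."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    ws, ps, qs = [], [], []
    for _ in range(n_factors):
        w = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            w[j] = float(np.dot(Xc[:, j], yc))
        w = w / np.sqrt(np.sum(w ** 2))
        t = Xc @ w
        tt = float(np.dot(t, t))
        p = Xc.T @ t / tt
        q = float(np.dot(yc, t) / tt)
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
        ws.append(w)
        ps.append(p)
        qs.append(q)

    def predict(X_new):
        Xn = np.array(X_new, dtype=float) - x_mean
        out = np.full(Xn.shape[0], y_mean)
        for w, p, q in zip(ws, ps, qs):
            t = Xn @ w
            out = out + q * t
            Xn = Xn - np.outer(t, p)
        return out

    return predict


def math_code_loops(spectrum, wavelengths, code):
    """Literal step-by-step smoothing/gap-derivative pipeline on one spectrum."""
    d, g, s1, s2 = code
    x = list(map(float, spectrum))
    wl = list(map(float, wavelengths))

    def smooth(vals, wls, s):
        if s == 1:
            return list(vals), list(wls)
        out_v, out_w = [], []
        for i in range(len(vals) - s + 1):
            out_v.append(sum(vals[i:i + s]) / s)
            out_w.append(sum(wls[i:i + s]) / s)
        return out_v, out_w

    x, wl = smooth(x, wl, s1)
    for _ in range(d):
        nx, nw = [], []
        for i in range(len(x) - g):
            nx.append(x[i + g] - x[i])
            nw.append((wl[i + g] + wl[i]) / 2.0)
        x, wl = nx, nw
    x, wl = smooth(x, wl, s2)
    return np.array(x), np.array(wl)


def mahalanobis_sq(scores):
    """Per-row squared Mahalanobis distance via explicit inverse."""
    S = np.array(scores, dtype=float)
    mu = S.mean(axis=0)
    Sc = S - mu
    cov = Sc.T @ Sc / (S.shape[0] - 1)
    inv = np.linalg.inv(cov)
    return np.array([row @ inv @ row for row in Sc])


def ols_fit_line(x, ref):
    """Normal-equations solve of x ≈ a + b*ref over channels."""
    A = np.column_stack([np.ones(len(ref)), ref])
    coef = np.linalg.solve(A.T @ A, A.T @ np.asarray(x, float))
    return float(coef[0]), float(coef[1])


def kruskal_h(groups):
    """Brute-force Kruskal-Wallis H with tie correction."""
    all_vals = np.concatenate(groups)
    order = np.argsort(all_vals, kind="mergesort")
    ranks = np.empty(len(all_vals))
    sorted_vals = all_vals[order]
    i = 0
    pos = 1
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg_rank = (pos + pos + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg_rank
        pos += j - i + 1
        i = j + 1
    n = len(all_vals)
    h = 0.0
    start = 0
    for grp in groups:
        r = ranks[start:start + len(grp)]
        h += r.sum() ** 2 / len(grp)
        start += len(grp)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    correction = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / correction
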