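"""Independent reference implementations used only to check the package.

These deliberately share no code with nmrfinger: the PLS oracle is a literal
NIPALS transcription, Q2 is the untruncated textbook formula, and window
integrals use numpy's trapezoid directly on the raw grid.
"""

import numpy as np


def nipals_pls1_scores(X_train, y_train, X_new, max_iter=500, tol=1e-14):
    """One-component PLS1 regression predictions by the NIPALS recipe.

    Mean-centres X and y on the training data, iterates the NIPALS update
    (which converges immediately for a single y-column), and predicts
    y for X_new via the regression coefficient b = w (p'w)^-1 q.
    """
    X = np.asarray(X_train, float)
    y = np.asarray(y_train, float).ravel()
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    u = yc.copy()
    w = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w_new = Xc.T @ u / (u @ u)
        w_new /= np.linalg.norm(w_new)
        t = Xc @ w_new
        q = yc @ t / (t @ t)
        u_new = yc * q / (q * q)
        if np.linalg.norm(w_new - w) < tol:
            w = w_new
            break
        w, u = w_new, u_new
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    q = yc @ t / (t @ t)
    b = w / (p @ w) * q
    return (np.asarray(X_new, float) - xm) @ b + ym


def plain_q2(y, yhat):
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    return 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)


def trapezoid_window_integral(ppm, intensity, lo, hi):
    """Integral of intensity over [lo, hi] ppm on an ascending copy of the grid."""
    ppm = np.asarray(ppm, float)
    intensity = np.asarray(intensity, float)
    if ppm[0] > ppm[-1]:
        ppm, intensity = ppm[::-1], intensity[::-1]
    grid = np.linspace(lo, hi, 4001)
    return np.trapezoid(np.interp(grid, ppm, intensity), grid)


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj
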