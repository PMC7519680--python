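"""Central-difference gradient and Hessian helpers.

Step sizes scale with the magnitude of each coordinate; the Hessian is
symmetrized.  Accuracy is adequate for Wald standard errors on a logit
scale (relative error ~1e-6 for smooth likelihoods).
"""

from __future__ import annotations

import numpy as np


def gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * (1.0 + abs(x[i]))
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    # diagonal
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        H[i, i] = (f(x + e) - 2 * f0 + f(x - e)) / h[i] ** 2
    # off-diagonal
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H
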