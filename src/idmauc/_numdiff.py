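"""Shared numerical-derivative helpers."""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np


def numerical_covariance(
    neg_loglik: Callable[[np.ndarray], float], theta: np.ndarray, step: float = 1e-4
) -> Optional[np.ndarray]:
    """Inverse central-difference Hessian of a negative log-likelihood.

    ``step`` is relative (scaled by max(1, |theta_i|)).  Returns the
    pseudo-inverse so that flat directions yield large but finite
    variances instead of failing outright.
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    H = np.zeros((p, p))
    h = step * np.maximum(1.0, np.abs(theta))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                neg_loglik(theta + ei + ej)
                - neg_loglik(theta + ei - ej)
                - neg_loglik(theta - ei + ej)
                + neg_loglik(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        return np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return None
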