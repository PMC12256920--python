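"""Numba kernel for the coordinate-ascent sweep.

One kernel source covers all execution modes: the CSR row structure passed
in decides whether rows hold all neighbors (symmetric mode) or only the
right-adjacent run (triangular mode), and ``inv_s`` folds
dequantize-on-the-fly into the inner product (``inv_s = 1.0`` when the
data are already floats).  Numba specializes per dtype, so the same code
runs the float64, float32, and quantized paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_range(indptr, indices, data, inv_s, bhat, n_per_variant,
                include, q, gamma, mu, eta, s2, lam,
                pi, sigma_b2, sigma_e2,
                lo, hi, bcast_lo, bcast_hi):
    """Serially update variants ``lo .. hi-1`` in ascending order.

    Each update recomputes (s2, mu, gamma, eta) for variant j from the
    current q_j, then broadcasts the change in eta_j to the q of every
    stored neighbor whose index falls in [bcast_lo, bcast_hi).  Restricting
    the broadcast window emulates chunked (parallel) execution, where
    cross-chunk information is one epoch stale.
    """
    log_odds = np.log(pi / (1.0 - pi))
    for j in range(lo, hi):
        if not include[j]:
            continue
        nj = n_per_variant[j]
        s2_j = sigma_e2 / (nj * (1.0 + lam[j]) + sigma_e2 / sigma_b2)
        mu_j = (nj * s2_j / sigma_e2) * (bhat[j] - q[j])
        logit = log_odds + 0.5 * np.log(s2_j / sigma_b2) \
            + mu_j * mu_j / (2.0 * s2_j)
        if logit > 30.0:
            gamma_j = 1.0
        elif logit < -30.0:
            gamma_j = np.exp(logit)
        else:
            gamma_j = 1.0 / (1.0 + np.exp(-logit))
        eta_new = gamma_j * mu_j
        d = eta_new - eta[j]
        s2[j] = s2_j
        mu[j] = mu_j
        gamma[j] = gamma_j
        eta[j] = eta_new
        if d != 0.0:
            for ptr in range(indptr[j], indptr[j + 1]):
                k = indices[ptr]
                if bcast_lo <= k < bcast_hi and k != j:
                    q[k] += data[ptr] * inv_s * d
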