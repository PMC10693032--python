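"""Shared test utilities: independent oracles and small conveniences."""

from __future__ import annotations

import numpy as np

from placomp.preprocess import iqr_standardize

TRIMESTERS = ("pm25_t1", "pm25_t2", "pm25_t3")


def standardize_exposures(cohort):
    """Return a copy of the cohort with IQR-standardized exposures."""
    out = cohort.copy()
    for tri in TRIMESTERS:
        out[tri], _ = iqr_standardize(out[tri].to_numpy())
    return out


def grid_projection_oracle(R: np.ndarray, b: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Exhaustive simplex grid search for min ||b - R w||^2, w >= 0, sum <= 1.

    Brute-force oracle for K in {2, 3}, vectorized through the Gram form
    of the objective. Completely independent of the QP solver under test.
    """
    K = R.shape[1]
    G = R.T @ R
    c = R.T @ b
    m = int(round(1.0 / step))
    grid = np.arange(m + 1) * step
    if K == 2:
        W1, W2 = np.meshgrid(grid, grid, indexing="ij")
        obj = (
            G[0, 0] * W1 ** 2 + 2 * G[0, 1] * W1 * W2 + G[1, 1] * W2 ** 2
            - 2 * (c[0] * W1 + c[1] * W2)
        )
        obj = np.where(W1 + W2 <= 1.0 + 1e-12, obj, np.inf)
        i = np.unravel_index(np.argmin(obj), obj.shape)
        return np.array([W1[i], W2[i]])
    if K == 3:
        W2, W3 = np.meshgrid(grid, grid, indexing="ij")
        feas23 = W2 + W3
        q = (
            G[1, 1] * W2 ** 2 + 2 * G[1, 2] * W2 * W3 + G[2, 2] * W3 ** 2
            - 2 * (c[1] * W2 + c[2] * W3)
        )
        lin = G[0, 1] * W2 + G[0, 2] * W3 - c[0]
        best_obj, best_w = np.inf, None
        for w1 in grid:
            obj = np.where(
                feas23 <= 1.0 - w1 + 1e-12, q + 2 * w1 * lin + G[0, 0] * w1 * w1, np.inf
            )
            j = np.unravel_index(np.argmin(obj), obj.shape)
            if obj[j] < best_obj:
                best_obj, best_w = obj[j], np.array([w1, W2[j], W3[j]])
        return best_w
    raise ValueError("oracle supports K in {2, 3}")
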