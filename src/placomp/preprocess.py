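"""Exposure preprocessing helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["iqr_standardize"]


def iqr_standardize(x) -> tuple[np.ndarray, float]:
    """Center an exposure at its median and scale by its interquartile range.

    Quartiles use the linear-interpolation convention (numpy's default),
    so effects downstream read "per one IQR increase in exposure".
    Returns the standardized vector and the IQR used.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4 or not np.all(np.isfinite(x)):
        raise ValueError("need at least 4 finite values in a 1-d exposure vector")
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("degenerate exposure: IQR is zero")
    return (x - med) / iqr, float(iqr)
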