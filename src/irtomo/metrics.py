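"""Fit statistics used across the package.

Defined here once with the exact degenerate-input contracts the rest of the
package relies on (constant inputs raise rather than silently returning 0).
"""

from __future__ import annotations

import numpy as np

__all__ = ["r2_score", "pearson_r", "UndefinedStatistic"]


class UndefinedStatistic(ValueError):
    """The requested statistic is undefined for the given inputs."""


def r2_score(truth, pred) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot.

    Requires length >= 2 and non-constant truth.
    """
    t = np.asarray(truth, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if t.size < 2 or t.size != p.size:
        raise ValueError("need two equal-length arrays of length >= 2")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatistic("R^2 undefined for constant truth")
    return 1.0 - float(np.sum((t - p) ** 2)) / ss_tot


def pearson_r(x, y) -> float:
    """Pearson correlation; requires both inputs non-constant."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size < 2 or xv.size != yv.size:
        raise ValueError("need two equal-length arrays of length >= 2")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0.0:
        raise UndefinedStatistic("Pearson r undefined for constant input")
    return float(np.sum(xc * yc) / denom)
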