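"""Figures of merit for depth and lifetime estimation."""

from __future__ import annotations

import numpy as np

from .estimate import DepthMap

__all__ = ["inlier_fraction", "rmse", "rmse_ratio"]


def _as_map(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, DepthMap):
        return np.asarray(x.depth, dtype=float), np.asarray(x.valid, dtype=bool)
    x = np.asarray(x, dtype=float)
    return x, np.ones(x.shape, dtype=bool)


def inlier_fraction(depth, truth, pct: float) -> float:
    """Fraction of valid pixels within ``pct`` percent of the true depth.

    A pixel is an inlier when ``|d_hat - d| <= (pct/100) * d``.  Pixels
    flagged invalid in either map are excluded; an empty valid set raises.
    """
    est, v1 = _as_map(depth)
    tru, v2 = _as_map(truth)
    if est.shape != tru.shape:
        raise ValueError("shape mismatch between estimate and truth")
    valid = v1 & v2
    if not valid.any():
        raise ValueError("no valid pixels to evaluate")
    err = np.abs(est[valid] - tru[valid])
    return float((err <= (pct / 100.0) * tru[valid]).mean())


def rmse(estimate, truth) -> float:
    """Root mean squared difference over jointly valid pixels."""
    est, v1 = _as_map(estimate)
    tru, v2 = _as_map(truth)
    if est.shape != tru.shape:
        raise ValueError("shape mismatch between estimate and truth")
    valid = v1 & v2
    if not valid.any():
        raise ValueError("no valid pixels to evaluate")
    return float(np.sqrt(np.mean((est[valid] - tru[valid]) ** 2)))


def rmse_ratio(a, b, truth=None) -> float:
    """How many times larger b's error is than a's: rmse(b) / rmse(a).

    With ``truth`` given, ``a`` and ``b`` are estimate maps; without it they
    are already-computed scalar RMSE values.
    """
    if truth is None:
        return float(b) / float(a)
    return rmse(b, truth) / rmse(a, truth)
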