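"""Coates correction: closed-form inversion of first-photon pileup.

A single-hit SPAD records only the first photon per laser cycle, which skews
high-flux histograms toward early bins.  Coates' estimator inverts the
distortion bin by bin:

    Phi_hat[n] = ln( (N_cycle - S[n]) / (N_cycle - S[n] - H[n]) ),

where S[n] is the cumulative count of all earlier bins.  On expected
(noise-free) histograms this is the exact inverse of the first-photon
detection law; on real data it amplifies noise at late bins, which the flux
recovery stage then has to suppress.
"""

from __future__ import annotations

import numpy as np

from .core import FluxCube, TransientCube

__all__ = ["coates_correct", "coates_correct_cube"]


def coates_correct(
    hist: np.ndarray, n_cycle: int, eps: float = 1e-6
) -> tuple[np.ndarray, bool]:
    """Per-bin flux estimate from one first-photon histogram.

    Returns ``(flux, saturated)``.  When every cycle has already detected a
    photon by some bin the denominator hits zero and the estimator diverges;
    such denominators are clamped at ``eps * n_cycle`` and the histogram is
    flagged ``saturated=True``.

    Raises if total counts exceed ``n_cycle`` (not a first-photon histogram).
    """
    hist = np.asarray(hist, dtype=float)
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    total = hist.sum()
    if total > n_cycle:
        raise ValueError("not a first-photon histogram: counts exceed n_cycle")
    earlier = np.concatenate([[0.0], np.cumsum(hist[:-1])])
    numer = n_cycle - earlier
    denom = numer - hist
    floor = eps * n_cycle
    saturated = bool(np.any(denom <= floor) or np.any(numer <= floor))
    numer = np.maximum(numer, floor)
    denom = np.maximum(denom, floor)
    return np.log(numer / denom), saturated


def coates_correct_cube(cube: TransientCube, eps: float = 1e-6) -> FluxCube:
    """Apply Coates correction independently at every pixel of a cube.

    Vectorised over pixels; saturated pixels (any clamped denominator) are
    recorded as a boolean mask in the output metadata.
    """
    counts = cube.counts.astype(float)
    if counts.ndim == 4:  # sequence: correct each frame
        frames = [
            coates_correct_cube(
                TransientCube(cube.counts[..., c], cube.dt, cube.n_cycle), eps
            )
            for c in range(cube.counts.shape[3])
        ]
        flux = np.stack([f.flux for f in frames], axis=3)
        sat = np.stack([f.meta["saturated"] for f in frames], axis=2)
        return FluxCube(flux, cube.dt, meta={"saturated": sat})
    cube.validate_first_photon()
    n_cycle = cube.n_cycle
    earlier = np.concatenate(
        [np.zeros_like(counts[..., :1]), np.cumsum(counts[..., :-1], axis=-1)], axis=-1
    )
    numer = n_cycle - earlier
    denom = numer - counts
    floor = eps * n_cycle
    saturated = (denom <= floor).any(axis=-1) | (numer <= floor).any(axis=-1)
    flux = np.log(np.maximum(numer, floor) / np.maximum(denom, floor))
    return FluxCube(flux, cube.dt, meta={"saturated": saturated})
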