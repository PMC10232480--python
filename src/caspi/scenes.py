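"""Parametric synthetic scenes for simulation studies.

Small generators for the two study geometries used throughout the tests and
bundled pipelines: piecewise-constant LiDAR depth steps and a FLIM field with
spatially invariant lifetimes and piecewise-constant relative contributions.
Both produce :class:`~caspi.simulate.SceneSpec` objects; the actual photon
statistics are applied by :func:`~caspi.simulate.simulate_cube`.
"""

from __future__ import annotations

import numpy as np

from .simulate import SceneSpec

__all__ = ["step_depth_scene", "band_beta_scene"]


def step_depth_scene(
    ny: int,
    nx: int,
    depths: tuple[float, ...] = (0.6, 1.0, 1.5),
    n_sig: float = 2.0,
    n_bkg: float = 50.0,
    intensity_contrast: float = 2.0,
) -> SceneSpec:
    """Vertical depth steps with a mild horizontal intensity gradient.

    Depth takes the given values over equal-width vertical bands (a staircase
    target); intensity ramps linearly from 1 to ``intensity_contrast`` across
    rows so signal flux varies over the field.  Defaults put the scene in the
    low signal-to-background regime (2 signal vs 50 background photons per
    pixel over all cycles).
    """
    cols = np.linspace(0, len(depths), nx, endpoint=False).astype(int)
    depth = np.asarray(depths, dtype=float)[cols][None, :].repeat(ny, axis=0)
    intensity = np.linspace(1.0, intensity_contrast, ny)[:, None].repeat(nx, axis=1)
    return SceneSpec(intensity=intensity, depth=depth, n_sig=n_sig, n_bkg=n_bkg)


def band_beta_scene(
    ny: int,
    nx: int,
    tau1: float = 3e-9,
    tau2: float = 1.5e-9,
    beta_values: tuple[float, ...] = (0.1, 0.5, 0.9),
    n_sig: float = 200.0,
    n_bkg: float = 0.0,
) -> SceneSpec:
    """FLIM field: two invariant lifetimes, banded relative contributions.

    ``beta1`` takes the given values over equal-width vertical bands while
    ``tau1``/``tau2`` are constant across the image — the standard testbed
    for comparing pixel-wise and global bi-exponential fitting.  Default
    budget is 200 signal photons per pixel with no background.
    """
    cols = np.linspace(0, len(beta_values), nx, endpoint=False).astype(int)
    beta1 = np.asarray(beta_values, dtype=float)[cols][None, :].repeat(ny, axis=0)
    intensity = np.ones((ny, nx))
    return SceneSpec(
        intensity=intensity,
        lifetime_maps={"tau1": tau1, "tau2": tau2, "beta1": beta1},
        n_sig=n_sig,
        n_bkg=n_bkg,
    )
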