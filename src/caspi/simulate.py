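"""Synthetic SPAD/TCSPC acquisition for LiDAR and FLIM scenes.

Emulates the full measurement chain of a time-correlated single-photon
camera: a scene-dependent time-varying photon flux (Gaussian return pulse at
the depth-encoded delay for LiDAR, exponential fluorescence decay for FLIM,
plus uniform background), Poisson photon arrivals, and — in the default
``first_photon`` detector mode — the single-hit-per-cycle behaviour of a SPAD
that produces pileup at high flux.

Flux units throughout are expected photons per time bin per laser cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SPEED_OF_LIGHT, FluxCube, LaserPrior, TransientCube

__all__ = [
    "SceneSpec",
    "SimConfig",
    "discrete_gaussian_pulse",
    "lidar_flux",
    "multipath_flux",
    "flim_flux",
    "detection_probabilities",
    "sample_histogram",
    "simulate_cube",
]


@dataclass
class SceneSpec:
    """Ground-truth scene description plus the illumination budget.

    Exactly one of ``depth`` (LiDAR) or ``lifetime_maps`` (FLIM) is set.
    ``n_sig`` / ``n_bkg`` are the mean signal / background photons per pixel
    summed over all laser cycles; the per-pixel signal budget additionally
    scales with intensity and (for LiDAR) inverse squared depth.

    ``lifetime_maps`` is a dict with scalar-or-map entries ``tau1``, ``tau2``
    (seconds) and ``beta1`` (relative contribution of tau1, in [0, 1]).
    """

    intensity: np.ndarray
    n_sig: float
    n_bkg: float
    depth: np.ndarray | None = None
    lifetime_maps: dict | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity <= 0):
            raise ValueError("intensity must be strictly positive")
        if (self.depth is None) == (self.lifetime_maps is None):
            raise ValueError("exactly one of depth or lifetime_maps must be given")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if self.depth.shape != self.intensity.shape:
                raise ValueError("depth and intensity shapes differ")
        else:
            b1 = np.asarray(self.lifetime_maps["beta1"], dtype=float)
            if np.any(b1 < 0) or np.any(b1 > 1):
                raise ValueError("beta1 must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class SimConfig:
    """Acquisition parameters: histogram geometry, laser prior, detector model."""

    nt: int
    dt: float
    n_cycle: int
    laser: LaserPrior
    detector: str = "first_photon"
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.detector not in ("first_photon", "all_photons"):
            raise ValueError(f"unknown detector mode {self.detector!r}")


def discrete_gaussian_pulse(m: float, fwhm: float, dt: float, nt: int) -> np.ndarray:
    """Unit-sum discrete Gaussian pulse centred at bin ``m``.

    The standard deviation in bins is ``FWHM / (2 sqrt(2 ln 2) dt)``.  Mass
    truncated by the histogram edges is renormalised away so the pulse always
    sums to exactly 1 (the per-cycle budget is conserved near boundaries).
    """
    if not 0 <= m < nt:
        raise ValueError("pulse centre m must lie within [0, nt)")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)) * dt)
    n = np.arange(nt, dtype=float)
    if sigma < 1e-9:
        p = np.zeros(nt)
        p[int(round(m))] = 1.0
        return p
    p = np.exp(-0.5 * ((n - m) / sigma) ** 2)
    return p / p.sum()


def lidar_flux(scene: SceneSpec, cfg: SimConfig) -> FluxCube:
    """Ground-truth LiDAR flux cube from intensity and depth maps.

    Per pixel p the per-cycle signal budget is

        Nbar_sig(p) = (N_sig / N_cycle) * (I(p) / D^2(p)) * E[D^2 / I],

    spread over time bins as a unit-sum Gaussian centred at the round-trip
    bin ``round(2 d / (c dt))``; the background adds uniformly,

        Nbar_bkg(p) = (N_bkg / (N_cycle * Nt)) * I(p) / E[I]   per bin.

    Signal falls off with inverse squared depth at fixed intensity, while the
    background does not depend on depth.
    """
    if scene.depth is None:
        raise ValueError("lidar_flux requires a depth map")
    nt, dt = cfg.nt, cfg.dt
    max_depth = SPEED_OF_LIGHT * nt * dt / 2.0
    if np.any(scene.depth < 0) or np.any(scene.depth >= max_depth):
        raise ValueError(f"depth outside the unambiguous range [0, {max_depth:g}) m")
    intensity, depth = scene.intensity, scene.depth
    norm = np.mean(depth**2 / intensity)
    sig_budget = (scene.n_sig / cfg.n_cycle) * (intensity / depth**2) * norm
    bkg = (scene.n_bkg / (cfg.n_cycle * nt)) * intensity / intensity.mean()

    if cfg.laser.kind != "gaussian":
        raise ValueError("lidar_flux expects a gaussian laser prior")
    m = 2.0 * depth / (SPEED_OF_LIGHT * dt)
    flux = np.empty(scene.shape + (nt,), dtype=float)
    # pixels sharing a (rounded) depth bin share a pulse shape
    m_round = np.round(m).astype(int)
    for mb in np.unique(m_round):
        pulse = discrete_gaussian_pulse(mb, cfg.laser.fwhm, dt, nt)
        mask = m_round == mb
        flux[mask] = sig_budget[mask, None] * pulse[None, :]
    flux += bkg[..., None]
    return FluxCube(flux, dt, meta={"model": "lidar"})


def multipath_flux(
    scene: SceneSpec,
    cfg: SimConfig,
    second_depth: np.ndarray,
    second_weight: float = 0.5,
) -> FluxCube:
    """Two-path LiDAR flux: direct return plus a weighted indirect return.

    Models multipath interference as a second, delayed pulse carrying
    ``second_weight`` times the direct signal budget; flash-illumination
    scenes with corners produce such multi-peak transients.
    """
    direct = lidar_flux(scene, cfg)
    indirect_scene = SceneSpec(
        intensity=scene.intensity,
        depth=np.asarray(second_depth, dtype=float),
        n_sig=scene.n_sig * second_weight,
        n_bkg=0.0,
    )
    indirect = lidar_flux(indirect_scene, cfg)
    flux = direct.flux + indirect.flux
    return FluxCube(flux, cfg.dt, meta={"model": "lidar-multipath"})


def _decay_response(
    tau1: float, tau2: float, beta1: float, pulse: np.ndarray, dt: float
) -> np.ndarray:
    """Unit-sum discrete response: laser pulse (x) bi-exponential decay."""
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    nt = len(pulse)
    n = np.arange(nt, dtype=float)
    h1 = np.exp(-n * dt / tau1)
    h1 /= h1.sum()
    h2 = np.exp(-n * dt / tau2)
    h2 /= h2.sum()
    h = beta1 * h1 + (1.0 - beta1) * h2
    r = np.convolve(pulse, h)[:nt]  # truncate to the cycle window
    return r / r.sum()


def flim_flux(scene: SceneSpec, cfg: SimConfig) -> FluxCube:
    """Ground-truth FLIM flux cube from lifetime and contribution maps.

    Per pixel: per-cycle signal budget (intensity-weighted share of
    ``n_sig / n_cycle``) times the unit-sum convolution of the laser pulse
    with the bi-exponential decay ``beta1 h(tau1) + (1 - beta1) h(tau2)``,
    plus uniform background as in the LiDAR model.
    """
    if scene.lifetime_maps is None:
        raise ValueError("flim_flux requires lifetime maps")
    nt, dt = cfg.nt, cfg.dt
    maps = scene.lifetime_maps
    shape = scene.shape
    tau1 = np.broadcast_to(np.asarray(maps["tau1"], dtype=float), shape)
    tau2 = np.broadcast_to(np.asarray(maps.get("tau2", maps["tau1"]), dtype=float), shape)
    beta1 = np.broadcast_to(np.asarray(maps.get("beta1", 1.0), dtype=float), shape)

    intensity = scene.intensity
    sig_budget = (scene.n_sig / cfg.n_cycle) * intensity / intensity.mean()
    bkg = (scene.n_bkg / (cfg.n_cycle * nt)) * intensity / intensity.mean()

    pulse = cfg.laser.pulse(nt)
    flux = np.empty(shape + (nt,), dtype=float)
    # cache responses: scenes typically have few distinct (tau1, tau2, beta1)
    cache: dict[tuple[float, float, float], np.ndarray] = {}
    for idx in np.ndindex(shape):
        key = (float(tau1[idx]), float(tau2[idx]), float(beta1[idx]))
        r = cache.get(key)
        if r is None:
            r = _decay_response(key[0], key[1], key[2], pulse, dt)
            cache[key] = r
        flux[idx] = sig_budget[idx] * r
    flux += bkg[..., None]
    return FluxCube(flux, dt, meta={"model": "flim"})


def detection_probabilities(flux: np.ndarray) -> np.ndarray:
    """First-photon detection probabilities per bin for one laser cycle.

    With Poisson arrivals of mean ``Phi[n]`` per bin, a photon is seen in bin
    n with probability ``q[n] = 1 - exp(-Phi[n])``, and is the *first* of the
    cycle with probability ``p[n] = q[n] prod_{i<n} (1 - q[i])``.  At low
    flux p is proportional to Phi; at high flux p piles up at early bins.
    """
    flux = np.asarray(flux, dtype=float)
    if np.any(flux < 0):
        raise ValueError("flux must be non-negative")
    q = -np.expm1(-flux)
    none_before = np.concatenate(
        [np.ones_like(flux[..., :1]), np.exp(-np.cumsum(flux[..., :-1], axis=-1))],
        axis=-1,
    )
    return q * none_before


def sample_histogram(
    flux: np.ndarray,
    n_cycle: int,
    mode: str = "first_photon",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample a photon detection histogram from a per-cycle flux vector.

    ``first_photon`` draws, for each of ``n_cycle`` independent cycles, the
    bin of the first arriving photon (or no detection); the cycle outcomes
    follow the closed-form first-photon law, so the histogram is one
    multinomial draw over (bins + no-detection).  ``all_photons`` is the
    idealised dead-time-free detector: independent Poisson counts per bin.
    """
    rng = np.random.default_rng(rng)
    flux = np.asarray(flux, dtype=float)
    if np.any(flux < 0):
        raise ValueError("flux must be non-negative")
    if mode == "all_photons":
        return rng.poisson(n_cycle * flux)
    if mode != "first_photon":
        raise ValueError(f"unknown detector mode {mode!r}")
    p = detection_probabilities(flux)
    p_none = max(0.0, 1.0 - p.sum())
    pvals = np.concatenate([p, [p_none]])
    pvals /= pvals.sum()
    return rng.multinomial(n_cycle, pvals)[:-1]


def simulate_cube(
    scene_or_flux: SceneSpec | FluxCube, cfg: SimConfig
) -> tuple[TransientCube, FluxCube]:
    """Simulate a full transient cube; returns (measured cube, true flux).

    Accepts either a scene description (LiDAR or FLIM, dispatched on which
    ground-truth maps are present) or a pre-built flux cube (e.g. multipath).
    Per-pixel generators are spawned deterministically from ``cfg.seed`` so
    cubes are reproducible regardless of pixel evaluation order.
    """
    if isinstance(scene_or_flux, FluxCube):
        truth = scene_or_flux
    elif scene_or_flux.depth is not None:
        truth = lidar_flux(scene_or_flux, cfg)
    else:
        truth = flim_flux(scene_or_flux, cfg)
    ny, nx, nt = truth.flux.shape
    if nt != cfg.nt:
        raise ValueError("flux temporal length does not match cfg.nt")

    counts = np.empty((ny, nx, nt), dtype=np.int64)
    children = np.random.SeedSequence(cfg.seed).spawn(ny * nx)
    for i in range(ny):
        for j in range(nx):
            rng = np.random.default_rng(children[i * nx + j])
            counts[i, j] = sample_histogram(truth.flux[i, j], cfg.n_cycle, cfg.detector, rng)
    cube = TransientCube(
        counts, cfg.dt, cfg.n_cycle, meta={"seed": cfg.seed, "detector": cfg.detector}
    )
    if cfg.detector == "first_photon":
        cube.validate_first_photon()
    return cube, truth
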