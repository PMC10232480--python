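"""Hierarchical blind collaborative flux recovery (the CASPI core).

The recovery runs in two stages over small ``Cy x Cx x Nt`` cubelets anchored
at every pixel:

* **local** — each cubelet is transformed (3D DFT), its noise level is read
  off the pure noise band, and an initial estimate is formed either by hard
  thresholding at the noise bound (high SNR) or by guided spectral masking
  with the cubelet's pseudo-intensity patch (low SNR).  Overlapping estimates
  are fused by inverse-noise-power weighted averaging, then refined by
  empirical Wiener filtering and fused again.

* **nonlocal** — a pseudo-intensity image of the local-stage output (or an
  external intensity image) drives block matching; each cubelet is stacked
  with its ``Nsim`` most similar neighbours into a 4D set, and the same
  estimate / fuse / Wiener / fuse cycle runs on 4D DFTs, where structured
  signal accumulates across the similarity axis much faster than noise.

No training, no noise model supplied by the user: everything is estimated
from the data and the laser source prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    FluxCube,
    LaserPrior,
    NoiseBandMask,
    NoiseStats,
    TransientCube,
    noise_stats,
    noise_threshold,
    pseudo_intensity,
    pure_noise_band_gaussian,
    pure_noise_band_irf,
    snr_ratio,
)
from .pileup import coates_correct_cube

__all__ = [
    "RecoverConfig",
    "CubeletSet",
    "extract_cubelet",
    "gather_set",
    "hard_threshold_estimate",
    "guided_estimate",
    "select_initial",
    "block_match",
    "aggregate",
    "wiener_refine",
    "recover_stage",
    "caspi",
]

_TINY = 1e-30  # floor for inverse-noise-power weights


@dataclass
class RecoverConfig:
    """Tunable parameters of the recovery.

    Defaults follow the standard operating point: 8x8 cubelets, 10 similar
    cubelets, a 21x21 spatial search window (11 frames deep for sequences),
    and SNR branch thresholds 1/0.8 (local stage) and 1/0.9 (nonlocal stage).
    ``stride`` thins the anchor grid for speed; 1 anchors every pixel.

    ``min_sep`` is the minimum Chebyshev distance between the anchors of the
    cubelets grouped into one 4D set.  Overlapping cubelets share pixels and
    hence share noise; correlated noise concentrates at low similarity-axis
    frequencies, where it defeats the blind threshold (which models band
    coefficients as identically distributed).  Keeping members at least half
    a cubelet apart restores approximate independence; set 0 to group purely
    by distance rank.
    """

    cy: int = 8
    cx: int = 8
    n_sim: int = 10
    s_intra: int = 21
    s_inter: int = 11
    rth_local: float = 1.0 / 0.8
    rth_nonlocal: float = 1.0 / 0.9
    stride: int = 1
    min_sep: int = 4
    guide: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cy < 2 or self.cx < 2:
            raise ValueError("cubelet size must be at least 2x2")
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")
        if self.s_intra % 2 != 1:
            raise ValueError("s_intra must be odd")
        if self.min_sep < 0:
            raise ValueError("min_sep must be non-negative")
        if self.stride < 1:
            raise ValueError("stride must be at least 1")


@dataclass
class CubeletSet:
    """``Nsim`` stacked similar cubelets plus their source anchors (reference first)."""

    data: np.ndarray  # [cy, cx, nt, n_sim]
    anchors: list[tuple]

    def __post_init__(self) -> None:
        if len(self.anchors) != self.data.shape[3]:
            raise ValueError("anchor count does not match similarity axis length")
        if len(set(self.anchors)) != len(self.anchors):
            raise ValueError("anchors must be unique")


def noise_band(laser: LaserPrior, nt: int) -> NoiseBandMask:
    """Pure noise band for either kind of laser prior."""
    if laser.kind == "gaussian":
        return pure_noise_band_gaussian(laser.fwhm, laser.dt, nt)
    return pure_noise_band_irf(laser, nt)


def _anchor_axis(n: int, c: int, stride: int) -> np.ndarray:
    """Anchor coordinates along one spatial axis: strided, last block clamped."""
    if n < c:
        raise ValueError("image smaller than the cubelet")
    pos = list(range(0, n - c + 1, stride))
    if pos[-1] != n - c:
        pos.append(n - c)
    return np.asarray(pos)


def extract_cubelet(cube: np.ndarray, anchor: tuple[int, int], cy: int, cx: int) -> np.ndarray:
    """Contiguous ``cy x cx`` spatial window, full temporal extent, at ``anchor``."""
    r, c = anchor
    ny, nx = cube.shape[:2]
    if not (0 <= r <= ny - cy and 0 <= c <= nx - cx):
        raise ValueError(f"anchor {anchor} out of bounds for cubelet {cy}x{cx}")
    return cube[r : r + cy, c : c + cx]


def hard_threshold_estimate(
    block: np.ndarray, band: NoiseBandMask, stats: NoiseStats
) -> np.ndarray:
    """Zero every DFT coefficient below the noise bound; keep the global DC.

    Works on 3D cubelets and 4D transient sets alike (full N-dimensional DFT).
    """
    spec = np.fft.fftn(block)
    delta = noise_threshold(stats)
    keep = np.abs(spec) >= delta
    keep[(0,) * block.ndim] = True  # DC carries the mean flux, never noise
    return np.real(np.fft.ifftn(spec * keep))


def guided_estimate(block: np.ndarray, guide_patch: np.ndarray) -> np.ndarray:
    """Spectral masking of a cubelet by its intensity patch, for very low SNR.

    The guide patch is normalised to unit sum, 2D-transformed, and its
    spectrum multiplies the cubelet's transform at every temporal frequency —
    transferring the spatial-frequency support of the intensity image onto
    the transient data.  The unit DC of the guide preserves per-time-bin
    spatial sums.
    """
    guide_patch = np.asarray(guide_patch, dtype=float)
    if np.any(guide_patch < 0):
        raise ValueError("guide patch must be non-negative")
    total = guide_patch.sum()
    if total == 0:
        raise ValueError("guide patch is all zero")
    mask = np.fft.fft2(guide_patch / total)
    shape = (guide_patch.shape[0], guide_patch.shape[1]) + (1,) * (block.ndim - 2)
    spec = np.fft.fftn(block) * mask.reshape(shape)
    return np.real(np.fft.ifftn(spec))


def select_initial(
    block: np.ndarray,
    band: NoiseBandMask,
    stats: NoiseStats,
    rth: float,
    guide_patch: np.ndarray,
) -> np.ndarray:
    """Adaptive initial estimate: thresholding if R > rth, guided otherwise."""
    if snr_ratio(stats) > rth:
        return hard_threshold_estimate(block, band, stats)
    return guided_estimate(block, guide_patch)


def block_match(
    guide_image: np.ndarray,
    anchor: tuple,
    cfg: RecoverConfig,
    patches: np.ndarray | None = None,
) -> list[tuple]:
    """Anchors of the ``n_sim`` cubelets most similar to the reference.

    Similarity is the squared L2 distance between ``cy x cx`` patches of the
    guide image; candidates live in an ``s_intra x s_intra`` window (times
    ``s_inter`` frames for a 3D guide video) centred on the reference and
    clamped to valid anchor positions.  The reference is always first; ties
    break in row-major (then frame) scan order; candidates closer than
    ``cfg.min_sep`` (Chebyshev, spatial axes) to an already-selected anchor
    are skipped so that grouped cubelets carry approximately independent
    noise.  If fewer than ``n_sim`` eligible candidates exist, all are
    returned.

    ``patches`` optionally carries precomputed sliding-window patches of the
    guide (as produced by :func:`numpy.lib.stride_tricks.sliding_window_view`)
    to amortise repeated calls.
    """
    guide_image = np.asarray(guide_image, dtype=float)
    if not np.all(np.isfinite(guide_image)):
        raise ValueError("guide image must be finite")
    seq = guide_image.ndim == 3
    ny, nx = guide_image.shape[:2]
    cy, cx = cfg.cy, cfg.cx
    if patches is None:
        patches = np.lib.stride_tricks.sliding_window_view(
            guide_image, (cy, cx), axis=(0, 1)
        )
    half = (cfg.s_intra - 1) // 2
    if seq:
        r, c, f = anchor
    else:
        r, c = anchor
    r0, r1 = max(0, r - half), min(ny - cy, r + half)
    c0, c1 = max(0, c - half), min(nx - cx, c + half)
    if seq:
        ref = patches[r, c, f]
        fhalf = (cfg.s_inter - 1) // 2
        f0, f1 = max(0, f - fhalf), min(guide_image.shape[2] - 1, f + fhalf)
        cand = patches[r0 : r1 + 1, c0 : c1 + 1, f0 : f1 + 1]
        d = ((cand - ref) ** 2).sum(axis=(-2, -1))
        rr, cc, ff = np.meshgrid(
            np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), np.arange(f0, f1 + 1),
            indexing="ij",
        )
        cand_anchors = list(zip(rr.ravel(), cc.ravel(), ff.ravel()))
    else:
        ref = patches[r, c]
        cand = patches[r0 : r1 + 1, c0 : c1 + 1]
        d = ((cand - ref) ** 2).sum(axis=(-2, -1))
        rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
        cand_anchors = list(zip(rr.ravel(), cc.ravel()))
    d = d.ravel()
    ref_anchor = tuple(int(v) for v in anchor)
    order = np.argsort(d, kind="stable")  # stable sort = row-major tie-break
    result = [ref_anchor]
    for idx in order:
        if len(result) >= cfg.n_sim:
            break
        a = tuple(int(v) for v in cand_anchors[idx])
        if a == ref_anchor:
            continue
        if cfg.min_sep and any(
            max(abs(a[0] - s[0]), abs(a[1] - s[1])) < cfg.min_sep
            and (not seq or a[2] == s[2])
            for s in result
        ):
            continue
        result.append(a)
        if len(result) == cfg.n_sim:
            break
    return result


def gather_set(
    cube: np.ndarray, anchors: Sequence[tuple], cy: int, cx: int
) -> CubeletSet:
    """Stack the cubelets at ``anchors`` (reference first) into a 4D set."""
    blocks = [extract_cubelet(cube, a[:2], cy, cx) for a in anchors]
    return CubeletSet(np.stack(blocks, axis=3), [tuple(a) for a in anchors])


def aggregate(
    estimates: Sequence[np.ndarray],
    anchors: Sequence[tuple],
    weights: Sequence[float],
    shape: tuple,
) -> np.ndarray:
    """Weighted average of overlapping cubelet estimates on the full grid.

    Each estimate is written back at its anchor; every pixel-bin value is
    ``sum_i w_i est_i / sum_i w_i`` over the cubelets covering it.  Raises if
    any pixel is left uncovered.
    """
    num = np.zeros(shape, dtype=float)
    den = np.zeros(shape[:2] if len(shape) == 3 else shape[:2] + shape[3:], dtype=float)
    for est, anchor, w in zip(estimates, anchors, weights):
        cy, cx = est.shape[:2]
        r, c = anchor[:2]
        if len(shape) == 4:
            f = anchor[2]
            num[r : r + cy, c : c + cx, :, f] += w * est
            den[r : r + cy, c : c + cx, f] += w
        else:
            num[r : r + cy, c : c + cx] += w * est
            den[r : r + cy, c : c + cx] += w
    if np.any(den == 0):
        raise ValueError("aggregation left uncovered pixels")
    if len(shape) == 4:
        return num / den[:, :, None, :]
    return num / den[..., None]


def wiener_refine(
    noisy_block: np.ndarray, initial_energy: np.ndarray, stats: NoiseStats
) -> np.ndarray:
    """Empirical Wiener filtering of a noisy block.

    ``W = |A|^2 / (|A|^2 + E[|B_noise|^2])`` with ``|A|^2`` the spectral
    energy of the initial estimate and the noise power taken from the *noisy*
    block's pure-noise band.  W lies in [0, 1]; zero noise power gives W = 1
    (pass-through).
    """
    if stats.mean_sq == 0.0:
        return np.asarray(noisy_block, dtype=float).copy()
    w = initial_energy / (initial_energy + stats.mean_sq)
    spec = np.fft.fftn(noisy_block)
    return np.real(np.fft.ifftn(spec * w))


def _guide_patch_for(
    x: np.ndarray, guide_image: np.ndarray | None, anchor: tuple, cy: int, cx: int
) -> np.ndarray:
    """Guide patch at an anchor: external/pseudo-intensity image if available,
    else the block's own pseudo-intensity (clipped at zero)."""
    if guide_image is not None:
        if guide_image.ndim == 3:
            r, c, f = anchor
            patch = guide_image[r : r + cy, c : c + cx, f]
        else:
            r, c = anchor[:2]
            patch = guide_image[r : r + cy, c : c + cx]
    else:
        block = extract_cubelet(x, anchor[:2], cy, cx)
        if x.ndim == 4:
            block = block[..., anchor[2]]
        patch = block.sum(axis=2)
    patch = np.clip(patch, 0.0, None)
    if patch.sum() == 0:  # degenerate dark patch: fall back to a flat guide
        patch = np.ones((cy, cx))
    return patch


def recover_stage(
    x: np.ndarray,
    cfg: RecoverConfig,
    laser: LaserPrior,
    stage: str,
    guide_image: np.ndarray | None = None,
) -> np.ndarray:
    """One recovery stage (local 3D cubelets or nonlocal 4D transient sets).

    ``x`` is a per-cycle flux array, 3D ``(Ny, Nx, Nt)`` or a 4D sequence
    ``(Ny, Nx, Nt, Nc)``.  The nonlocal stage requires a guide image (2D, or
    3D guide video for sequences) to drive block matching.
    """
    if stage not in ("local", "nonlocal"):
        raise ValueError(f"unknown stage {stage!r}")
    x = np.asarray(x, dtype=float)
    seq = x.ndim == 4
    if seq and stage == "local":
        out = np.empty_like(x)
        for f in range(x.shape[3]):
            g = None if guide_image is None else guide_image[..., f]
            out[..., f] = recover_stage(x[..., f], cfg, laser, "local", g)
        return out

    ny, nx, nt = x.shape[:3]
    band = noise_band(laser, nt)
    cy, cx = cfg.cy, cfg.cx
    rows = _anchor_axis(ny, cy, cfg.stride)
    cols = _anchor_axis(nx, cx, cfg.stride)
    if seq:
        frames = np.arange(x.shape[3])
        anchors = [(int(r), int(c), int(f)) for r in rows for c in cols for f in frames]
    else:
        anchors = [(int(r), int(c)) for r in rows for c in cols]

    rth = cfg.rth_local if stage == "local" else cfg.rth_nonlocal
    if stage == "nonlocal":
        if guide_image is None:
            raise ValueError("nonlocal stage requires a guide image")
        guide_image = np.asarray(guide_image, dtype=float)
        patches = np.lib.stride_tricks.sliding_window_view(
            guide_image, (cy, cx), axis=(0, 1)
        )
        matched = [block_match(guide_image, a, cfg, patches) for a in anchors]
    else:
        matched = [[a] for a in anchors]

    def grab(anchor: tuple) -> np.ndarray:
        b = extract_cubelet(x, anchor[:2], cy, cx)
        return b[..., anchor[2]] if seq else b

    def build_block(group: list[tuple]) -> np.ndarray:
        if stage == "local":
            return grab(group[0])
        return np.stack([grab(a) for a in group], axis=3)

    def scatter(num, den, est, group, w):
        """Write a block (or each member of a 4D set) back at its anchor."""
        members = [est] if stage == "local" else [est[..., k] for k in range(est.shape[3])]
        for blk, a in zip(members, group):
            r, c = a[:2]
            if seq:
                num[r : r + cy, c : c + cx, :, a[2]] += w * blk
                den[r : r + cy, c : c + cx, a[2]] += w
            else:
                num[r : r + cy, c : c + cx] += w * blk
                den[r : r + cy, c : c + cx] += w

    den_shape = (ny, nx) if not seq else (ny, nx, x.shape[3])

    # ---- pass 1: noise estimation + adaptive initial estimates --------------
    # accumulated in place: inverse-noise-power weighted averaging
    mean_sqs = np.empty(len(anchors))
    weights = np.empty(len(anchors))
    num = np.zeros_like(x)
    den = np.zeros(den_shape)
    for i, group in enumerate(matched):
        block = build_block(group)
        stats = noise_stats(np.fft.fftn(block), band, time_axis=2)
        mean_sqs[i] = stats.mean_sq
        weights[i] = 1.0 / max(stats.mean_sq, _TINY)
        gp = _guide_patch_for(x, guide_image, group[0], cy, cx)
        est = select_initial(block, band, stats, rth, gp)
        scatter(num, den, est, group, weights[i])
    if np.any(den == 0):
        raise ValueError("anchor grid left uncovered pixels")
    initial = num / (den[:, :, None, :] if seq else den[..., None])

    # ---- pass 2: empirical Wiener refinement on the noisy blocks ------------
    num[:] = 0.0
    den[:] = 0.0
    for i, group in enumerate(matched):
        if stage == "local":
            init_block = extract_cubelet(initial, group[0][:2], cy, cx)
            if seq:
                init_block = init_block[..., group[0][2]]
        else:
            init_block = np.stack(
                [
                    extract_cubelet(initial, a[:2], cy, cx)[..., a[2]]
                    if seq
                    else extract_cubelet(initial, a[:2], cy, cx)
                    for a in group
                ],
                axis=3,
            )
        a2 = np.abs(np.fft.fftn(init_block)) ** 2
        stats = NoiseStats(0.0, mean_sqs[i], 0.0, 0)
        refined = wiener_refine(build_block(group), a2, stats)
        scatter(num, den, refined, group, weights[i])
    return num / (den[:, :, None, :] if seq else den[..., None])


def caspi(
    cube: TransientCube | FluxCube | np.ndarray,
    laser: LaserPrior,
    cfg: RecoverConfig | None = None,
    do_coates: bool = True,
) -> FluxCube:
    """Full two-stage blind flux recovery from a photon transient cube.

    Accepts a measured :class:`TransientCube` (counts; converted to per-cycle
    flux by Coates correction, or plain ``counts / n_cycle`` when
    ``do_coates=False``), an already-corrected :class:`FluxCube`, or a bare
    float array.  Returns the recovered flux, clipped to be non-negative.
    Fully deterministic: identical inputs give bitwise-identical output.
    """
    if cfg is None:
        cfg = RecoverConfig()
    if isinstance(cube, TransientCube):
        dt = cube.dt
        if do_coates:
            x = coates_correct_cube(cube).flux
        else:
            x = cube.counts.astype(float) / cube.n_cycle
    elif isinstance(cube, FluxCube):
        dt, x = cube.dt, cube.flux
    else:
        dt, x = laser.dt, np.asarray(cube, dtype=float)

    local = recover_stage(x, cfg, laser, "local", guide_image=cfg.guide)
    if cfg.guide is not None:
        guide = cfg.guide
    else:
        loc = np.clip(local, 0.0, None)
        guide = loc.sum(axis=2) if loc.ndim == 4 else pseudo_intensity(loc)
    final = recover_stage(x, cfg, laser, "nonlocal", guide_image=guide)
    return FluxCube(np.clip(final, 0.0, None), dt, meta={"stages": ["local", "nonlocal"]})
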