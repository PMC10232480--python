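# caspi

Blind recovery of time-varying photon fluxes from single-photon camera data,
with simulation and scene-property estimation for single-photon LiDAR and
fluorescence-lifetime imaging (FLIM).

## What problem this solves

A SPAD array driven by time-correlated single-photon counting records, per
pixel, a histogram of photon detection times — a *photon transient*. Under
photon-starved conditions the histogram is a sparse Poisson sample of the
true flux; under photon-flooded conditions it piles up toward early time
bins because a single-hit detector keeps only the first photon of each laser
cycle. Both regimes ruin the downstream science: depth maps from
time-of-flight peaks, lifetime maps from fluorescence decays.

This package implements a training-free, blind pipeline that recovers the
latent flux `Φ[n]` (expected photons per bin per cycle) from a transient cube
`H ∈ Z^(Ny×Nx×Nt)` given only a laser source prior (a Gaussian pulse width,
or a tabulated instrument response):

1. **Pileup inversion** (Coates): `Φ̂[n] = ln((N − S[n]) / (N − S[n] − H[n]))`
   with `S[n]` the cumulative count of earlier bins and `N` the cycle count.
2. **Blind noise estimation**: temporal frequencies above the laser pulse's
   spectral support (`f > 3·sqrt(2 ln 2)/(π·FWHM)` for a Gaussian pulse)
   contain only noise; the bound `δ_noise = (1 + 4·sqrt(4/π − 1))·E[|B_noise|]`
   and the SNR surrogate `R = E[|B_noise^c|²]/E[|B_noise|²]` come entirely
   from the data.
3. **Two-stage collaborative filtering**: per-pixel 8×8×Nt cubelets are
   denoised by adaptive hard thresholding / intensity-guided spectral
   masking plus empirical Wiener filtering, first using local 3D transforms,
   then using 4D transforms of the ten most similar cubelets found by block
   matching on a pseudo-intensity image.
4. **Estimation**: matched-filter depth (LiDAR); Poisson maximum-likelihood
   mono-exponential lifetimes, bi-exponential contribution maps, and global
   (shared-lifetime) analysis (FLIM).

A physically faithful SPAD/TCSPC simulator (Poisson arrivals, first-photon
pileup, Gaussian or arbitrary pulses, multipath returns, mono- and
bi-exponential decays) makes every stage testable end to end with no
external data. See `docs/methods.md` for the model details and design
choices.

## Worked example

Simulate a low-SBR LiDAR scene (2 signal vs 50 background photons per pixel
over 1000 cycles), recover the flux, and compare depth maps:

```python
import numpy as np
from caspi import (LaserPrior, SimConfig, FluxCube, caspi,
                   matched_filter_depth, inlier_fraction, simulate_cube)
from caspi.scenes import step_depth_scene

laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
cfg = SimConfig(nt=128, dt=100e-12, n_cycle=1000, laser=laser, seed=0)
scene = step_depth_scene(32, 32)            # depth steps 0.6 / 1.0 / 1.5 m
cube, truth = simulate_cube(scene, cfg)

raw = FluxCube(cube.counts.astype(float) / cfg.n_cycle, cfg.dt)
d_raw = matched_filter_depth(raw, laser)
d_rec = matched_filter_depth(caspi(cube, laser), laser)

print(f"1% depth inliers, raw:       {inlier_fraction(d_raw, scene.depth, 1.0):.3f}")
print(f"1% depth inliers, recovered: {inlier_fraction(d_rec, scene.depth, 1.0):.3f}")
```

Output:

```
1% depth inliers, raw:       0.161
1% depth inliers, recovered: 0.855
```

Matched filtering on the raw histograms finds the right depth at 16% of
pixels — background photons win the arg-max almost everywhere. After blind
flux recovery the same matched filter is right at 86% of pixels.

The same pipeline is scriptable from the shell:

```bash
caspi pipeline --config src/caspi/configs/lidar_lowsbr.yaml --out out/ --verbose
```

which writes the simulated cube (HDF5), the recovered flux, depth and
intensity maps (TIFF), a metrics CSV, and a JSON run log embedding the
config hash. `caspi simulate|correct|recover|estimate|evaluate` expose the
individual stages.

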