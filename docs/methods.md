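# Methods

## The problem

Single-photon cameras (SPAD arrays driven by time-correlated single-photon
counting) record, at each pixel, a histogram of photon detection times over
many laser cycles — a *photon transient*. The stack of transients over the
pixel array is a 3D *photon transient cube* `(Ny, Nx, Nt)`. Two distortions
separate the cube from the quantity of interest, the time-varying incident
flux `Φ[n]` (expected photons per time bin per cycle):

* **Photon noise** — at low flux the histogram is a sparse Poisson sample of
  the transient shape;
* **Pileup** — a single-hit SPAD records only the first photon per cycle, so
  at high flux the histogram skews toward early bins.

This package recovers `Φ` blind (no training data, no user-supplied noise
level) and feeds the result to standard downstream estimators: matched-filter
depth for LiDAR, Poisson maximum-likelihood lifetime and bi-exponential
contribution fits for FLIM.

## Measurement model

Poisson arrivals with per-bin mean `Φ[n]` give a first-photon detection
probability

    q[n] = 1 − exp(−Φ[n]),      p[n] = q[n] · Π_{i<n} (1 − q[i]),

and the histogram `H` over `N_cycle` cycles is multinomial over
`(p[1..Nt], 1 − Σp)`. The simulator draws that multinomial directly — it is
distributionally identical to the per-cycle rejection procedure and orders of
magnitude faster; the literal per-cycle sampler is kept in the test suite as
the independent oracle. Pileup is inverted in closed form (Coates):

    Φ̂[n] = ln( (N_cycle − S[n]) / (N_cycle − S[n] − H[n]) ),  S[n] = Σ_{i<n} H[i],

which is the exact inverse of the detection law on expected histograms (a
property the tests verify to 1e-9) but amplifies noise at late bins;
saturated denominators are clamped at `eps·N_cycle` (`eps = 1e-6`, our
choice) and flagged.

## Blind noise estimation

The optical chain low-passes the illumination, so the flux cannot contain
temporal frequencies beyond the laser pulse's spectral support. For a
Gaussian pulse of width FWHM the *pure noise band* is every temporal
frequency above `3·sqrt(2 ln 2)/(π·FWHM)` (three standard deviations of the
pulse's Gaussian spectrum); for a tabulated, possibly bimodal instrument
response it is everything above the first frequency past the spectral peak
where the magnitude falls below 1% of its maximum. Band statistics are
computed on the full two-sided N-dimensional DFT of a block, over *all*
spatial/similarity frequencies (the band is a purely temporal object); the
DC temporal frequency is never a member because constant background flux is
signal there.

For circular complex Gaussian noise the coefficient magnitudes are Rayleigh,
so mean + 4 standard deviations expressed through the mean gives the noise
bound

    δ_noise = (1 + 4·sqrt(4/π − 1)) · E[|B_noise|]  ≈ 3.0908 · E[|B_noise|],

exceeded by pure noise with probability ≈ 5.5e-4 per coefficient. The blind
SNR surrogate is `R = E[|B_noise^c|²] / E[|B_noise|²]` (≈1 for pure noise).

## Two-stage collaborative recovery

Recovery operates on 8×8×Nt cubelets anchored at every pixel (anchors
clamped at the borders; a configurable stride thins the grid for speed).

**Local stage.** Each cubelet is 3D-DFT'd; depending on `R` relative to a
branch threshold (1/0.8), either *hard thresholding* at `δ_noise` (all
coefficients below the bound zeroed, global DC always kept) or *guided
processing* (the cubelet's spectrum multiplied by the 2D spectrum of its
unit-sum pseudo-intensity patch — circular convolution with the intensity
pattern, for very low SNR) forms an initial estimate. Overlapping estimates
are fused per pixel by inverse-noise-power weights `ω_i = 1/E[|B_noise,i|²]`.
A second pass Wiener-filters each noisy cubelet with
`W = |A|²/(|A|² + E[|B_noise|²])`, where `|A|²` is the spectral energy of the
initial estimate re-extracted from the fused cube at the same anchor
(two-pass, as in transform-domain collaborative filtering), and fuses again
with the same weights.

**Nonlocal stage.** A pseudo-intensity image of the local-stage output (or
an external intensity image, when available) drives block matching: squared-L2
distances between 8×8 patches inside a 21×21 search window (×11 frames for
4D sequences), the ten most similar cubelets stacked into a 4D set. The same
estimate → fuse → Wiener → fuse cycle runs on 4D DFTs of the *noisy* sets,
where structured signal accumulates across the similarity axis much faster
than independent noise; every member returns to its own anchor with the
set's weight. The branch threshold is 1/0.9 here. Intermediate negative
values are allowed throughout; only the final output is clipped at zero
(early clipping would bias the Wiener step).

**Member separation.** Matched cubelets that overlap spatially share pixels
and therefore share noise; the shared part concentrates at low
similarity-axis frequencies where it exceeds `δ_noise`, whose derivation
assumes identically-distributed band coefficients. On scenes with a flat
intensity (where matching is noise-driven and happily groups adjacent,
heavily-overlapping patches) this makes the 4D stage *worse* than the local
stage. `RecoverConfig.min_sep` (default 4 px Chebyshev — half a cubelet)
skips candidates closer than that to an already-selected member, restoring
approximate independence; `min_sep=0` restores pure distance-rank grouping.
Measured on the bi-exponential FLIM testbed, this turns the 4D stage from a
1.3× degradation into a 1.7× improvement in flux RMSE.

## Downstream estimators

* **Depth** — circular cross-correlation with the unit-sum pulse template;
  depth `c·n*·Δt/2` at the arg-max lag, ties to the smallest lag (flagged
  unconfident), all-zero transients invalid.
* **Mono-exponential lifetime** — Poisson MLE of `A·e^(−nΔt/τ) + b` on the
  decay tail, amplitude (and optionally background) profiled out, bounded 1D
  search over τ (tolerance 1e-4 ns). The excitation pulse is treated as a
  delta on the tail.
* **Bi-exponential contributions** — the model is linear in the non-negative
  amplitudes `(a1, a2, b)` of the two pulse-convolved decay components and a
  flat offset, so the profiled problem is concave; the map fitter runs
  multiplicative (Richardson–Lucy form) EM vectorised over all pixels, the
  scalar fitter a bounded Brent search over `β1 = a1/(a1+a2)` with inner
  profiling — two routes to the same optimum, cross-checked in the tests.
* **Global analysis** — shared `(τ1, τ2)` across the image, per-pixel
  contributions; alternating ascent where the lifetime step follows the
  *profile* likelihood (each Nelder–Mead candidate re-profiles the per-pixel
  amplitudes with a short warm-started EM). A frozen-amplitude lifetime step
  — the textbook alternation — stalls far from the optimum on this badly
  conditioned surface.

**Fit windows.** All decay fitters default to the tail window starting one
bin past the transient maximum (standard FLIM practice; for cube-level fits
the window comes from the image-summed transient so all pixels share it).
This matters after recovery: spectral shrinkage smears the sharp rise edge
(≈20% at the first bin in our measurements) while leaving the decay
accurate, and a full-curve fit amplifies that rise distortion into a
systematic contribution bias. `β1` is always defined on full-curve component
areas regardless of window.

**Background profiling.** Profiling a free flat offset is the robust default,
but on background-free data at low counts the offset can absorb part of the
slow component's tail: on the 200-photon global-analysis testbed the
offset-augmented likelihood *genuinely prefers* `τ1 ≈ 2.64 ns` over the
generating 3 ns (Δ log-likelihood ≈ 62 in its favour). Parameter-recovery
studies on background-free data therefore fit the matched model
(`background=False`); comparative studies keep the default on both sides.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the photon statistics of SPAD acquisition exactly
(Poisson arrivals, first-photon selection, pileup) and two scene families:

* *LiDAR staircase* — piecewise-constant depth bands with an intensity
  gradient; per-pixel signal scales with `I/D²` (normalised so the image
  mean budget is `N_sig` photons over all cycles), background with `I`,
  uniform in time. Multipath adds a second, weighted return.
* *FLIM contribution bands* — spatially invariant lifetimes (3 ns / 1.5 ns
  defaults), `β1` piecewise in {0.1, 0.5, 0.9} over vertical bands, fixed
  signal budget per pixel, pulse-convolved bi-exponential decays.

Study conditions used throughout the tests, chosen once as a realistic
operating point: LiDAR — 128 bins × 100 ps (12.8 ns cycle, 1.92 m range),
400 ps pulse, 1000 cycles, 2 signal vs 50 background photons per pixel,
32×32 pixels; FLIM — 256 bins × 50 ps (12.8 ns cycle ≈ 78 MHz repetition),
200 ps pulse (delta-like against the cycle, yet wide enough that the
3-sigma spectral cutoff of 5.6 GHz leaves a usable noise band below the
10 GHz Nyquist), 50 000 cycles (per-cycle flux ≈ 4e-3, pileup negligible),
200 signal photons per pixel, no background, 64×64 pixels for the headline
comparison and 32×32 for parameter recovery.

Deliberately not modelled: detector jitter and afterpulsing, dark-count
structure beyond a uniform background, quantum efficiency (taken as 1),
physically-rendered multipath, vendor file formats. Passing tests therefore
demonstrate correctness of the photon statistics and of the recovery and
fitting machinery — not robustness to real-detector artefacts.

These synthetic fields are also adversarial for block matching in one
specific way: the pseudo-intensity image is *flat* (total photons per pixel
carry no information about depth/contribution band), so similar-cubelet
search is noise-driven and cannot avoid grouping cubelets across band
boundaries. Real scenes with intensity texture give the matcher more to work
with; results here are conservative in that respect.

## Numerical choices

* Unnormalised forward DFTs on every axis; magnitude statistics on the full
  two-sided spectrum (the noise-bound constant presumes identically
  distributed band coefficients).
* Time bins are 0-based half-open intervals `[nΔt, (n+1)Δt)`.
* Inverse-noise-power weights are floored at 1e-30 so noise-free blocks get
  large finite weights; aggregation of a constant field is exact.
* Coates saturation guard `eps = 1e-6` of `N_cycle`; saturated pixels
  flagged in metadata.
* Degenerate guided patches (all-zero) fall back to a flat guide.
* EM convergence: amplitude change below 1e-8 of the per-pixel total, cap
  2000 iterations; near the `β1 ∈ {0,1}` boundaries EM converges only ~1/k,
  which is why the scalar fitter uses bounded Brent with boundary snapping
  instead.
* One master seed; per-pixel child generators spawned deterministically, so
  cubes are reproducible regardless of pixel evaluation order. The recovery
  itself is deterministic.

## Known limitations

* Spectral shrinkage plus the final non-negativity clip leaves a small
  systematic distortion in recovered transients: the rise edge is smeared and
  band-limited residual noise in near-zero tail regions is rectified upward.
  Contribution fits on recovered fluxes inherit a bias of order 0.01–0.03 in
  `β1` from this, concentrated in fast-decay regions; tail-window fitting
  removes the rise-edge part but not the tail rectification.
* On flat-intensity scenes the nonlocal stage's gain over the local stage is
  modest (see the member-separation note above); its full benefit needs
  scenes where intensity actually guides the matching.
* The global analysis likelihood is nearly flat in `(τ1, τ2, β-field)`
  trade-offs at low counts; with a free background offset the shared
  lifetimes are biased (measured above), and with mono-exponential data
  `β1` is unidentifiable (only the effective lifetime is pinned).
* Runtime is dominated by per-anchor FFTs; a 64×64×256 cube takes ~2 min on
  one CPU at stride 1. `stride` 2–4 trades accuracy for a near-quadratic
  speed-up.
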