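# Methods

## Generalized Langevin model of the centroid velocity

The centroid velocity is modeled as

    dv/dt = −β v + α V + σ ξ(t),      dV/dt = α v − γ V,

a 2×2 linear stochastic system per spatial component with white noise only
on v.  The drift matrix C = [[β, −α], [−α, γ]] is symmetric, so the model
is stationary iff both eigenvalues λ± = (β+γ ± √((β−γ)²+4α²))/2 are
positive, i.e. βγ > α²; `GLEParams` enforces this at construction.  The
stationary VAC is φ₊e^(−λ₊τ) + φ₋e^(−λ₋τ) with

    φ± = 2σ² ( e_x,±⁴ / (2λ±) + e_x,₊² e_x,₋² / (λ₊+λ₋) ),

where e_x,± are the x-components of the unit eigenvectors.  We re-derived
this from the stationary covariance of the linear system rather than
transcribing it, and the unit tests verify it against a generic numerical
eigendecomposition and against double quadrature of the continuous VAC.

Parameters (1/s except σ in μm·s^−3/2 and σ_X in μm); the packaged
reference set is the fit to cell-tracking data at 1 s sampling:
α = 0.0741, β = 0.116, γ = 0.0641, σ = 0.266, with σ_X = 0.155 for the
measurement-noise variant.

### Observation model

Two effects separate the observed VAC from the continuous one:

1. **Finite sampling.** The observed velocity is the position difference
   over δt, so the observed VAC is the double integral of the continuous
   VAC over two unit sampling windows.  Per exponential mode this gives
   `e^(−(m−1)λδt)((1−e^(−λδt))/(λδt))²` at lag m ≥ 1 and
   `2(e^(−λδt)−1+λδt)/(λδt)²` at lag 0.
2. **Positional noise.** Additive i.i.d. Gaussian noise on each sampled
   position changes the observed VAC by +2σ_X²/δt² at lag 0 and −σ_X²/δt²
   at lag 1 only.  σ_X here is the RMS magnitude of the 2D noise vector
   (per-component SD σ_X/√2); this is the convention under which the
   lag-0/1 corrections are exact for the vector dot-product VAC, and the
   simulator uses the same convention so that simulation, closed forms and
   fitting are mutually consistent.

### Simulation

Euler–Maruyama at an internal step of 2 ms (configurable), positions
accumulated as the time integral of v, recorded every `sample_interval`,
then positional noise added.  The chain starts at (v, V) = (0, 0) and
discards a burn-in of 10/λ₋ (≈ 870 s for the reference parameters) so that
recorded statistics are stationary; the burn-in multiple is overridable.
All randomness flows through one `numpy` Generator, so a seed fixes the
output bit-for-bit.

### Fitting

`fit_gle_to_vac` minimizes the squared error between the closed-form
sampled VAC and the input curve at lags ≥ `tau_min` (2 s when ignoring
measurement noise — short lags are corrupted in real data — and 0 when
co-fitting σ_X).  For fixed (λ₊, λ₋) the model is *linear* in
(φ₊, φ₋, σ_X²), so those are profiled out by nonnegative least squares on
a 12×12 log-spaced rate grid, the rates refined by Nelder–Mead, the
(λ±, φ±) solution mapped back to (α, β, γ, σ) in closed form (a single
monotone 1D root for the eigenvector weight split), and a final
Levenberg–Marquardt polish run in log-parameter space.  On noiseless
closed-form input the round trip is exact to solver precision (≪ 2%
tested); the multimodality of the raw rate objective is handled by the
grid, with ties broken by MSE.

**Estimator precision.** On *empirical* VAC curves from 35 trajectories ×
3600 s (the study-scale data volume), σ and σ_X are determined to ±2% but
α, β, γ only to ~±8%, with errors flipping sign across seeds — sampling
noise of the VAC, not optimizer bias.  Tests assert recovery at
tolerances matching this precision.

`fit_two_exponentials` fits Φⱼ, Tⱼ mixtures (1–3 components) the same way
(profiled nonnegative amplitudes over multi-start rates) and reports the
Gaussian-error BIC, N·ln(RSS/N) + 2k·ln(N).  The RSS is floored at
(10⁻⁸ × data scale)² so that nested models which both fit a noiseless
curve to optimizer precision are ranked by the parameter penalty.  For
model comparison on empirical VACs the package default window is lags
0–50 s: windows that drop lag 0 or extend to 100 s intermittently prefer
three components because VAC estimation noise is correlated across lags.
Comparisons involving measurement noise should either use the noise-free
simulation or drop lags 0–1, whose σ_X distortion masquerades as a third
component.

## Trajectory statistics

Velocities and accelerations are forward differences at the sampling
interval.  Acceleration is split into components parallel and orthogonal
to the current velocity (2D scalar cross product); zero-speed steps have
no direction and are excluded from direction-dependent statistics.  Speed
statistics bin on left-closed bins of width 0.1 μm/s; empty bins are
reported as missing, not zero, and unbiased SDs require ≥ 2 samples.  The
speed-magnitude autocorrelation is implemented as the raw centered product
(global ensemble mean subtracted), which is a covariance, not normalized
to 1 at lag 0 — a normalized variant sits behind a flag.  σ_G is the
maximum-likelihood SD of a zero-mean Gaussian over the pooled x- and
y-velocity components; under isotropy the speed is then Rayleigh with
mode σ_G and median σ_G√(2 ln 2).  The MSD log–log exponent is fitted by
OLS over lags 10–100 s by default, spanning the crossover between the
fast-decay and persistent regimes.

## Boundary analysis

**Extraction.** Contours come from sub-pixel marching squares on the
binary mask (validated single-component), oriented to positive signed
area, started at the upper-left-most boundary point, and resampled to 500
equal arc-length points.  The raw pixel boundary is stair-stepped, so the
polygon is lightly smoothed (circular Gaussian on the coordinates,
σ = 3 points) before the final resampling; this leaves the perimeter of a
rasterized R = 50 px circle within 0.2% of 2πR.

**Curvature.** Tangent angles by central differences, differentiated over
a ±5-point window and smoothed with a circular Gaussian of σ = 15 points.
The windowed difference telescopes, so the discrete circulation
Σcᵢ·ds is exactly 2π regardless of smoothing.  The heavy smoothing is
deliberate: a digitized circle has genuine flat runs of ~√(8R) px near
axis-aligned arcs, and with the calibration raster used by the synthetic
generator (R = 40–60 px at 256² px) this setting keeps circle curvature
constant to ≤ 5% (SD) with an unbiased mean, while still resolving
protrusion-scale bumps (≥ 0.2 rad wide).  These estimators are our own,
validated on analytic shapes.

**Linking and velocity.** Consecutive frames are aligned by the cyclic
index shift minimizing the mean squared inter-point distance (computed by
FFT cross-correlation, verified against brute force), preserving
orientation, with the current frame re-indexed so the point linked to
previous index 0 becomes index 0.  The normal velocity is the
displacement of same-index points projected on the frame-t outward
normal, divided by the frame interval.

**Front/rear decomposition.** Each frame's velocity profile is fitted
with a periodic joint half-cosine: amplitude A₁ ≥ 0 on a contiguous front
arc and −A₂ ≤ 0 on its complement, both vanishing at the arc ends.  The
two templates have disjoint support, so for a given arc the amplitudes
are independent clipped linear solutions; all 500 start positions are
scanned exactly per candidate arc length (FFT correlation), lengths on a
stride-5 grid with local refinement.

**Wave tracking.** Three-class Otsu on the pooled curvature kymograph
gives thresholds c₁ < c₂ (computed once per movie; the classes are meant
to be stable across time).  Contiguous protrusive runs (c > c₂, periodic)
are linked across frames on index overlap, all overlapping pairs linked,
so splits and merges appear as one-to-many links.  Per link, the angular
velocity is the wrapped difference of the outward-normal angle at the
(possibly half-integer, circularly interpolated) fragment centers over
Δt.  ω_c is the maximum-likelihood exponential scale of |ω| (the sample
mean); a histogram-fit variant is available.  Signed values are not used
because an exponential law is only defined on magnitudes.

**Leading edge.** Per frame, the fragment whose center normal is
circularly closest to the centroid-velocity angle ψ(t); frames with no
fragments or undefined ψ split the record and lifetimes never bridge the
gap.  Break times are frames whose leading fragment is not linked to the
next frame's leading fragment (run boundaries count as breaks); lifetimes
are differences of consecutive break times minus one frame interval, and
τ_d is the left-truncated exponential MLE scale, mean(τ | τ ≥ Δt) − Δt.
The persistence estimate is T_est = 4/(ω_c² τ_d): a velocity angle doing
a persistent random walk with those statistics has direction
autocorrelation exp(−ω_c²τ_d t/4).

The 1D angle-walk generator draws increments of amplitude ωτ/√2 every τ
(binary or Gaussian), which realizes the Gaussian propagator with
Var(Δψ) = ω²τt/2 behind that closed form; a naive ±ωτ step would double
the diffusion and halve the decay time.

## Fourier shape analysis

Outlines are resampled to 160 equal-arc points, rescaled by the uniform
per-mask factor 3000·A/(160·L) (A = pixel count, L = outline length in
px; a unit-perimeter alternative sits behind a flag), centred, and
DFT-transformed as x + iy.  The power spectrum S_k is invariant to
translation, rotation and start point.  Signed modes follow
C_n = q̃_n (n ≥ 1), C₋ₙ = q̃₁₆₀₋ₙ: the centred spectrum has q̃₀ ≈ 0, so
indexing from the first harmonic keeps conjugate pairs aligned.  The PCA
(unbiased covariance, descending eigenvalues, orthonormal eigenvectors
with the largest loading of each component oriented positive) is fitted
once on a reference set and applied frozen.  Reconstruction rebuilds
S = S̄ + ΣPCₘeₘ, clips negatives with a warning, and takes the zero-phase
inverse DFT; the boundary-image rendering rescales the contour to a
sensible raster because the spectrum-unit contour is far off the pixel
scale.  Mode autocorrelations are normalized complex autocorrelations
after mean removal; the reported statistic is the real part, while the
decay time is fitted to the modulus (robust to a rotating phase), by
log-linear regression over the initial above-noise stretch, with `inf`
flagged for non-decaying series.  The coupling C_nm = Ċ₋ₙCₘ − C₋ₙĊₘ
(−n+m = 1) uses forward differences at the frame interval; against the
centroid velocity we report the mean cosine between arg(C_nm) and the
velocity angle plus through-origin proportionality fits of (Re, Im) onto
(v_x, v_y).

## Synthetic data

The generator's job is ground truth, not photorealism: binary masks only,
rasterized at 256² px with cell radius ≥ 40 px so curvature estimation
stays inside its calibration.  Base shapes are star-convex radial
profiles — fan (broad leading edge: +0.30 cos θ − 0.10 cos 2θ), split
(front cleft between two lobes: +0.10 cos θ − 0.36 cos 3θ), dumbbell
(0.75 + 0.45 cos 2θ), trident, disc — all normalized to equal enclosed
area (amoeboid deformation is approximately area-preserving) with
per-family radius multipliers calibrated once so the rescaled fundamental
S₁ matches across families.  With size and fundamental matched, the
leading PCA axes of a mixed set reflect genuine shape differences: PC1
loads on the elongation modes (wavenumbers ±1/2-fold partners) and the
dumbbell family sits strictly highest on it.  Samples jitter the low
shape modes (SD 0.015) and overall size (SD 0.002) and take random
orientations.  Traveling protrusions are Gaussian radial bumps whose
centers advance at programmed angular speeds; ground truth (per-frame
bump angles, speeds, lifetimes, polygon centroids, class labels) is
recorded so every downstream recovery test can be scored without
re-reading the images.

What the generator does not emulate: segmentation errors, cell-cell
contacts, non-star-convex shapes (deeply folded pseudopods), intensity
texture, and uneven frame intervals.  Passing recovery tests therefore
demonstrates the correctness of the estimators on clean single-cell
geometry, not robustness to segmentation artifacts.

## Problem sizes

The test suite and the acceptance script run the trajectory ensemble at
the study scale (35 × 3600 s, 2 ms internal steps); property tests use
smaller ensembles (10–100 trajectories, 400–2500 s, 10–20 ms steps) where
Euler bias is negligible relative to the Monte-Carlo tolerance being
asserted.  Synthetic movies are 60–80 frames at 256–384² px.

## Known limitations

- The GLE rate parameters are weakly identified from realistic data
  volumes (~±8% at 35 × 3600 s); report decay times and weights when
  comparing datasets.
- Curvature smoothing trades locality for digitization robustness;
  features narrower than ~0.2 rad of boundary arc are attenuated.
- Wave statistics assume one cell per frame and a closed, simple boundary;
  masks with holes or touching cells are rejected, not repaired.
- The Otsu thresholds are global per movie; movies with drifting curvature
  scale (e.g. strong cell growth) would need per-window thresholds.
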