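# Methods

This note documents the models, numerical choices, and validation design
of `subangio`, in the order the pipeline runs.

## Angiographic kinetic model

The voxelwise control−label difference signal after a pseudo-continuous
ASL preparation is modeled with four parameters: transit time δt (s) from
the labeling plane to the voxel, gamma-kernel sharpness s (s⁻¹) and
time-to-peak p (s) describing bolus dispersion, and an amplitude A
proportional to local blood volume.  The ideal bolus is a rectangle of the
labeling duration τ; dispersion convolves it with the gamma-variate kernel
D(t_d), which integrates to one and peaks exactly at t_d = p.  The
difference magnetization additionally relaxes with the arterial-blood T1
and is attenuated by every preceding excitation pulse, with the number of
pulses counted as n = ⌊t_d/TR⌋ (capped at the train length) — i.e. all
labeled blood is assumed to experience the pulses played before its
dispersion delay.  The observed amplitude at excitation i carries a
sin αᵢ factor from the variable flip angle.

Conventions and defaults:

* Time origin at the start of labeling; excitation i occurs at
  τ + (i−1)·TR (a configurable gap between labeling end and the first
  excitation defaults to zero).  This places the bolus plateau and its
  sharp trailing edge inside the readout window, which is the regime the
  single-vessel phantom probes.
* Flip schedule: αᵢ = α_min + (α_max − α_min)·((i−1)/(N−1))², a monotone
  quadratic from 3° to 12° over N = 144 readouts.  Small early flips
  preserve longitudinal magnetization for later frames.
* T1 of arterial blood defaults to 1.65 s (a standard value at 3 T);
  configurable.
* Units: seconds internally; degrees at API boundaries, radians inside.
* Labeling efficiency is not modeled — it scales all timecourses equally
  and is absorbed by A.

**Integration.**  R(t_d) is piecewise constant on TR intervals and
D·T is t_d^(p·s)·e^(−λ·t_d) with effective rate λ = s + 1/T1b, so on each
TR interval the integral is an exact difference of regularized lower
incomplete gamma functions.  The per-TR segment integrals are accumulated
once per parameter set and the two integration limits are interpolated
into the cumulative sum, giving machine-accurate timecourses in microseconds
per entry (the 64 000-entry dictionary builds in seconds).  A dense
midpoint-quadrature implementation is kept solely as a test oracle; the
suite checks agreement to 10⁻⁶ (relative to the curve maximum) on 100
random parameter draws with 10⁴ nodes per TR.

## Temporal subspace

The dictionary spans δt ∈ [0.1, 2.0] s, s ∈ [1, 20] s⁻¹,
p ∈ [0.001, 0.5] s with 40 equispaced samples per axis (A is excluded: it
cannot change the span).  Rows are not normalized before the SVD, so
higher-energy entries weight the basis; the sin αᵢ modulation is part of
each row.  The basis sign is fixed per column (largest-magnitude element
positive) for reproducibility.

With K = 12 components the Frobenius relative projection error of the
dictionary is 2.31%, i.e. 99.95% of the dictionary's signal energy is
captured (the suite asserts the Parseval identity between the two).  The
error decreases monotonically in K and is at numerical zero at K = N.
Per-row reprojection error is a few tenths of a percent for typical
entries; a small tail of sharp, low-dispersion entries (small p, large s,
whose trailing edge is steepest) reaches tens of percent — these are the
entries for which any 12-dimensional linear basis is weakest, and the
fitting stage's nonlinear refinement does not depend on the basis.

K = 12 is the default: it matches the unknown count of the 12-bin
baseline, and the per-timepoint residual oscillations visible at K = 4 or
8 are largely gone.

## Sampling geometry

Spoke m (1-based) points along azimuth 2π·frac(m·φ1) and polar angle
arccos(frac(m·φ2)), with φ1 = 1/ψ ≈ 0.6823 and φ2 = 1/ψ² ≈ 0.4656 for the
real root ψ of x³ − x² − 1.  The fractional part is applied before the
trig functions (required for arccos).  Directions cover the upper
hemisphere; spokes are full diameters through the k-space origin, so
sphere coverage is complete.  Samples are uniformly spaced along each
diameter from −0.5 to just under +0.5 cycles/voxel, with 2× readout
oversampling by default (samples per spoke = 2 × matrix size; the count is
a free design choice).

Acquisition order is repeat-first: the global golden index advances over
preparation repeats within a timepoint, m(i, j) = (i−1)·N_rep + j, so each
one-TR frame owns a contiguous golden-ratio run.  The suite verifies that
such runs leave smaller coverage holes (covering radius over probe
directions) than the strided per-frame sets a timepoint-first ordering
would produce.  The "largest angular gap" is measured as the covering
radius — the largest hole a probe direction can sit in — because the
literal largest nearest-neighbour distance rewards clustered sets.

Temporal binning groups bin b from timepoints (b−1)·w+1 … b·w; its center
delay (b−1+½)·w·TR is the post-labeling delay quoted for that frame
(88.2 ms for the first of twelve 12-TR bins).

## NUFFT

No non-uniform FFT library is bundled with the target environment, so the
package implements Kaiser–Bessel gridding: 2× oversampled centered FFT,
width-6 kernel with the Beatty β, and separable deapodization by the
kernel's analytic Fourier transform.  The interpolation weights are built
once into a sparse matrix per coordinate set, so repeated transforms are a
sparse mat-vec plus an FFT, and the adjoint is the exact conjugate
transpose (inner-product identity at machine precision regardless of
kernel accuracy).  Forward accuracy against a direct O(M·N) non-uniform
DFT oracle is ~7·10⁻⁶ relative on an 8³ grid; the oracle stays in the test
suite.

## Reconstruction

Both reconstructions minimize ½‖A x − y‖² + λ Σ ‖Wᵢ(x)‖_* where Wᵢ
extracts non-overlapping cubic patches of the component (or bin) stack and
the nuclear-norm prox is exact SVD soft-thresholding per patch.  Patches
are cyclically shifted by a fixed deterministic schedule across iterations
to suppress blocking.  The squared fidelity term is assumed (it is what a
gradient-based solver of this family minimizes).

* **Subspace operator.**  Per component, the coil-weighted map is
  transformed once at all sample coordinates; the temporal weighting is a
  per-sample multiplication by Φ[t(m), k].  The full frame series is never
  materialized.
* **Toeplitz precombination.**  The normal operator is block-Toeplitz:
  for weights w_k (basis entries or bin indicators), block (k, k′) is a
  circular convolution with kernel Σ_m w_km w_k′m e^{2πi k_m·u}, evaluated
  once on a 2× embedding grid via the adjoint NUFFT.  Solver iterations
  then cost only FFTs, and the quadratic objective value is a free
  by-product.  The binned operator's gram is block-diagonal (one kernel
  per bin).
* **λ = 0** (least squares): preconditioned conjugate gradient.  The
  preconditioner inverts the Toeplitz symbol per frequency as a K×K block,
  with its eigenvalues clipped to a small positive floor first — the
  circulant embedding of a PSD Toeplitz operator need not be PSD, and the
  radial sampling-density spread otherwise slows CG by orders of
  magnitude.
* **λ > 0**: monotone FISTA — accelerated proximal gradient with the step
  from a power-iteration estimate of the operator norm, restarting the
  momentum whenever the objective would increase; the objective trace is
  non-increasing to within 10⁻⁶ per step, and more than five consecutive
  failed restarts raise a divergence error carrying the trace.
* **Initialization**: adjoint of |k|²-density-compensated data, rescaled
  to the least-squares optimum along its own direction; iterations use the
  uncompensated operator.
* **Preprocessing**: k-space is divided by the 95th percentile of its
  pooled magnitude before reconstruction, which is the scale convention
  under which the default weights λ = 5·10⁻⁴ (subspace) and 10⁻¹
  (binning) are meaningful.  In vivo data would be subtracted
  control−tag per trajectory-sharing pair before reconstruction; the
  synthetic path produces difference data directly.  Multi-coil data can
  be PCA-compressed to virtual channels, and coil maps estimated from the
  late-frame mean data by Walsh-style dominant-eigenvector combination
  (per-voxel by default; covariance pooling is available for noisy data
  but biases phase-varying regions).
* Coefficients are complex with a real temporal basis; no phase
  constraint is imposed.

Defaults: 100 iterations, 6³ patches.  The test suite runs 4³ patches on
a 12³ grid, where 250 iterations bring the subspace objective close to its
floor.

## Single-vessel phantom

A one-voxel-wide line through the volume center along one grid axis, with
linear ramps δt 0.25→1.8 s, p 0.1→0.5 s, s 1→10 s⁻¹ and A = 1 on the
vessel (zero elsewhere): increasing arrival delay and dispersion
downstream, as in a real artery.  The 4D series is the kinetic-model
timecourse per vessel voxel; it represents the difference signal directly,
and the simulation is noiseless by default (seeded complex Gaussian noise
is available and bit-reproducible).  K-space is simulated frame by frame
with the forward NUFFT at each timepoint's own spokes.

Scales: the library defaults target a 64³ desk-scale grid with 32
repeats (the in-sequence 1.13 mm/~180³ geometry is configurable but
slow); the test suite runs the full paired comparison at 12³ with 32
repeats and 24 samples per spoke, which preserves every qualitative
feature of the comparison (the vessel spans 12 voxels with the same
parameter ramps) at a cost of minutes.

What the phantom does not emulate: vascular trees and branching, partial
volume, motion, off-resonance, gradient imperfections, background tissue,
and measurement noise in the default configuration.  Passing tests
therefore demonstrate correctness of the operators, solver, and fitting
machinery and the direction of the subspace-versus-binning comparison —
not in vivo image quality.

## Parameter fitting

Exhaustive normalized-correlation matching against the dictionary
initializes (δt, s, p), with A from least-squares scaling; bounded
nonlinear least squares (trust-region reflective) refines all four.
Magnitudes of complex timecourses are fit; bounds (δt ∈ [0.05, 2.2] s,
s ∈ [0.5, 25] s⁻¹, p ∈ [10⁻³, 0.6] s, A ≥ 0) slightly exceed the
dictionary ranges to avoid boundary pile-up.  The refinement never returns
a worse residual than its initialization.  Voxels are fit where the peak
magnitude exceeds a threshold fraction (default 0.2) of the global
95th-percentile peak, or inside an explicit mask.

Binned series are fit against the model sampled at each bin's center
timepoint — the frame's quoted post-labeling delay — which is how binned
frames are interpreted downstream.  This convention is what produces the
characteristic binning bias (plateau flattening and missed peaks) that the
paired comparison quantifies; fitting bin-averaged model curves instead
would partially hide it.

On noiseless model curves the fit recovers all four parameters to better
than 1% across the physiological ranges (50 random draws in the suite).

## Evaluation design

* **PSF**: intensity profile along one axis perpendicular to the vessel,
  through the mid-vessel voxel, at the frame of peak vessel signal;
  peak-normalized; FWHM by linear interpolation; sidelobe level is the
  maximum outside ±2 voxels of the peak.
* **Timecourse NRMSE**: per-voxel RMS error of magnitudes normalized by
  the truth RMS; binned frames are compared against the truth averaged
  over each bin's window; summaries are means over the vessel mask.  All
  metrics are invariant to a global complex phase.
* **Unregularized-recovery check**: radial spokes never sample the
  Cartesian corner frequencies (beyond the |k| ≤ 0.5 ball), and signal
  outside the temporal subspace is not representable, so pure least
  squares on raw phantom data is an inconsistent problem whose iterates
  semiconverge.  The solver-correctness test therefore simulates data
  from the subspace-projected, ball-limited series — the recoverable
  ground truth — and requires ≤ 2% NRMSE per vessel voxel plus a
  ≤ 10⁻⁴ relative data residual.
* **Regularization sweep**: λ ∈ {10⁻⁴, 5·10⁻⁴, 10⁻³, 10⁻²} on identical
  scaled data; mean absolute relative parameter errors along the vessel;
  the suite asserts 5·10⁻⁴ is not worse than 10⁻² for any parameter.
* All subspace/binning comparisons are paired on the same simulated
  k-space data.

## Known limitations

* The gridding NUFFT is single-threaded numpy/scipy; the in-sequence
  ~180³ geometry is feasible but slow, and Toeplitz kernels at K = 12 on
  large grids are memory-hungry (K² /2 real volumes on the 2× grid).
* The LLR prox uses non-overlapping shifted patches, not fully
  overlapping patches (cycle spinning across iterations approximates the
  latter).
* Uncertainty estimates for fitted parameters are out of scope; the fit
  is a point estimate.
* The one-voxel vessel makes the sidelobe level a fragile metric at small
  grids; only the main-lobe width ordering is asserted.
* Cone (non-radial) trajectory design, scanner raw-data parsing, and
  perfusion-signal modeling are out of scope.
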