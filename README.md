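# subangio

Subspace-constrained reconstruction of 4D arterial-spin-labeling (ASL)
dynamic angiography at one frame per repetition time.

## The problem

Non-contrast 4D angiography with pseudo-continuous ASL acquires a train of
~144 radial readouts (TR = 14.7 ms) after each 1.8 s labeling period,
following a 3D golden-ratio spoke schedule.  A single TR holds far too few
spokes to reconstruct a volume on its own, so frames are conventionally
"binned" over ~12 adjacent TRs — sacrificing temporal resolution and
blurring the passage of the blood bolus.

`subangio` instead represents every voxel's signal timecourse in a
low-dimensional temporal subspace derived from an angiographic kinetic
model, and reconstructs the subspace coefficient maps directly from all
spokes jointly.  The result is a 4D angiogram with one frame per TR
(14.7 ms temporal resolution) plus voxelwise hemodynamic parameter maps.

## The model and the method

**Kinetic model.**  The control−label difference signal of blood arriving
in a voxel with transit time δt is the labeled bolus (a rectangle of the
labeling duration τ) dispersed by a gamma-variate kernel with sharpness
*s* (s⁻¹) and time-to-peak *p* (s),

    D(t_d) = s / Γ(1 + p·s) · e^(−s·t_d) · (s·t_d)^(p·s),   t_d > 0,

attenuated by T1 decay of arterial blood, T(δt, t_d) = exp(−(δt+t_d)/T1b),
and by the preceding variable-flip-angle excitations,
R(t_d) = Π cos αᵢ over n = ⌊t_d/TR⌋ pulses.  The signal at excitation *i*
(flip αᵢ, time *t* after labeling onset) is

    S(t) = A · sin αᵢ · ∫ D(t_d) T(δt, t_d) R(t_d) dt_d

over the bolus window t_d ∈ [t−δt−τ, t−δt].  Because R is piecewise
constant on TR intervals and D·T is a gamma-form integrand with rate
s + 1/T1b, the integral evaluates exactly as regularized incomplete-gamma
differences — no quadrature in the hot path.

**Temporal subspace.**  A dictionary of 40³ timecourses over δt ∈
[0.1, 2.0] s, s ∈ [1, 20] s⁻¹, p ∈ [0.001, 0.5] s is compressed by SVD;
the first K = 12 right singular vectors Φ form the basis, and every frame
series is represented as x ≅ Φα.

**Reconstruction.**  Coefficient maps α solve

    min_α ½‖P F C Φ α − y‖² + λ Σᵢ ‖Wᵢ(α)‖_*

with non-uniform Fourier sampling P F (Kaiser–Bessel gridding NUFFT), coil
maps C, and locally-low-rank (LLR) regularization over spatial patches of
the coefficient stack.  The temporal weighting commutes with the spatial
transform, so the normal operator is precombined into per-component-pair
Toeplitz kernels and iterations run entirely in the subspace domain —
monotone FISTA for λ > 0, preconditioned CG for λ = 0.  The temporal-binning
baseline solves the same problem with per-bin frames in place of Φα.

**Parameter fitting.**  Voxelwise (δt, s, p, A) are estimated by exhaustive
dictionary correlation followed by bounded nonlinear least squares on the
timecourse magnitude.

## Worked example

A one-voxel-wide vessel through the volume center with linearly varying
kinetics (δt 0.25→1.8 s, p 0.1→0.5 s, s 1→10 s⁻¹) is simulated, acquired
with golden-ratio radial spokes, and reconstructed both ways:

```python
import numpy as np
import subangio as sa

seq = sa.SequenceParams()   # TR 14.7 ms, 1.8 s labeling, 144 readouts, 3-12 deg flips
phi1, phi2 = sa.golden_means()
print(f"3D golden means: phi1={phi1:.4f}, phi2={phi2:.4f}")

dictionary = sa.build_dictionary(sa.parameter_grid(), seq)
subspace = sa.extract_subspace(dictionary, 12)
err = sa.relative_error(dictionary, subspace)
energy = 100 * (1 - (err / 100) ** 2)
print(f"dictionary {dictionary.matrix.shape}: K=12 relative error {err:.3f}% "
      f"({energy:.2f}% of signal energy captured)")

phantom = sa.make_vessel_phantom(12)
series = sa.phantom_series(phantom, seq).astype(complex)
sampling = sa.build_sampling(seq, n_repeats=32, matrix_size=12,
                             samples_per_spoke=24)
data, factor = sa.scale_kspace(sa.simulate_kspace(series, sampling))
coeffs, trace = sa.reconstruct_subspace(
    data, sampling, subspace,
    config=sa.ReconConfig(lam=5e-4, n_iterations=250, patch_size=4))
frames = sa.expand(coeffs, subspace) * factor
binned, _ = sa.reconstruct_binned(
    data, sampling,
    config=sa.ReconConfig(lam=1e-1, n_iterations=100, patch_size=4,
                          bin_size=12))
binned = binned * factor

mask = np.abs(series).max(axis=0) > 0
_, nrmse_sub = sa.timecourse_nrmse(frames, series, mask)
_, nrmse_bin = sa.timecourse_nrmse(binned, series, mask)
print(f"vessel timecourse NRMSE: subspace {nrmse_sub:.3f} vs binned {nrmse_bin:.3f}")
print(f"PSF FWHM: subspace {sa.psf_profile(frames, phantom).fwhm:.2f} vs "
      f"binned {sa.psf_profile(binned, phantom).fwhm:.2f} voxels")

maps = sa.fit_volume(frames, seq, dictionary, mask=mask)
vi = phantom.vessel_indices
print("fitted transit times along the vessel (s):",
      np.round(maps.delta_t[vi][maps.mask[vi]], 2))
```

Output of this exact script:

```
3D golden means: 0.6823, 0.4656
dictionary (64000, 144): K=12 relative error 2.307% (99.95% of signal energy captured)
vessel timecourse NRMSE: subspace 0.150 vs binned 0.177
PSF FWHM: subspace 1.13 vs binned 1.17 voxels
fitted transit times along the vessel (s): [0.26 0.38 0.51 0.63 0.76 0.89 1.02 1.15 1.28 1.43 1.6  1.79]
```

The golden means are the azimuthal/polar increments of the spoke schedule;
the K = 12 basis captures 99.95% of the dictionary's signal energy; the
one-TR subspace frames track the vessel's timecourses more closely than
12-fold binning (lower NRMSE, thinner cross-vessel point-spread function);
and the fitted transit times recover the simulated 0.25→1.8 s ramp.

## Command line

```bash
subangio traj     --config seq.yaml -o traj.h5      # golden-ratio sampling
subangio dict     --config seq.yaml --k 12 -o subspace.h5
subangio simulate --config sim.yaml -o run/         # phantom + k-space
subangio recon    --mode subspace --data run/kspace.h5 \
                  --subspace subspace.h5 -o out/    # NIfTI frames + maps
subangio fit      --images out/frames.nii.gz --config seq.yaml -o maps/
subangio eval     --truth truth.nii.gz --recon out/frames.nii.gz -o report/
```

Every command writes a JSON sidecar with its fully resolved configuration.

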