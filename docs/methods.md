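# Methods

## Model

Light transport through a thin diffusive layer is linear: with `N`
orthonormal input modes and `M` camera pixels, the transmission matrix
`T ∈ C^{M×N}` maps incident-mode coefficients `x = (α_1…α_N)` to the
diffused field `y = T x`, and the camera records `I = |y|²`. The method
rests on two assumptions:

1. **Gaussian speckle.** The diffused fields `t_p` behave as circular
   complex Gaussian random fields over the camera plane, so mixed fourth
   moments factor into sums of products of second moments (the Gaussian
   moment theorem; `moment_identity_check` verifies this empirically).
2. **Quasi-orthogonal columns.** Spatial correlations between distinct
   columns average to `O(1/√M)`, adequate for a thin diffuser; residual
   physical correlations can be whitened with
   `calibration.filter_correlated_modes`.

Under these, the speckle-correlation scattering matrix
`Z = (1/M) T† diag(I) T` has expectation `x x† + mean(I)·Id` plus a
fluctuation of order `1/√γ`, `γ = M/N`, so its leading eigenvector
estimates `x`. The Monte-Carlo residual of the plain spectral estimate is
`1 − corr ≈ 2.9/γ` (measured over 50 seeds, independent of `N` at fixed
`γ`); the vector error decays as `γ^{-1/2}`. This intrinsic noise is what
the Gerchberg–Saxton refinement removes: on noiseless synthetic scenes the
refined correlation exceeds 0.9999 already at `γ = 32`.

## Synthetic diffuser and measurement

- `generate_tm` draws i.i.d. circular complex Gaussian entries and rescales
  each column to unit mean square modulus, `(1/M)Σ_m|t_{p,m}|² = 1`, so
  spatial correlation against `y` estimates `α_p` with no extra factor.
  Mesoscopic (random-matrix) correlations and speckle-grain oversampling
  are deliberately not modeled: rows are independent, matching a sensor
  whose speckle grain is about one pixel.
- **Noise model.** SNR is defined per array as `mean(signal)/sd(noise)`:
  intensity noise is additive white Gaussian with `sd = mean(I)/snr`;
  TM noise perturbs entries with complex Gaussian
  `sd = rms(|T|)/snr`. Negative noisy intensities are preserved — clipping
  would bias the second moments that Z is built from. The only place
  negatives are floored is inside the GS amplitude constraint `√max(I,0)`,
  where the amplitude must be real.
- **Seeding.** One user seed expands into independent per-stage streams via
  `SeedSequence` spawn keys, so the TM draw, the phantom, and each noise
  source are individually reproducible.

What the generator does *not* emulate: physically rigorous scattering
(thickness, mean free path, memory effect), SLM pixelation, interferometer
drift, detector nonlinearity, shot noise, or co-registration errors between
tilted illuminations. Passing tests therefore demonstrate the mathematics
of the retrieval under the stated statistical model, not end-to-end
hardware performance.

## Calibration

Three-step phase-shifting with delays `{0, 2π/3, 4π/3}` (the standard
equally-spaced scheme; configurable). The closed form
`t·R* = (1/3) Σ_k I_k e^{iθ_k}` was verified against a brute-force
least-squares fit of the interferogram model before being frozen into the
estimator. Dividing by `|R|` from the sample-arm-blocked frame compensates
the reference amplitude; the remaining per-pixel phase `e^{-i arg R}` is
common to every TM column and cancels exactly inside the Z quadratic form
(`T† diag(I) T` is invariant under `T → diag(e^{-i arg R}) T`), so
retrieval from a calibrated TM equals retrieval from the true TM. Pixels
whose reference intensity falls below `1e-12 × max` raise a
degenerate-reference error rather than silently amplifying noise.

`filter_correlated_modes` whitens singular directions deviating from the
bulk median by more than a user factor, rescaling them to the median rather
than deleting them, so the retrieval basis keeps its size.

## Retrieval numerics

- `build_ssm` symmetrizes `(Z+Z†)/2` (round-off only; asymmetry logged)
  and, by default, subtracts `mean(I)·Id`. The shift leaves eigenvectors —
  hence retrieval — provably unchanged; it only makes the noiseless Z
  numerically rank one. `N_Z = M` (plain spatial average): any positive
  constant rescales amplitudes without moving the eigenvector.
- `retrieve_field` uses a full Hermitian eigendecomposition up to
  `N = 4096` and an iterative leading-pair solver above (tolerance 1e-10,
  max 10,000 matvecs; the tail median is then approximated from the trace).
  The unit eigenvector is scaled by `√max(λ1 − median(λ2…λN), 0)` — the
  tail median being the robust estimate of the uniform eigenvalue shift —
  and the global phase is fixed by rotating the largest-magnitude
  coefficient to zero phase (ties: lowest index). Leading eigenvalues tied
  within 1e-9 relative raise a degenerate-spectrum error.
- `gs_refine` defaults to the Moore–Penrose back-projection (precomputed
  once), which carries the classical error-reduction guarantee of a
  non-increasing speckle-plane residual; the `(1/M) T†` adjoint mode is a
  cheaper approximation that coincides with pinv as `γ` grows (measured
  agreement 0.87/0.97/0.993 at `γ` = 16/64/256). Stopping: successive-
  iterate correlation above 0.999998, capped at 1000 iterations (flagged,
  not raised).

## Rendering and refocusing

Modes sit on a centred spatial-frequency grid, row-major over `(f_y, f_x)`,
even counts placing the extra mode on the negative side; synthesis uses
orthonormal FFTs so `‖field‖ = ‖α‖` exactly and projection is an exact
left inverse. Units are mm (lengths), nm (wavelength) and cycles/mm, with
the origin at the grid centre.

Angular-spectrum propagation multiplies the spectrum by
`exp(i2πz√(1/λ² − f²))`; evanescent components are zeroed by default
(far-field geometry) with an exponential-decay alternative. It is unitary
on the propagating band and additive in `z`. Focal stacks propagate the
original field to each plane independently (no chaining of round-off).

**Focus metric.** The package's sharpness score is the mean gradient
magnitude of the amplitude divided by the region's mean amplitude. The
unnormalized gradient is a total-variation measure that *grows* as
defocused coherent light spreads fringes across the region (verified on
the two-plane test scene, where it dips at focus); normalizing turns it
into a characteristic spatial frequency that peaks at each object's plane.

**Compounding** propagates each independently speckled hologram to the
common plane and averages amplitudes pixelwise (mean, not RMS — the common
speckle-compounding choice; configurable by composing with numpy). For
fully developed speckle the contrast falls as `1/√K`.

## Study conditions and problem sizes

The noise-tolerance sweep defaults to desk scale `N = 256` with 20
repetitions per cell, γ on powers of two up to 64 and SNR grid
`{1, 3, 10, 30, 100, ∞}`; the Z build cost scales as `M·N²`, and these
sizes keep a full sweep in minutes on one core while reproducing the
qualitative surfaces (γ-monotone recovery, SNR = 1 robustness at large γ,
GS dominance at small γ / high SNR). The reference sensor bookkeeping
(66×60 modes over 5.28×4.00 mm, 512×512 pixels, hence γ = 66.2 and an
80 μm spot; 3N+1 = 11,881 calibration frames) is asserted at full N with a
reduced synthetic camera, since a full 262,144×3,960 complex TM (16.6 GB)
exceeds the library's 4 GB allocation budget, which `generate_tm` enforces
with a resource error.

## Known limitations

- The spectral (SSM-only) estimate carries an `O(1/γ)` correlation deficit
  with raw-intensity weighting; regimes below `γ ≈ 4` are noisy and `γ < 1`
  is unsupported.
- Error-reduction refinement is a local method: at very low SNR or tiny γ
  it can stall at the max-iteration cap (flagged in the result).
- The phase retrieved is relative: a global phase (and the reference phase
  at calibration time) is unobservable by construction.
- Angular compounding assumes co-registered holograms; registration of
  tilted-illumination acquisitions is out of scope, and the synthetic
  stand-in uses independent speckle realizations instead.
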