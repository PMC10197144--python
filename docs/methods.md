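# Methods

## The design problem

A GRIN-objective miniscope images a ~15–20 µm slab of tissue sharply; neurons
outside that slab blur into background. `edofmask` designs a **binary
(0/π) pupil-phase element** that, glued to the objective's back aperture,
stretches the usable depth range several-fold while keeping the optic
passive, thin and fabricable by single-step photolithography. The design
loop is: compose a continuous pupil phase from a three-term basis, binarize
it, push an on-axis neuron-sized source through a Fourier-optics forward
model over a stack of depths, and score how well the axial signal holds up
over a target depth band. A small elitist genetic algorithm (GA) searches
the three coefficients.

## Forward model

The simulated intensity at depth `z` is

```
I(x,y;z) = | F⁻¹{ F{O} · M(u,v) · e^{iA(u,v)} · e^{i·defo(u,v;z)} } |² · e^{-(z-z₀)/ls}
```

* `O` — the source: a uniform disk of diameter 0–10 µm (default 5 µm, a
  proxy neuron) on the object-space lattice (pixel = sensor pixel /
  magnification = 3.45/9.2 = 0.375 µm), normalized to unit energy.
* `M` — the candidate pupil: the ±1 transmission of the binary mask, or a
  single diffraction order `e^{±iφ}` for twin-foci analysis.
* `A` — the native objective aberration, modeled as primary (Seidel)
  spherical aberration `2π·W040·ρ⁴` with `W040 = 29.4` waves at the pupil
  edge (`ρ` = NA-normalized pupil radius), the value a ray-trace of the
  0.55 NA GRIN objective predicts. Higher even radial orders can be added
  but default to zero.
* `defo` — the exact angular-spectrum defocus kernel
  `(2πn/λ)·z·√(1-(λu/n)²-(λv/n)²)`, `n = 1.33`.
* `e^{-(z-z₀)/ls}` — scattering loss with mean free path `ls = 100` µm
  (neural tissue), referenced to the shallowest simulated plane. PSF
  broadening by scattering is neglected (sub-one-mean-free-path imaging).
  Because a shift of the reference plane only rescales the whole stack,
  FWHM and fitness readings do not depend on the choice of `z₀`.

The object sits *inside* the field transform: the model is coherent, which
is an approximation for fluorescence but makes each depth a single FFT and
is the model the binary mask is optimized under. Transforms are
orthonormal, so with a unit-modulus pupil over the full lattice and no
decay the per-slice energy is exactly conserved (asserted to 1e-9 in the
tests).

The sign convention places the +1-order extended focus *in front of* the
nominal focal plane (negative `z`, shallower, less attenuated) and the −1
order behind it (deeper, more attenuated), matching the asymmetry the twin
foci show in practice.

### Simulation window

The reference design configuration specifies 100 depth planes at 1 µm and a target
extension of 80 µm in the first diffraction order, but not where the window
sits relative to the nominal focus. We reconstructed the placement
self-consistently: with the window at `z ∈ [-180, -81]` µm and the target
band `z_target = [-180, -100]` µm, the reference coefficient set (26.65
waves spherical, 129 µm defocus) is within two cost units of the best mask
found by a dense coefficient scan. These are the package defaults
(`OpticalConfig.z_start_um = -180`, `FitnessSpec.z_target = (-180, -100)`);
both are plain config fields.

## Binary mask and diffraction orders

The continuous phase `axi + defo + γ` is wrapped into `[0, 2π)` and
thresholded at π (half-open rule: `[0,π) → 0`, `[π,2π) → π`), a
deterministic, idempotent operation. The resulting transmission is exactly
±1. A two-level profile diffracts the conjugate pair `e^{+iφ}` and
`e^{-iφ}` (plus weaker odd orders), so one designed phase yields **twin
foci**: with the learned +26.65 waves of spherical aberration the +1 order
*exaggerates* the native 29.4 waves and stretches far, while the −1 order
largely cancels it and stays compact; opposite 129 µm defocus terms push
the two foci apart so their axial profiles do not overlap and the total
depth of field is the sum of the two FWHMs.

## Fitness and the genetic algorithm

A candidate's stack is reduced to its per-depth maximum-intensity profile;
a depth is "on" when it reaches half the stack maximum. The cost is
`-(on-depths inside z_target) + α·(on-depths outside)`, `α = 4`. A
voxel-count variant (every voxel above half-max is counted) is available
via `FitnessSpec(mode="voxel")`; the per-depth profile reading is the
default. Thresholding against the in-window maximum makes the cost
scale-invariant, so the decay reference plane drops out here too.

The GA is the elitist ("queen bee") variant: per generation of M = 60, the
best `round(0.2·M) = 12` pass unchanged (so the best cost is monotone —
asserted for every seed), `floor(0.4·48) = 19` are crossover children
(per-trait uniform pick between the two best of a 4-candidate tournament)
and the remaining 29 are mutation children (a tournament child whose traits
are each re-drawn uniformly from the bounds with probability 0.1). Default
bounds: axicon ∈ [0, 5], defocus ∈ [-300, 300] µm, spherical ∈ [-60, 60]
waves. Initialization is uniform over the bounds; ties break toward the
earlier index; all randomness flows through one seeded generator, so a run
is exactly reproducible from its seed. Because a mask depends on the
coefficients only through the wrapped sum, the mask of `-p̄` equals the mask
of `p̄`; only coefficient *magnitudes* are physically meaningful.

A note on what the GA finds: under these bounds the search reliably
discovers mask families with a **non-negligible axicon term** that cover
the entire target band (cost at the theoretical floor), scoring strictly
better than the axicon-free spherical+defocus family. A dense scan over
2,146 coefficient triples, evaluated under 115 window/target placements,
found no placement where the axicon-free family wins. Runs with different
seeds therefore land in the axicon family, typically with |spherical| ≈
45–60 waves and |defocus| ≈ 95–125 µm. The acceptance script reports these
recovered magnitudes as computed.

## Characterization

The recoverable depth range is the FWHM of the axial optical signal: the
stack is resliced to xz, maximum-projected, and the z line through the
lateral peak is extracted; half-max crossings are found by linear
interpolation with no smoothing. For twin foci, peaks must be ≥ 5 axial
steps apart and ≥ 20% of the global maximum; each focus is measured on its
side of the inter-peak midpoint and the total DoF is the sum. One-sided
profiles (no crossing within the window) are flagged rather than guessed.
Lateral resolution is summarized by the azimuthal mean of the xy MIP
(verified against the Airy half-width for an unaberrated point source).
SBR is mean-signal over mean-background on user or Otsu-segmented regions —
the conventional contrast summary, since no standard definition exists.

Under the defaults, the +1-order focus of the reference coefficient set has
an axial FWHM of **71.0 µm** (grid-converged between 512² and 1000²,
identical in single and double precision) — between the 80 µm the design
aimed for and the 67 µm measured on the bench instrument. The gap to 80 µm
persists under every modeling convention we varied (decay reference,
emission wavelength within the filter band, profile definition) and is
reported as computed.

## Post-filtering

Extended-depth frames carry extra diffuse background. The negative
Laplacian-of-Gaussian kernel `-∇²G_σ` has zero DC response and a positive
center lobe `1/(πσ⁴)`, so flat background vanishes and bright blobs whose
radius matches σ become positive peaks (σ defaults to 8 px; choose ≈ half
the object diameter in pixels). The analytic kernel is truncated at ±4σ
(<1e-7 truncated mass) and the tiny residual lattice DC is subtracted so a
constant image filters to exactly zero. Convolution is linear (reflect
padding, cached frequency-domain kernel). Particle extraction thresholds at
mean + 2·std of the filtered frame, labels connected components and drops
those smaller than a disk of the minimum diameter; touching objects merge —
a stated limitation, not a bug.

## Synthetic phantoms

`phantom` emulates the bead-in-scattering-resin samples used on the bench:
5 µm (or 10 µm) fluorescent beads at ~2120 particles/mm³, scattering set by
1.1 µm polystyrene spheres (n = 1.5979) in clear resin (n = 1.5403). Bead
counts are Poisson with mean density x volume; positions are uniform in a
rectangular slab (the physical sample was a spherical cap, but the imaging
model is shift-invariant, so geometry only gates placement). The rendered
measurement convolves each depth slice of the scene with the PSF slice at
that depth and sums — the 2D-to-2D compression the mask is designed for —
then adds a 5% background pedestal, photon-shot noise at ~1000 peak photons
and 1% Gaussian read noise (no bench camera noise figures are available;
these are ordinary 16-bit-sCMOS-like defaults).

The scattering mean free path follows `ls = 2d/(3·Φ·Qs)`; `Qs` comes from
an in-package Lorenz–Mie series (validated against a standard reference
case to four significant figures and against the Rayleigh limit). At the
default 0.515 µm the recipe's implied `Qs = 0.292` gives `ls ≈ 118` µm
rather than the nominal 100 µm; the 100 µm figure would require
`Qs = 0.345`, reached only below ~0.49 µm. The package reports what the
series gives. `contact_print_resolution` (`d = k√(λh)`) is included as the
lithography rule-of-thumb used when printing the mask; it makes no claim
about any particular process.

## What the synthetic data does and does not show

The phantom generator reproduces the *geometry and statistics* of the bench
samples (bead size, density, depth distribution, scattering decay,
shot/read noise) but not off-axis aberrations, field-dependent
illumination, refractive-index mismatch or detector fixed-pattern effects.
A passing end-to-end test (masked-pupil recall exceeding open-pupil recall
for beads beyond the native depth of field, ≥90% recall inside the
extension band on a seeded ~50-bead scene) validates the design logic and
the processing chain, not absolute bench performance.

## Numerical choices

* Orthonormal FFTs; zero frequency at index N/2 (even N) per `fftshift`.
* Evanescent frequencies (beyond `n/λ`) get zero defocus phase; they are
  unreachable inside the NA support since NA < n.
* GA evaluations run in single precision (complex64) with per-candidate
  memoization; characterization defaults to double precision. The two
  agree to well below one axial step on the design FWHM.
* Problem sizes: acceptance-grade runs use a 512² grid for forward
  characterization and 256² for GA recovery (three seeds); unit tests use
  64–256². These sizes are grid-converged for every quantity asserted.
* Degenerate inputs are rejected loudly: all-zero stacks (undefined
  maximum), non-finite phases, overdense bead volumes (>50% fill),
  undersampled pupils (N < 32), NA ≥ n.

## Known limitations

* Coherent-object forward model (see above): faithful to the design
  method, approximate for incoherent fluorescence.
* Only the ±1 orders of the binary profile are analyzed; higher odd orders
  exist but carry ≤ (1/3)² ≈ 11% of the ±1 energy each.
* On-axis design only: no field-dependent aberrations, so off-axis PSF
  degradation is out of scope.
* The GA's axicon-bearing optima outperform the axicon-free family under
  this model; see the note under the genetic algorithm.
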