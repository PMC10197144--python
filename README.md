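# edofmask

Design and characterization of **binary pupil-phase diffractive elements
(DOEs) that extend the depth of field of GRIN-lens miniscopes**.

Head-mounted one-photon miniscopes image neural activity through a high-NA
(0.55) gradient-index objective whose depth of field is only ~15–20 µm,
while neurons are spread through hundreds of microns of tissue. A thin
two-level (0/π) phase mask glued to the objective's pupil can stretch the
usable depth range several-fold without moving parts, extra weight or a 3D
reconstruction step. This package implements the full computational side of
that approach, for optical designers and systems-neuroscience tool builders:

* a Fourier-optics forward model of the masked, aberrated objective —
  `I(x,y;z) = |F⁻¹{F{O}·M·e^{iA}·e^{i·defo(z)}}|²·e^{-z/ls}` — including the
  GRIN lens' spherical aberration (W040 = 29.4 waves), the exact
  angular-spectrum defocus kernel and exponential scattering loss
  (ls = 100 µm in tissue);
* composition and binarization of the pupil phase from the three standard
  extended-DoF kernels (axicon, defocus, primary spherical aberration), and
  the conjugate ±1 diffraction-order decomposition that gives a binary mask
  its twin foci;
* an elitist ("queen bee") genetic algorithm minimizing
  `cost = -Σ_{z∈target} 1[I(z) ≥ 0.5·Imax] + 4·Σ_{z∉target} 1[I(z) ≥ 0.5·Imax]`
  over 10 generations of 60 candidates (20% elite, tournament of 4, 10%
  per-trait mutation, 0.4 crossover fraction);
* characterization: axial FWHM / depth-of-field measurement by xz reslice +
  maximum-intensity projection, twin-foci accounting, radially averaged
  lateral resolution, signal-to-background ratio;
* a zero-DC Laplacian-of-Gaussian post-filter with cached transform and
  particle extraction, for pulling blob-like fluorescent objects out of the
  raised background that depth compression produces;
* a seeded synthetic phantom generator (fluorescent beads in scattering
  resin, Lorenz–Mie scattering-length calculator) so the whole design →
  image → filter → detect chain can be validated end to end with known
  ground truth.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate the reference mask design — +26.65 waves of spherical aberration
and a 129 µm defocus displacement, zero axicon — and measure the axial
extent of its +1st-order focus for a 5 µm source in scattering tissue:

```python
import numpy as np
from edofmask import (OpticalConfig, AberrationModel, BasisCoefficients,
                      make_pupil_grid, grin_aberration, order_field,
                      make_source, simulate_stack)
from edofmask.characterize import axial_signal, fwhm

config = OpticalConfig(grid_size=512, z_start_um=-230.0, n_depths=200)
grid = make_pupil_grid(config)
coeffs = BasisCoefficients(axicon=0.0, defocus_um=129.0, spherical_waves=26.65)

stack = simulate_stack(
    make_source(5.0, config),
    order_field(coeffs, +1, grid, config),          # isolate the +1 order
    grin_aberration(AberrationModel(w040=29.4), grid),
    config.depths(), ls=100.0, config=config, grid=grid,
    working_dtype=np.complex64,
)
width, _ = fwhm(axial_signal(stack), config.depth_step_um)
print(f"+1st-order axial FWHM: {width:.1f} um")
```

```
+1st-order axial FWHM: 71.0 um
```

So the exaggerated-aberration order alone keeps the signal above half
maximum over ~71 µm of depth — versus roughly 15–20 µm for the bare
objective near focus — and the −1 order adds a second, more compact focus
on the other side of the nominal focal plane.

The same comparison end to end on a synthetic scattering phantom
(`edofmask pipeline`, or `run_pipeline` in the API) prints, for a seeded
~50-bead scene (192 µm field, beads spread through the mask's 100 µm
extension band — the configuration the end-to-end tests use):

```
Ground-truth beads: 45
Overall recall — masked pupil: 0.89, open pupil: 0.36
```

i.e. after LoG filtering and particle extraction, the masked system
recovers ~89% of beads spread over a 100 µm depth band where the bare
objective finds ~36%.

A full design run from the shell:

```
edofmask init-config design.yaml
edofmask design design.yaml --out design_out/
```

writes the optimized coefficients (`result.json`), the 1-bit mask image and
its ring-radius table (for lithography), the per-generation fitness history
and a run manifest with config snapshot, seed and output hashes.

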