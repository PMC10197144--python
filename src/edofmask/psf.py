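"""Fourier-optics forward model of the masked, aberrated miniscope.

For each simulated plane z the on-axis source is transformed to the pupil
plane, multiplied by the candidate pupil field, the native objective
aberration and the angular-spectrum defocus kernel at z, transformed back,
and squared in modulus:

    I(x, y; z) = | F^-1 { F{O} * M * e^{iA} * e^{i defo(z)} } |^2 * e^{-(z - z0)/ls}

The trailing exponential models the intensity lost to scattering as the
source sits deeper in the sample (z0 is the shallowest simulated plane);
broadening of the PSF by scattering within one mean free path is neglected.
The object sits inside the field transform — a coherent-imaging reading of
the model — which keeps the evaluation a single FFT per plane and is the
approximation the mask design rests on.

Transforms use orthonormal scaling so Parseval's identity holds exactly:
with a unit-modulus pupil over the full lattice and no decay, per-slice
energy equals the source energy at every z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .optics import OpticalConfig, PupilGrid, defocus_phase, make_pupil_grid

__all__ = [
    "SourceObject",
    "IntensityStack",
    "make_source",
    "simulate_stack",
    "on_axis_profile",
    "centered_fft2",
    "centered_ifft2",
]


def centered_fft2(field: np.ndarray) -> np.ndarray:
    """Orthonormal 2D FFT with zero frequency and zero position centered."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(field, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def centered_ifft2(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`centered_fft2`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(spectrum, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


@dataclass(frozen=True)
class SourceObject:
    """On-axis fluorescent source on the object-space pixel lattice.

    ``amplitude`` is an N x N non-negative map normalized to unit energy
    (sum of squared amplitude equals 1).
    """

    diameter_um: float
    amplitude: np.ndarray

    @property
    def energy(self) -> float:
        return float(np.sum(self.amplitude**2))


@dataclass
class IntensityStack:
    """Simulated 3D intensity I(x, y; z), stored as (z, y, x).

    ``z_coords`` are in um relative to the nominal focal plane, strictly
    increasing with uniform step.  ``scattering_length`` is in um
    (``inf`` disables the decay factor).
    """

    data: np.ndarray
    z_coords: np.ndarray
    decay_applied: bool
    scattering_length: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("IntensityStack data must be 3D (z, y, x)")
        if self.data.shape[0] != len(self.z_coords):
            raise ValueError("z_coords length must match the number of slices")
        dz = np.diff(self.z_coords)
        if len(dz) and (np.any(dz <= 0) or not np.allclose(dz, dz[0])):
            raise ValueError("z_coords must be strictly increasing and uniform")

    @property
    def depth_step_um(self) -> float:
        z = np.asarray(self.z_coords)
        return float(z[1] - z[0]) if len(z) > 1 else 1.0

    def save(self, path: str | Path) -> tuple[Path, Path]:
        """Write a float32 multi-page TIFF plus a JSON sidecar."""
        path = Path(path)
        tiff_path = path if path.suffix in (".tif", ".tiff") else path.with_suffix(".tif")
        tifffile.imwrite(tiff_path, self.data.astype(np.float32))
        sidecar = tiff_path.with_suffix(".json")
        meta = {
            "z_coords_um": [float(z) for z in self.z_coords],
            "decay_applied": bool(self.decay_applied),
            "scattering_length_um": (
                None if np.isinf(self.scattering_length) else float(self.scattering_length)
            ),
        }
        sidecar.write_text(json.dumps(meta, indent=2))
        return tiff_path, sidecar

    @classmethod
    def load(cls, path: str | Path) -> "IntensityStack":
        path = Path(path)
        data = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        ls = meta["scattering_length_um"]
        return cls(
            data=np.asarray(data),
            z_coords=np.asarray(meta["z_coords_um"], dtype=float),
            decay_applied=meta["decay_applied"],
            scattering_length=np.inf if ls is None else float(ls),
        )


def make_source(diameter_um: float, config: OpticalConfig) -> SourceObject:
    """Centered uniform disk of the given diameter, unit energy.

    Diameter 0 yields a single-pixel impulse.  Pixels whose center lies
    within the disk radius are set to a constant amplitude; the map is then
    normalized so the summed squared amplitude is 1.
    """
    if diameter_um < 0:
        raise ValueError("source diameter must be non-negative")
    n = config.grid_size
    if diameter_um > config.field_of_view_um:
        raise ValueError(
            f"source diameter {diameter_um} um exceeds the simulated field "
            f"of view ({config.field_of_view_um:.1f} um)"
        )
    amp = np.zeros((n, n))
    c = n // 2
    if diameter_um == 0:
        amp[c, c] = 1.0
    else:
        dx = config.object_pixel_um
        coords = (np.arange(n) - c) * dx
        xx, yy = np.meshgrid(coords, coords, indexing="xy")
        amp[np.hypot(xx, yy) <= diameter_um / 2.0] = 1.0
        amp /= np.sqrt(np.sum(amp**2))
    return SourceObject(diameter_um=diameter_um, amplitude=amp)


def simulate_stack(
    source: SourceObject,
    pupil_field: np.ndarray,
    aberration: np.ndarray,
    depths: np.ndarray,
    ls: float,
    config: OpticalConfig,
    grid: PupilGrid | None = None,
    apply_aperture: bool = True,
    stack_dtype=np.float32,
    working_dtype=np.complex128,
) -> IntensityStack:
    """Run the forward model over the requested depth planes.

    Parameters
    ----------
    pupil_field : complex map on the pupil lattice (e.g. the +/-1 binary
        mask transmission, or a single-order field).
    aberration : native objective aberration phase in radians.
    depths : axial planes in um (relative to nominal focus), increasing.
    ls : scattering length in um; ``np.inf`` disables decay.
    apply_aperture : clip the pupil to the NA support (disable to study the
        ideal all-pass lattice, e.g. for energy-conservation checks).
    stack_dtype : dtype of the stored intensity (float32 keeps large stacks
        affordable; pass float64 for tight numerical assertions).
    working_dtype : complex dtype of the FFTs (complex64 roughly halves the
        cost for optimization loops).
    """
    depths = np.asarray(depths, dtype=float)
    pupil_field = np.asarray(pupil_field)
    if pupil_field.shape != source.amplitude.shape:
        raise ValueError("pupil_field shape does not match the source lattice")
    if np.asarray(aberration).shape != pupil_field.shape:
        raise ValueError("aberration shape does not match the pupil lattice")
    if not np.isinf(ls) and ls <= 0:
        raise ValueError("finite scattering length must be positive")

    if grid is None:
        grid = make_pupil_grid(config)
    spectrum = centered_fft2(source.amplitude.astype(working_dtype))
    pupil = spectrum * pupil_field * np.exp(1j * np.asarray(aberration))
    if apply_aperture:
        pupil = pupil * grid.aperture
    pupil = pupil.astype(working_dtype)

    n = pupil.shape[0]
    data = np.empty((len(depths), n, n), dtype=stack_dtype)
    # Batched over z: the defocus kernel is the only z-dependent factor.
    batch = max(1, int(2**24 // (n * n)))
    for start in range(0, len(depths), batch):
        zs = depths[start : start + batch]
        kernels = np.stack(
            [np.exp(1j * defocus_phase(grid, z, config)).astype(working_dtype) for z in zs]
        )
        fields = centered_ifft2(pupil[None, :, :] * kernels)
        data[start : start + len(zs)] = (np.abs(fields) ** 2).astype(stack_dtype)

    decay_applied = not np.isinf(ls)
    if decay_applied:
        rel = depths - depths.min()
        data *= np.exp(-rel / ls)[:, None, None].astype(stack_dtype)
    return IntensityStack(
        data=data,
        z_coords=depths,
        decay_applied=decay_applied,
        scattering_length=float(ls),
    )


def on_axis_profile(stack: IntensityStack) -> np.ndarray:
    """Per-slice maximum intensity as a function of z."""
    return stack.data.reshape(stack.data.shape[0], -1).max(axis=1)
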