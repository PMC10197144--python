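"""Pupil-plane coordinates and basis phase kernels.

The imaging model lives in the pupil (Fourier) plane of the objective.  A
discrete object-space lattice of pitch ``sensor_pixel / magnification``
induces a spatial-frequency lattice ``(u, v)`` in cycles/um; the numerical
aperture of the objective defines a circular support of radius ``NA / lambda``
on that lattice.  Three radially symmetric phase kernels — axicon, angular
spectrum defocus and primary (Seidel) spherical aberration — form the basis
from which extended depth-of-field pupil masks are composed.

Conventions
-----------
* Phases are returned in radians on the full ``N x N`` lattice.
* The normalized pupil radius ``rho = (lambda / NA) * sqrt(u^2 + v^2)``
  equals 1 exactly on the NA cutoff circle.
* Spherical aberration of ``W`` waves means a phase of ``2*pi*W*rho**4``,
  i.e. ``W`` full waves of path error at the pupil edge (Seidel W040).
* Zero frequency sits at the exact center sample for odd ``N`` and at index
  ``N // 2`` for even ``N`` (the ``fftshift`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "OpticalConfig",
    "PupilGrid",
    "AberrationModel",
    "make_pupil_grid",
    "axicon_phase",
    "defocus_phase",
    "spherical_phase",
    "grin_aberration",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and sampling parameters of the miniscope simulation.

    Defaults describe a 0.55 NA GRIN-objective miniscope with 9.2x
    magnification onto a 3.45 um sensor, imaging GFP emission (0.515 um)
    in an aqueous medium, simulated over 100 axial planes at 1 um pitch.

    ``z_start_um`` places the shallowest simulated plane relative to the
    nominal (unaberrated, unmasked) focal plane; depths increase into the
    sample, which is also the direction along which scattering attenuates
    the signal.
    """

    na: float = 0.55
    magnification: float = 9.2
    sensor_pixel_um: float = 3.45
    wavelength_um: float = 0.515
    n_medium: float = 1.33
    grid_size: int = 1000
    depth_step_um: float = 1.0
    n_depths: int = 100
    z_start_um: float = -180.0
    working_distance_um: float = 230.0

    def __post_init__(self) -> None:
        if self.na <= 0 or self.wavelength_um <= 0:
            raise ValueError("na and wavelength_um must be positive")
        if self.na >= self.n_medium:
            raise ValueError(
                f"non-physical configuration: NA ({self.na}) must be smaller "
                f"than the medium index ({self.n_medium})"
            )
        if self.grid_size < 32:
            raise ValueError("grid_size < 32 undersamples the pupil")
        for name in ("magnification", "sensor_pixel_um", "depth_step_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_depths < 1:
            raise ValueError("n_depths must be at least 1")

    @property
    def object_pixel_um(self) -> float:
        """Object-space sampling pitch (sensor pixel back-projected)."""
        return self.sensor_pixel_um / self.magnification

    @property
    def cutoff_frequency(self) -> float:
        """NA cutoff frequency NA/lambda in cycles/um."""
        return self.na / self.wavelength_um

    @property
    def field_of_view_um(self) -> float:
        return self.grid_size * self.object_pixel_um

    def depths(self) -> np.ndarray:
        """Simulated axial planes (um, relative to the nominal focus)."""
        return self.z_start_um + self.depth_step_um * np.arange(self.n_depths)


@dataclass(frozen=True)
class PupilGrid:
    """Centered spatial-frequency lattice with NA-normalized radius."""

    u: np.ndarray
    v: np.ndarray
    rho: np.ndarray
    aperture: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def aperture_fraction(self) -> float:
        return float(np.mean(self.aperture))


@dataclass(frozen=True)
class AberrationModel:
    """On-axis (rotationally symmetric) aberrations of the objective.

    ``w040`` is the primary spherical-aberration coefficient in waves at the
    pupil edge.  ``higher_order`` maps even radial powers k to coefficients
    in waves, contributing ``2*pi*W_k*rho**k`` each; the default is empty
    because the GRIN objective is dominated by primary spherical aberration.
    """

    w040: float = 29.4
    higher_order: Mapping[int, float] = field(default_factory=dict)


def make_pupil_grid(config: OpticalConfig) -> PupilGrid:
    """Build the centered (u, v) lattice induced by the object-space pixels.

    The frequency pitch is ``1 / (N * dx)`` with ``dx`` the object-space
    pixel, so the lattice extent ``1 / (2 dx)`` must cover the NA cutoff
    ``NA / lambda`` — otherwise the pupil is truncated and the configuration
    is rejected.
    """
    n = config.grid_size
    dx = config.object_pixel_um
    f = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    u, v = np.meshgrid(f, f, indexing="xy")
    cutoff = config.cutoff_frequency
    if cutoff > 1.0 / (2.0 * dx):
        raise ValueError(
            f"object-space sampling ({dx:.4f} um) cannot represent the NA "
            f"cutoff {cutoff:.4f} cycles/um"
        )
    rho = np.hypot(u, v) / cutoff
    return PupilGrid(u=u, v=v, rho=rho, aperture=rho <= 1.0)


def axicon_phase(grid: PupilGrid, p1: float) -> np.ndarray:
    """Conical (axicon) phase, linear in radial frequency.

    ``phase = pi * p1 * sqrt(u^2 + v^2)`` with ``p1`` in um (strength per
    cycles/um of radial frequency).
    """
    return np.pi * p1 * np.hypot(grid.u, grid.v)


def defocus_phase(
    grid: PupilGrid, displacement_um: float, config: OpticalConfig
) -> np.ndarray:
    """Exact angular-spectrum defocus phase for an axial displacement z.

    ``phase = (2 pi n / lambda) * z * sqrt(1 - (lambda u / n)^2 - (lambda v / n)^2)``

    Frequencies beyond the propagating-wave circle (evanescent; unreachable
    inside the NA support because NA < n) get zero phase.
    """
    lam = config.wavelength_um
    n = config.n_medium
    arg = 1.0 - (lam * grid.u / n) ** 2 - (lam * grid.v / n) ** 2
    kz = np.sqrt(np.clip(arg, 0.0, None))
    return (2.0 * np.pi * n / lam) * displacement_um * kz


def spherical_phase(grid: PupilGrid, w_waves: float) -> np.ndarray:
    """Primary spherical aberration: ``2*pi*W*rho^4``, W in waves at rho=1."""
    return 2.0 * np.pi * w_waves * grid.rho**4


def grin_aberration(model: AberrationModel, grid: PupilGrid) -> np.ndarray:
    """Total on-axis aberration phase of the objective (radians).

    Applied in the forward model as the unit-modulus factor ``exp(i * A)``.
    """
    phase = spherical_phase(grid, model.w040)
    for order, w in model.higher_order.items():
        if order < 2 or order % 2:
            raise ValueError(f"radial aberration order must be even >= 2, got {order}")
        phase = phase + 2.0 * np.pi * w * grid.rho**order
    return phase
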