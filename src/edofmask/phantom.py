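"""Synthetic bead phantoms, Mie scattering length, and a lithography utility.

The bench experiments this package emulates image 5- and 10-um fluorescent
beads embedded in clear resin whose bulk scattering is set by 1.1-um
polystyrene spheres.  The geometric-optics scattering mean free path of a
monodisperse suspension is

    ls = 2 d / (3 Phi Qs)

with ``d`` the scatterer diameter, ``Phi`` the volume fraction and ``Qs``
the Mie scattering efficiency of one sphere in the host medium.  ``mie_qs``
evaluates the Lorenz-Mie series for ``Qs`` directly (homogeneous sphere,
relative index = particle/medium, size parameter from the in-medium
wavelength).

``generate_bead_volume`` and ``render_measurement`` build seeded 3D bead
scenes on the object-space grid and compress them through a simulated 3D
PSF into a single 2D frame, replicating the extended-depth measurement
geometry with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy.special import spherical_jn, spherical_yn

from .psf import IntensityStack

__all__ = [
    "PhantomSpec",
    "MieParams",
    "scattering_length",
    "mie_qs",
    "generate_bead_volume",
    "render_measurement",
    "contact_print_resolution",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Bead scene parameters emulating the scattering-phantom experiments.

    Defaults: 5-um beads at 2120 particles/mm^3 over a 600-um field (the
    bench phantom conditions) in a medium with a 100-um scattering length,
    photon-shot noise plus 1% read noise.
    """

    bead_diameter_um: float = 5.0
    density_per_mm3: float = 2120.0
    fov_um: float = 600.0
    depth_range_um: tuple[float, float] = (-180.0, -81.0)
    scattering_length_um: float = 100.0
    background_level: float = 0.05
    noise_model: str = "poisson+gaussian"
    read_noise_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_per_mm3 < 0:
            raise ValueError("density must be non-negative")
        if self.fov_um <= 0 or self.depth_range_um[1] <= self.depth_range_um[0]:
            raise ValueError("field of view and depth range must be positive")
        if self.noise_model not in ("none", "poisson+gaussian"):
            raise ValueError("noise_model must be 'none' or 'poisson+gaussian'")


@dataclass(frozen=True)
class MieParams:
    """Inputs of the scattering-length estimate for the resin phantom.

    Defaults are the phantom recipe: 1.1-um polystyrene scatterers
    (n = 1.5979) in clear resin (n = 1.5403), at the green emission band.
    """

    scatterer_diameter_um: float = 1.1
    volume_fraction: float = 0.027 / 1.27
    particle_index: float = 1.5979
    medium_index: float = 1.5403
    wavelength_um: float = 0.515

    def __post_init__(self) -> None:
        if not (0.0 < self.volume_fraction < 1.0):
            raise ValueError("volume fraction must lie in (0, 1)")

    @property
    def size_parameter(self) -> float:
        """pi d n_medium / lambda (in-medium wavelength)."""
        return np.pi * self.scatterer_diameter_um * self.medium_index / self.wavelength_um

    @property
    def relative_index(self) -> float:
        return self.particle_index / self.medium_index


def scattering_length(d_um: float, phi: float, qs: float) -> float:
    """Scattering mean free path ls = 2d / (3 Phi Qs) in um."""
    if d_um <= 0 or phi <= 0 or qs <= 0:
        raise ValueError("d, phi and qs must be positive")
    if phi >= 1:
        raise ValueError("volume fraction must be below 1")
    return 2.0 * d_um / (3.0 * phi * qs)


def mie_qs(params: MieParams) -> float:
    """Lorenz-Mie scattering efficiency of a homogeneous sphere.

    Standard series (Bohren & Huffman): logarithmic derivative by downward
    recurrence, Riccati-Bessel functions from scipy's spherical Bessel
    routines, truncated at the Wiscombe criterion ``x + 4 x^(1/3) + 2``.
    """
    x = params.size_parameter
    m = params.relative_index
    if x <= 0:
        raise ValueError("size parameter must be positive")
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))

    # Logarithmic derivative D_n(mx), downward recurrence from well above nmax.
    mx = m * x
    nstart = nmax + max(15, int(np.ceil(abs(mx))))
    d = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)

    n = np.arange(1, nmax + 1)
    psi = x * spherical_jn(n, x)
    chi = -x * spherical_yn(n, x)
    xi = psi - 1j * chi
    psi_nm1 = x * spherical_jn(n - 1, x)
    chi_nm1 = -x * spherical_yn(n - 1, x)
    xi_nm1 = psi_nm1 - 1j * chi_nm1
    # Recurrences psi_n' = psi_{n-1} - n psi_n / x (same for xi).
    dn = d[1 : nmax + 1]
    a = ((dn / m + n / x) * psi - psi_nm1) / ((dn / m + n / x) * xi - xi_nm1)
    b = ((dn * m + n / x) * psi - psi_nm1) / ((dn * m + n / x) * xi - xi_nm1)
    qs = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    if not np.isfinite(qs):
        raise ArithmeticError("Mie series failed to converge")
    return float(qs)


def generate_bead_volume(
    spec: PhantomSpec,
    object_pixel_um: float,
    depth_step_um: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded 3D bead scene rendered on the object-space grid.

    Bead count is Poisson with mean ``density * volume``; centers are
    uniform in the slab.  Beads are solid spheres of the specified diameter
    rasterized into the (z, y, x) volume.  Returns ``(volume, centers_um,
    z_coords)`` where ``centers_um`` is an (n, 3) table of (x, y, z)
    positions (x, y measured from the field center).
    """
    rng = np.random.default_rng(spec.seed)
    nxy = int(round(spec.fov_um / object_pixel_um))
    z0, z1 = spec.depth_range_um
    z_coords = np.arange(z0, z1 + 0.5 * depth_step_um, depth_step_um)
    nz = len(z_coords)

    volume_mm3 = (spec.fov_um / 1000.0) ** 2 * ((z1 - z0) / 1000.0)
    count = int(rng.poisson(spec.density_per_mm3 * volume_mm3))
    bead_volume_frac = (
        count * (4.0 / 3.0) * np.pi * (spec.bead_diameter_um / 2.0) ** 3
        / (spec.fov_um**2 * (z1 - z0))
    )
    if bead_volume_frac > 0.5:
        raise ValueError("bead density too high: beads occupy > 50% of the volume")

    centers = np.column_stack(
        [
            rng.uniform(-spec.fov_um / 2.0, spec.fov_um / 2.0, count),
            rng.uniform(-spec.fov_um / 2.0, spec.fov_um / 2.0, count),
            rng.uniform(z0, z1, count),
        ]
    )
    volume = np.zeros((nz, nxy, nxy), dtype=np.float32)
    half_fov = spec.fov_um / 2.0
    xy = (np.arange(nxy) + 0.5) * object_pixel_um - half_fov
    r = spec.bead_diameter_um / 2.0
    for cx, cy, cz in centers:
        zsel = np.abs(z_coords - cz) <= r
        if not zsel.any():
            continue
        dx2 = (xy - cx) ** 2
        dy2 = (xy - cy) ** 2
        for iz in np.flatnonzero(zsel):
            r2 = r**2 - (z_coords[iz] - cz) ** 2
            disk = dy2[:, None] + dx2[None, :] <= r2
            volume[iz][disk] = 1.0
    return volume, centers, z_coords


def render_measurement(
    volume: np.ndarray,
    psf_stack: IntensityStack,
    spec: PhantomSpec,
) -> np.ndarray:
    """Compress a 3D bead scene through a 3D PSF into one 2D frame.

    Each z slice of the scene is convolved (FFT, circular) with the PSF
    slice at the same depth — scattering decay enters through the PSF stack
    — and the slices are summed.  A constant background pedestal and, per
    the noise model, photon-shot plus Gaussian read noise are added.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (z, y, x)")
    if volume.shape[0] != psf_stack.data.shape[0]:
        raise ValueError(
            f"volume has {volume.shape[0]} z slices but the PSF stack has "
            f"{psf_stack.data.shape[0]}"
        )
    nz, ny, nx = volume.shape

    image = np.zeros((ny, nx))
    for iz in range(nz):
        if not volume[iz].any():
            continue
        psf = np.asarray(psf_stack.data[iz], dtype=float)
        py, px = psf.shape
        # center-crop or pad the PSF slice to the scene lattice
        if (py, px) != (ny, nx):
            cy, cx = py // 2, px // 2
            hy, hx = min(ny, py) // 2, min(nx, px) // 2
            crop = psf[cy - hy : cy - hy + min(ny, py), cx - hx : cx - hx + min(nx, px)]
            psf = np.zeros((ny, nx))
            psf[
                ny // 2 - crop.shape[0] // 2 : ny // 2 - crop.shape[0] // 2 + crop.shape[0],
                nx // 2 - crop.shape[1] // 2 : nx // 2 - crop.shape[1] // 2 + crop.shape[1],
            ] = crop
        ft = sfft.rfft2(volume[iz].astype(float)) * sfft.rfft2(sfft.ifftshift(psf))
        image += sfft.irfft2(ft, s=(ny, nx))

    image = np.clip(image, 0.0, None)
    peak = image.max() if image.max() > 0 else 1.0
    image = image + spec.background_level * peak
    if spec.noise_model == "poisson+gaussian":
        rng = np.random.default_rng(spec.seed + 1)
        peak_photons = 1000.0  # detected photons at the brightest pixel
        photons = peak_photons * image / image.max()
        image = rng.poisson(photons).astype(float)
        image += rng.normal(0.0, spec.read_noise_fraction * peak_photons, image.shape)
    return image


def contact_print_resolution(wavelength_um: float, gap_um: float, k: float = 2.0) -> float:
    """Contact/proximity printing resolution d = k * sqrt(lambda * h), um.

    ``k ~ 2`` for photolithography; ``h`` is the mask-to-resist separation
    (plus resist thickness).  ``k = 0`` is allowed and gives 0.
    """
    if wavelength_um <= 0 or gap_um <= 0:
        raise ValueError("wavelength and gap must be positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    return k * np.sqrt(wavelength_um * gap_um)
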