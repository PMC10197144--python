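"""Binary diffractive-element phase composition and analysis.

A candidate mask is the binarization of a continuous phase composed from
the three basis kernels (axicon, defocus, spherical aberration).  The
two-level {0, pi} profile transmits ``exp(i*phi) = +/-1``; such a binary
profile splits the designed wavefront into conjugate +1 / -1 diffraction
orders, each carrying ``exp(+i*phi_cont)`` or ``exp(-i*phi_cont)`` on top
of whatever native aberration the objective contributes.  The twin foci of
the extended-depth design arise from exactly this decomposition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .optics import (
    OpticalConfig,
    PupilGrid,
    axicon_phase,
    defocus_phase,
    spherical_phase,
)

__all__ = [
    "BasisCoefficients",
    "BinaryMask",
    "compose_continuous_phase",
    "binarize_phase",
    "mask_transmission",
    "order_field",
    "export_mask",
    "import_mask",
    "ring_boundaries",
]


@dataclass(frozen=True)
class BasisCoefficients:
    """Optimization vector: (axicon strength, defocus um, spherical waves)."""

    axicon: float = 0.0
    defocus_um: float = 0.0
    spherical_waves: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.axicon, self.defocus_um, self.spherical_waves])

    @classmethod
    def from_array(cls, arr) -> "BasisCoefficients":
        a, d, s = (float(x) for x in arr)
        return cls(axicon=a, defocus_um=d, spherical_waves=s)


@dataclass(frozen=True)
class BinaryMask:
    """Two-level pupil phase in {0, pi} plus the coefficients that made it."""

    phase: np.ndarray
    provenance: BasisCoefficients | None = None

    def __post_init__(self) -> None:
        vals = np.unique(self.phase)
        if not np.all(np.isin(vals, [0.0, np.pi])):
            raise ValueError("BinaryMask phase must contain only 0 and pi")


def compose_continuous_phase(
    coeffs: BasisCoefficients, grid: PupilGrid, config: OpticalConfig
) -> np.ndarray:
    """Unwrapped sum of the three basis kernels (radians)."""
    return (
        axicon_phase(grid, coeffs.axicon)
        + defocus_phase(grid, coeffs.defocus_um, config)
        + spherical_phase(grid, coeffs.spherical_waves)
    )


def binarize_phase(
    phase: np.ndarray, provenance: BasisCoefficients | None = None
) -> BinaryMask:
    """Wrap a continuous phase into [0, 2*pi) and threshold at pi.

    Wrapped values in [0, pi) map to 0; values in [pi, 2*pi) map to pi.
    The half-open rule makes the operation deterministic and idempotent.
    """
    phase = np.asarray(phase, dtype=float)
    if not np.all(np.isfinite(phase)):
        raise ValueError("cannot binarize non-finite phase values")
    wrapped = np.mod(phase, 2.0 * np.pi)
    binary = np.where(wrapped >= np.pi, np.pi, 0.0)
    return BinaryMask(phase=binary, provenance=provenance)


def mask_transmission(mask: BinaryMask) -> np.ndarray:
    """Pupil transmission exp(i*phi): exactly +1 where phi=0, -1 where phi=pi."""
    return np.where(mask.phase == 0.0, 1.0, -1.0)


def order_field(
    coeffs: BasisCoefficients,
    order: int,
    grid: PupilGrid,
    config: OpticalConfig,
) -> np.ndarray:
    """Complex pupil field of one diffraction order of the binary mask.

    The +1 / -1 orders of a binary {0, pi} element carry conjugate copies of
    the continuous design phase; this returns ``exp(i * order * phi_cont)``
    so each focus can be simulated in isolation (the shared native
    aberration is applied separately by the forward model).
    """
    if order not in (+1, -1):
        raise ValueError(f"diffraction order must be +1 or -1, got {order}")
    phi = compose_continuous_phase(coeffs, grid, config)
    return np.exp(1j * order * phi)


def ring_boundaries(
    mask: BinaryMask, grid: PupilGrid, pupil_diameter_um: float
) -> list[tuple[int, float, float]]:
    """Radial ring structure of a (rotationally symmetric) binary mask.

    Walks the horizontal radius from the pupil center outward, records the
    pixel radii where the two-level phase flips, and converts them to
    physical radii on a pupil of the given diameter (rho=1 maps to the
    pupil edge).  Returns (ring_index, r_inner_um, r_outer_um) for each
    pi-phase ring inside the aperture.
    """
    n = mask.phase.shape[0]
    c = n // 2
    row_phase = mask.phase[c, c:]
    row_rho = grid.rho[c, c:]
    inside = row_rho <= 1.0
    phase = row_phase[inside]
    rho = row_rho[inside]
    r_um = rho * pupil_diameter_um / 2.0

    rings: list[tuple[int, float, float]] = []
    in_ring = False
    start = 0.0
    for k in range(phase.size):
        if phase[k] == np.pi and not in_ring:
            in_ring = True
            start = r_um[k]
        elif phase[k] == 0.0 and in_ring:
            in_ring = False
            rings.append((len(rings), start, r_um[k]))
    if in_ring:
        rings.append((len(rings), start, r_um[-1]))
    return rings


def export_mask(
    mask: BinaryMask,
    path: str | Path,
    grid: PupilGrid | None = None,
    pupil_diameter_um: float | None = None,
) -> tuple[Path, Path]:
    """Write a lossless 1-bit PNG of the mask and a CSV of its ring radii.

    ``path`` is the PNG destination; the ring table goes next to it with a
    ``_rings.csv`` suffix.  Ring radii require the pupil grid and a physical
    pupil diameter; without them the ring table is left empty.
    """
    path = Path(path)
    png_path = path if path.suffix == ".png" else path.with_suffix(".png")
    bits = (mask.phase == np.pi).astype(np.uint8)
    Image.fromarray(bits * 255).convert("1").save(png_path)

    csv_path = png_path.with_name(png_path.stem + "_rings.csv")
    rings = (
        ring_boundaries(mask, grid, pupil_diameter_um)
        if grid is not None and pupil_diameter_um is not None
        else []
    )
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ring_index", "r_inner_um", "r_outer_um"])
        for idx, r_in, r_out in rings:
            writer.writerow([idx, f"{r_in:.6f}", f"{r_out:.6f}"])
    return png_path, csv_path


def import_mask(path: str | Path) -> BinaryMask:
    """Re-load a mask exported by :func:`export_mask` (exact round-trip)."""
    img = np.asarray(Image.open(path).convert("1"), dtype=bool)
    return BinaryMask(phase=np.where(img, np.pi, 0.0))
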