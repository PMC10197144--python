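"""Depth-of-field and resolution metrics for simulated or measured stacks.

The recoverable depth range of a focus is defined operationally as the
full width at half maximum (FWHM) of the axial optical signal: the stack is
resliced into xz perspectives, maximum-intensity projected, and the z line
profile through the lateral position of the global maximum is extracted.
For a twin-foci design the total depth of field is the sum of the per-focus
FWHMs, provided the two axial profiles do not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .optics import OpticalConfig
from .psf import IntensityStack

__all__ = [
    "DoFMeasurement",
    "axial_signal",
    "fwhm",
    "dof_measure",
    "radial_average_mip",
    "sbr",
]

# Twin-foci detection: peaks closer than this many axial steps, or weaker
# than this fraction of the global maximum, are not counted as a second focus.
MIN_PEAK_SEPARATION_STEPS = 5
MIN_PEAK_FRACTION = 0.2


@dataclass
class DoFMeasurement:
    """Per-focus axial widths and their sum."""

    fwhms_um: list[float]
    focus_positions_um: list[float]
    one_sided: list[bool]

    @property
    def total_dof_um(self) -> float:
        return float(sum(self.fwhms_um))

    def to_dict(self) -> dict:
        return {
            "fwhms_um": [float(w) for w in self.fwhms_um],
            "focus_positions_um": [float(z) for z in self.focus_positions_um],
            "total_dof_um": self.total_dof_um,
            "one_sided": [bool(f) for f in self.one_sided],
        }


def axial_signal(stack: IntensityStack) -> np.ndarray:
    """Axial line profile of the xz maximum-intensity projection.

    The stack (z, y, x) is projected over y, giving an xz view; the profile
    is the z line through the x column holding the global maximum of that
    view.  Lateral translations of the whole stack leave the profile
    unchanged.
    """
    xz = stack.data.max(axis=1)  # (z, x)
    _, x_peak = np.unravel_index(np.argmax(xz), xz.shape)
    return xz[:, x_peak].astype(float)


def _half_crossing(profile, i_from, i_to, half):
    """Linearly interpolated index of the half-max crossing, scanning
    from ``i_from`` toward ``i_to`` (exclusive bounds handled by caller)."""
    step = 1 if i_to > i_from else -1
    prev = i_from
    for i in range(i_from + step, i_to + step, step):
        if profile[i] < half:
            frac = (profile[prev] - half) / (profile[prev] - profile[i])
            return prev + step * frac
        prev = i
    return None


def fwhm(profile: np.ndarray, step_um: float = 1.0) -> tuple[float, bool]:
    """Full width at half maximum of the global peak, in um.

    Crossings are located by linear interpolation between samples.  If the
    profile never falls below half maximum on one side, the width is taken
    up to the profile end on that side and the returned flag is True.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or profile.size < 2:
        raise ValueError("profile must be a 1D array with at least 2 samples")
    peak = int(np.argmax(profile))
    pmax = profile[peak]
    if pmax <= 0:
        raise ValueError("profile has no positive maximum")
    half = pmax / 2.0

    left = _half_crossing(profile, peak, 0, half)
    right = _half_crossing(profile, peak, profile.size - 1, half)
    one_sided = left is None or right is None
    if one_sided:
        warnings.warn(
            "profile does not fall below half maximum on one side; "
            "reporting a one-sided width",
            stacklevel=2,
        )
    lo = 0.0 if left is None else left
    hi = float(profile.size - 1) if right is None else right
    return (hi - lo) * step_um, one_sided


def dof_measure(stack: IntensityStack, n_foci: int = 1) -> DoFMeasurement:
    """Detect the ``n_foci`` strongest well-separated foci and size each.

    Peaks must be at least ``MIN_PEAK_SEPARATION_STEPS`` axial steps apart
    and reach ``MIN_PEAK_FRACTION`` of the global maximum.  Each focus is
    measured on the axial signal restricted to its side of the midpoint
    between adjacent foci, so overlapping tails attribute each depth to the
    nearer focus.
    """
    if n_foci not in (1, 2):
        raise ValueError("n_foci must be 1 or 2")
    profile = axial_signal(stack)
    step = stack.depth_step_um
    z = np.asarray(stack.z_coords)

    peaks, _ = find_peaks(
        profile,
        height=MIN_PEAK_FRACTION * profile.max(),
        distance=MIN_PEAK_SEPARATION_STEPS,
    )
    if profile.argmax() not in peaks:  # plateau/edge maxima
        peaks = np.sort(np.append(peaks, profile.argmax()))
    order = peaks[np.argsort(profile[peaks])[::-1]]
    chosen = np.sort(order[:n_foci])
    if len(chosen) < n_foci:
        raise ValueError(
            f"requested {n_foci} foci but found only {len(chosen)} "
            f"well-separated peaks at z = {z[chosen].tolist()}"
        )

    widths, positions, flags = [], [], []
    cuts = [0]
    for a, b in zip(chosen[:-1], chosen[1:]):
        cuts.append(int((a + b) // 2) + 1)
    cuts.append(profile.size)
    for k, pk in enumerate(chosen):
        seg = profile[cuts[k] : cuts[k + 1]]
        w, one_sided = fwhm(seg, step)
        widths.append(w)
        positions.append(float(z[pk]))
        flags.append(one_sided)
    return DoFMeasurement(fwhms_um=widths, focus_positions_um=positions, one_sided=flags)


def radial_average_mip(
    stack: IntensityStack, config: OpticalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal mean of the xy maximum-intensity projection.

    Returns ``(radii_um, profile)`` where radii are object-space bin centers
    (one bin per pixel pitch) measured from the MIP's peak position.
    """
    mip = stack.data.max(axis=0)
    cy, cx = np.unravel_index(np.argmax(mip), mip.shape)
    yy, xx = np.indices(mip.shape)
    r_px = np.hypot(yy - cy, xx - cx)
    bins = np.round(r_px).astype(int)
    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=mip.ravel())
    profile = sums / counts
    radii = np.arange(profile.size) * config.object_pixel_um
    return radii, profile


def sbr(
    image: np.ndarray,
    signal_regions: np.ndarray | None = None,
    background_regions: np.ndarray | None = None,
) -> float:
    """Signal-to-background ratio: mean over signal / mean over background.

    Regions are boolean masks.  With both omitted, the signal is segmented
    automatically by Otsu's threshold and the background is its complement.
    """
    image = np.asarray(image, dtype=float)
    if signal_regions is None and background_regions is None:
        from skimage.filters import threshold_otsu

        signal_regions = image > threshold_otsu(image)
        background_regions = ~signal_regions
    if signal_regions is None or background_regions is None:
        raise ValueError("provide both regions or neither")
    signal_regions = np.asarray(signal_regions, dtype=bool)
    background_regions = np.asarray(background_regions, dtype=bool)
    if not signal_regions.any() or not background_regions.any():
        raise ValueError("signal and background regions must be non-empty")
    if np.any(signal_regions & background_regions):
        raise ValueError("signal and background regions must be disjoint")
    return float(image[signal_regions].mean() / image[background_regions].mean())
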