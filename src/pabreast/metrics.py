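"""Target detectability metrics: ROI geometry, SNR, gCNR, and FWHM.

The target ROI is a disk the size of the target, concentric with it; the
background ROI is an annulus of inner radius ``2r`` whose outer radius is
chosen so that the two ROIs cover equal areas (``sqrt(5)*r`` in continuous
geometry; an integer pixel-count search under rasterization). SNR is the
target-ROI mean over the background-ROI standard deviation; gCNR is one
minus the overlap of the probability-normalized amplitude histograms of the
two ROIs (32 shared equal-width bins by default). Both are computed on
normalized linear amplitude images, prior to any log compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import BeamformedImage, ImageGrid

__all__ = [
    "ROIPair", "MetricsRecord", "DegenerateBackgroundError",
    "make_rois", "compute_snr", "compute_gcnr", "measure_fwhm",
    "save_roi_overlay",
]

GCNR_BINS = 32


class DegenerateBackgroundError(ValueError):
    """Raised when the background ROI has zero amplitude variance."""


@dataclass
class ROIPair:
    """Concentric target disk and equal-area background annulus."""

    target_mask: np.ndarray
    background_mask: np.ndarray
    r_mm: float
    center: tuple[float, float]
    grid: ImageGrid
    outer_radius_mm: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.target_mask & self.background_mask):
            raise ValueError("target and background ROIs must be disjoint")


@dataclass
class MetricsRecord:
    """One measured condition: detectability metrics plus metadata."""

    snr: float
    gcnr: float
    mu_i: float
    sigma_o: float
    wavelength_nm: float | None = None
    ita: float | None = None
    diameter_mm: float | None = None
    method: str | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def _radius_map(grid: ImageGrid, center: tuple[float, float]) -> np.ndarray:
    zz, xx = np.meshgrid(grid.z_coords, grid.x_coords, indexing="ij")
    return np.sqrt((zz - center[0]) ** 2 + (xx - center[1]) ** 2)


def make_rois(target_center: tuple[float, float], diameter_mm: float,
              grid: ImageGrid) -> ROIPair:
    """Build the target/background ROI pair for one target size.

    The outer annulus radius starts from the continuous-geometry solution
    ``sqrt(5)*r`` (equal areas: pi*(R^2 - (2r)^2) = pi*r^2) and is refined
    by a search over pixel radii to minimize the pixel-count area mismatch
    under rasterization. The same ROIPair is reused across wavelengths,
    skin tones, and beamforming methods for a given diameter.
    """
    r = diameter_mm / 2.0
    if r <= 0:
        raise ValueError("diameter must be positive")
    dmap = _radius_map(grid, target_center)
    target = dmap <= r
    n_target = int(target.sum())
    if n_target == 0:
        raise ValueError("target ROI contains no pixels")

    inner = 2.0 * r
    r_cont = np.sqrt(5.0) * r
    step = min(grid.dz, grid.dx) / 8.0
    candidates = np.arange(inner + step, r_cont + 2.0 * r, step)
    ring = dmap > inner
    best_R, best_err = None, None
    for R in candidates:
        n_bg = int(np.sum(ring & (dmap <= R)))
        err = abs(n_bg - n_target)
        if best_err is None or err < best_err:
            best_R, best_err = R, err
        if n_bg > 2 * n_target and err > best_err:
            break
    R = float(best_R)

    z_lo, z_hi = grid.z_coords[0], grid.z_coords[-1]
    x_lo, x_hi = grid.x_coords[0], grid.x_coords[-1]
    if (target_center[0] - R < z_lo or target_center[0] + R > z_hi
            or target_center[1] - R < x_lo or target_center[1] + R > x_hi):
        raise ValueError("background annulus exceeds the image bounds")

    background = ring & (dmap <= R)
    return ROIPair(target_mask=target, background_mask=background, r_mm=r,
                   center=tuple(target_center), grid=grid, outer_radius_mm=R)


def _image_values(image) -> np.ndarray:
    if isinstance(image, BeamformedImage):
        if image.stage == "compressed":
            raise ValueError("metrics are computed before log compression")
        return image.values
    return np.asarray(image)


def compute_snr(image, rois: ROIPair) -> float:
    """SNR = mu_i / sigma_o: target-ROI mean amplitude over the background-
    ROI amplitude standard deviation (sample std). A zero-variance
    background is signalled as :class:`DegenerateBackgroundError` rather
    than returned as infinity."""
    v = _image_values(image)
    mu_i = float(v[rois.target_mask].mean())
    bg = v[rois.background_mask]
    sigma_o = float(bg.std(ddof=1))
    # relative threshold: the std of a numerically constant background is
    # rounding noise, not variance
    if sigma_o <= 1e-12 * float(np.abs(bg).max()):
        raise DegenerateBackgroundError("background ROI amplitude is constant")
    return mu_i / sigma_o


def compute_gcnr(image, rois: ROIPair, n_bins: int = GCNR_BINS) -> float:
    """Generalized contrast-to-noise ratio.

    ``1 - sum_k min(h_i(x_k), h_o(x_k))`` over ``n_bins`` shared equal-width
    bins spanning the combined amplitude range of the two ROIs, with each
    histogram normalized to unit probability mass. Bounded in [0, 1]:
    0 for identically distributed ROIs, 1 for fully separable ones.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    v = _image_values(image)
    ti = v[rois.target_mask]
    bo = v[rois.background_mask]
    if ti.size == 0 or bo.size == 0:
        raise ValueError("both ROIs must be non-empty")
    lo = float(min(ti.min(), bo.min()))
    hi = float(max(ti.max(), bo.max()))
    if hi == lo:
        return 0.0  # all amplitudes identical: full histogram overlap
    hi_hist, edges = np.histogram(ti, bins=n_bins, range=(lo, hi))
    ho_hist, _ = np.histogram(bo, bins=edges)
    overlap = np.minimum(hi_hist / ti.size, ho_hist / bo.size).sum()
    return float(np.clip(1.0 - overlap, 0.0, 1.0))


def _half_max_width(profile: np.ndarray, coords: np.ndarray) -> float:
    peak = int(np.argmax(profile))
    pmax = profile[peak]
    pmin = profile.min()
    if pmax == pmin:
        raise ValueError("flat profile: no unique interior maximum")
    if peak == 0 or peak == len(profile) - 1:
        raise ValueError("profile maximum at the edge: target clipped")
    half = pmax / 2.0

    def cross(idx_range) -> float:
        prev = peak
        for i in idx_range:
            if profile[i] < half:
                f = (profile[prev] - half) / (profile[prev] - profile[i])
                return coords[prev] + f * (coords[i] - coords[prev])
            prev = i
        raise ValueError("half maximum not crossed: target clipped by the image")

    left = cross(range(peak - 1, -1, -1))
    right = cross(range(peak + 1, len(profile)))
    return abs(right - left)


def measure_fwhm(image, center: tuple[float, float], axis: str) -> float:
    """Full width at half maximum (mm) of the target profile.

    Averages the three lines (rows for a lateral profile, columns for an
    axial one) centered on the target line, locates the half-maximum
    crossings on both sides of the peak by linear interpolation, and
    returns their separation.
    """
    v = _image_values(image)
    grid = image.grid if isinstance(image, BeamformedImage) else None
    if grid is None:
        raise ValueError("measure_fwhm needs a BeamformedImage with a grid")
    iz = int(np.argmin(np.abs(grid.z_coords - center[0])))
    ix = int(np.argmin(np.abs(grid.x_coords - center[1])))
    if axis == "lateral":
        rows = slice(max(iz - 1, 0), min(iz + 2, v.shape[0]))
        profile = v[rows, :].mean(axis=0)
        coords = grid.x_coords
    elif axis == "axial":
        cols = slice(max(ix - 1, 0), min(ix + 2, v.shape[1]))
        profile = v[:, cols].mean(axis=1)
        coords = grid.z_coords
    else:
        raise ValueError("axis must be 'axial' or 'lateral'")
    return _half_max_width(profile, coords)


def save_roi_overlay(image, rois: ROIPair, path: str) -> None:
    """Export an RGB inspection overlay: image in gray, target ROI outlined
    in red, background annulus in blue."""
    import imageio.v3 as iio

    v = _image_values(image)
    g = np.clip(v / v.max() if v.max() > 0 else v, 0, 1)
    rgb = np.stack([g, g, g], axis=-1)
    rgb[rois.target_mask] = [1.0, 0.2, 0.2]
    rgb[rois.background_mask] = [0.2, 0.4, 1.0]
    iio.imwrite(path, (rgb * 255).astype(np.uint8))
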