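"""Image formation: FFT/k-space reconstruction, DAS, and SLSC beamforming.

All three methods consume the same one-way RF channel data. DAS sums
time-of-flight-delayed samples over the aperture; SLSC instead sums the
normalized spatial coherence of the delayed channels over the first ``M``
element lags, which suppresses incoherent clutter; the FFT method maps the
(time, lateral) spectrum onto axial wavenumbers through the acoustic
dispersion relation (Stolt regridding) for planar detection geometry.

Post-processing follows the study pipeline: envelope detection for DAS and
SLSC (the k-space image is rectified by absolute value), peak normalization
for every image, and log compression for display of the amplitude-based
(FFT, DAS) images only — SLSC images are displayed on a linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.signal import hilbert

from .acoustics import ChannelData

__all__ = [
    "ImageGrid", "SLSCConfig", "BeamformedImage",
    "delay_channels", "das", "spatial_coherence", "slsc", "fft_recon",
    "envelope", "normalize", "log_compress", "normalize_display",
    "postprocess", "write_tiff", "write_png",
]

MM = 1e-3  # mm -> m

#: Default display dynamic range (dB) for log-compressed FFT/DAS images.
#: Repository default; the source study does not print its value.
DISPLAY_DYNAMIC_RANGE_DB = 40.0


@dataclass(frozen=True)
class ImageGrid:
    """Reconstruction pixel grid: axial origin at the array face, lateral
    coordinates centered on the aperture. Spacings in mm."""

    z0: float
    dz: float
    nz: int
    x0: float
    dx: float
    nx: int

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.dx <= 0:
            raise ValueError("pixel spacings must be positive")

    @property
    def z_coords(self) -> np.ndarray:
        return self.z0 + self.dz * np.arange(self.nz)

    @property
    def x_coords(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nz, self.nx)

    @classmethod
    def from_grid_spec(cls, grid) -> "ImageGrid":
        """Image grid coincident with a phantom grid's imaging plane."""
        return cls(z0=grid.origin[0], dz=grid.voxel_size, nz=grid.shape[0],
                   x0=grid.origin[1], dx=grid.voxel_size, nx=grid.shape[1])


@dataclass(frozen=True)
class SLSCConfig:
    """Short-lag spatial coherence parameters: maximum lag ``M`` and the
    axial correlation kernel length in samples (odd)."""

    M: int = 10
    kernel_samples: int = 7

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.kernel_samples < 1 or self.kernel_samples % 2 == 0:
            raise ValueError("kernel_samples must be odd and >= 1")


def kernel_samples_for_length(kernel_mm: float, c: float, fs: float) -> int:
    """Convert an axial correlation kernel length (mm) to an odd sample
    count at sound speed ``c`` (m/s) and sampling rate ``fs`` (Hz)."""
    n = kernel_mm * MM / c * fs
    odd = 2 * int(round((n - 1) / 2)) + 1
    return max(odd, 1)


@dataclass
class BeamformedImage:
    values: np.ndarray
    grid: ImageGrid
    method: str  # FFT | DAS | SLSC
    stage: str = "raw"  # raw | envelope | normalized | compressed

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("image shape does not match grid")
        if self.method not in ("FFT", "DAS", "SLSC"):
            raise ValueError(f"unknown method {self.method!r}")


# ---------------------------------------------------------------------------
# Delays
# ---------------------------------------------------------------------------

def delay_channels(data: ChannelData, pixel: tuple[float, float], c: float,
                   kernel_samples: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-element samples at the one-way delay of one pixel.

    ``pixel`` is (z, x) in mm. For each element the sample at fractional
    delay index ``distance/c * fs`` is linearly interpolated; with
    ``kernel_samples > 1`` an axial window of that many samples centered on
    the delay is returned instead. Returns ``(windows, in_range)`` where
    ``windows`` has shape (n_elements, kernel_samples) and out-of-span
    entries are zero-filled and flagged False.
    """
    if c <= 0:
        raise ValueError("sound speed must be positive")
    pz, px = pixel
    fs = data.sampling_frequency_hz
    d = np.sqrt(pz ** 2 + (px - data.element_positions_mm) ** 2)
    idx = (d * MM / c - data.t0) * fs
    half = kernel_samples // 2
    offs = np.arange(-half, half + 1)
    pos = idx[:, None] + offs[None, :]
    i0 = np.floor(pos).astype(np.int64)
    frac = pos - i0
    n_t = data.rf.shape[1]
    valid = (i0 >= 0) & (i0 < n_t - 1)
    i0c = np.clip(i0, 0, n_t - 2)
    rows = np.arange(data.rf.shape[0])[:, None]
    win = data.rf[rows, i0c] * (1 - frac) + data.rf[rows, i0c + 1] * frac
    win[~valid] = 0.0
    return win, valid.all(axis=1)


# ---------------------------------------------------------------------------
# DAS
# ---------------------------------------------------------------------------

@njit(cache=True)
def _das_kernel(rf, el_x, zs, xs, samples_per_mm, out):
    ne, nt = rf.shape
    for iz in range(zs.size):
        z2 = zs[iz] * zs[iz]
        for ix in range(xs.size):
            acc = 0.0
            for e in range(ne):
                dx = xs[ix] - el_x[e]
                idx = np.sqrt(z2 + dx * dx) * samples_per_mm
                i0 = int(idx)
                if 0 <= i0 < nt - 1:
                    f = idx - i0
                    acc += rf[e, i0] * (1.0 - f) + rf[e, i0 + 1] * f
            out[iz, ix] = acc


def das(data: ChannelData, grid: ImageGrid, c: float | None = None) -> BeamformedImage:
    """Delay-and-sum beamforming: per pixel, the unapodized sum of the
    one-way-delayed samples over all elements."""
    if c is None:
        c = data.speed_of_sound
    samples_per_mm = MM / c * data.sampling_frequency_hz
    out = np.zeros(grid.shape)
    _das_kernel(np.ascontiguousarray(data.rf),
                np.ascontiguousarray(data.element_positions_mm),
                grid.z_coords, grid.x_coords, samples_per_mm, out)
    return BeamformedImage(values=out, grid=grid, method="DAS", stage="raw")


# ---------------------------------------------------------------------------
# SLSC
# ---------------------------------------------------------------------------

def spatial_coherence(windows: np.ndarray, m: int) -> float:
    """Normalized spatial coherence R(m) of aligned element windows.

    Averages, over all element pairs at lag ``m``, the normalized inner
    product of their axial kernel windows. Pairs with a zero-energy member
    are skipped with pair-count renormalization; if every pair is
    zero-energy the coherence is undefined and a ``ValueError`` is raised.
    """
    ne = windows.shape[0]
    if not 1 <= m <= ne - 1:
        raise ValueError("lag m must lie in [1, n_elements - 1]")
    energy = np.sum(windows ** 2, axis=1)
    acc, cnt = 0.0, 0
    for i in range(ne - m):
        ei, ej = energy[i], energy[i + m]
        if ei > 0 and ej > 0:
            acc += float(windows[i] @ windows[i + m]) / np.sqrt(ei * ej)
            cnt += 1
    if cnt == 0:
        raise ValueError(f"all element pairs at lag {m} have zero energy")
    return acc / cnt


@njit(cache=True)
def _slsc_kernel(rf, el_x, zs, xs, samples_per_mm, M, kernel, out):
    ne, nt = rf.shape
    half = kernel // 2
    win = np.empty((ne, kernel))
    energy = np.empty(ne)
    for iz in range(zs.size):
        z2 = zs[iz] * zs[iz]
        for ix in range(xs.size):
            # gather aligned kernel windows for every element
            for e in range(ne):
                dx = xs[ix] - el_x[e]
                idx = np.sqrt(z2 + dx * dx) * samples_per_mm
                en = 0.0
                for j in range(kernel):
                    p = idx + (j - half)
                    i0 = int(p)
                    if 0 <= i0 < nt - 1 and p >= 0:
                        f = p - i0
                        v = rf[e, i0] * (1.0 - f) + rf[e, i0 + 1] * f
                    else:
                        v = 0.0
                    win[e, j] = v
                    en += v * v
                energy[e] = en
            val = 0.0
            for m in range(1, M + 1):
                acc = 0.0
                cnt = 0
                for i in range(ne - m):
                    ei = energy[i]
                    ej = energy[i + m]
                    if ei > 0.0 and ej > 0.0:
                        num = 0.0
                        for j in range(kernel):
                            num += win[i, j] * win[i + m, j]
                        acc += num / np.sqrt(ei * ej)
                        cnt += 1
                if cnt > 0:
                    val += acc / cnt
            out[iz, ix] = val


def slsc(data: ChannelData, grid: ImageGrid, c: float | None = None,
         config: SLSCConfig | None = None) -> BeamformedImage:
    """Short-lag spatial coherence beamforming.

    Per pixel, sums the normalized coherence R(m) of the delayed element
    windows over lags m = 1..M. Raw pixel values lie in [-M, M]; negative
    values are clamped to zero downstream (see :func:`postprocess`).
    """
    if config is None:
        config = SLSCConfig()
    if c is None:
        c = data.speed_of_sound
    if config.M >= data.rf.shape[0]:
        raise ValueError("M must be below the element count")
    samples_per_mm = MM / c * data.sampling_frequency_hz
    out = np.zeros(grid.shape)
    _slsc_kernel(np.ascontiguousarray(data.rf),
                 np.ascontiguousarray(data.element_positions_mm),
                 grid.z_coords, grid.x_coords, samples_per_mm,
                 config.M, config.kernel_samples, out)
    return BeamformedImage(values=out, grid=grid, method="SLSC", stage="raw")


# ---------------------------------------------------------------------------
# FFT / k-space reconstruction
# ---------------------------------------------------------------------------

def fft_recon(data: ChannelData, grid: ImageGrid,
              c: float | None = None) -> BeamformedImage:
    """Planar-geometry k-space photoacoustic reconstruction.

    Takes the 2D spectrum of the (time, lateral) channel data, remaps
    temporal frequency onto axial wavenumber through the one-way dispersion
    relation ``omega = c * sqrt(kx^2 + kz^2)`` with linear (Stolt)
    interpolation and the associated Jacobian weighting, and inverse
    transforms onto an image whose axial sampling is ``c * dt``. The result
    is then resampled bilinearly onto the requested grid.
    """
    if c is None:
        c = data.speed_of_sound
    if c <= 0:
        raise ValueError("sound speed must be positive")
    rf = data.rf
    ne, nt = rf.shape
    dt = 1.0 / data.sampling_frequency_hz
    dx_el = float(np.diff(data.element_positions_mm).mean()) * MM
    if not np.allclose(np.diff(data.element_positions_mm),
                       np.diff(data.element_positions_mm)[0]):
        raise ValueError("element pitch must be uniform")

    p_tx = rf.T  # (time, lateral)
    P = np.fft.fft2(p_tx)
    w = 2.0 * np.pi * np.fft.fftfreq(nt, dt)
    kx = 2.0 * np.pi * np.fft.fftfreq(ne, dx_el)
    kz = w / c  # output axial wavenumber grid (dz = c*dt)

    w_sorted = np.fft.fftshift(w)
    order = np.argsort(w)  # fftshift ordering for interpolation
    P0 = np.zeros_like(P)
    kz_col = kz
    abs_k = np.abs(kz_col)
    for i in range(ne):
        w_new = np.sign(kz_col) * c * np.sqrt(kz_col ** 2 + kx[i] ** 2)
        col = P[:, i][order]
        re = np.interp(w_new, w_sorted, col.real, left=0.0, right=0.0)
        im = np.interp(w_new, w_sorted, col.imag, left=0.0, right=0.0)
        vals = re + 1j * im
        # evanescent components carry no propagating information
        vals[np.abs(w_new) > np.abs(w).max()] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            sf = c * abs_k / (2.0 * np.sqrt(kz_col ** 2 + kx[i] ** 2))
        sf[abs_k == 0] = 0.5 if kx[i] == 0 else 0.0
        P0[:, i] = c * sf * vals
    img_native = np.real(np.fft.ifft2(P0)) * 2.0

    z_native = (c * dt) * np.arange(nt) / MM  # mm
    x_native = data.element_positions_mm
    img = _bilinear_resample(img_native, z_native, x_native,
                             grid.z_coords, grid.x_coords)
    return BeamformedImage(values=img, grid=grid, method="FFT", stage="raw")


def _bilinear_resample(img, z_src, x_src, z_dst, x_dst):
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator((z_src, x_src), img, method="linear",
                                     bounds_error=False, fill_value=0.0)
    zz, xx = np.meshgrid(z_dst, x_dst, indexing="ij")
    return interp(np.stack([zz.ravel(), xx.ravel()], axis=1)).reshape(zz.shape)


# ---------------------------------------------------------------------------
# Envelope, normalization, display
# ---------------------------------------------------------------------------

def envelope(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Magnitude of the analytic signal along the axial dimension."""
    values = np.asarray(values)
    if values.shape[axis] < 8:
        raise ValueError("axial dimension must have at least 8 samples")
    return np.abs(hilbert(values, axis=axis))


def normalize(image: BeamformedImage) -> BeamformedImage:
    """Normalize by the brightest pixel; the result has maximum 1."""
    m = float(image.values.max())
    if m <= 0:
        raise ValueError("cannot normalize an all-zero image")
    return replace(image, values=image.values / m, stage="normalized")


def log_compress(image: BeamformedImage) -> BeamformedImage:
    """20*log10 of a normalized amplitude image (FFT/DAS display only;
    SLSC images stay linear)."""
    if image.method == "SLSC":
        raise ValueError("SLSC images are displayed on a linear scale")
    if image.stage != "normalized":
        raise ValueError("log compression applies to normalized images")
    with np.errstate(divide="ignore"):
        vals = 20.0 * np.log10(image.values)
    return replace(image, values=vals, stage="compressed")


def postprocess(image: BeamformedImage) -> BeamformedImage:
    """Raw beamformer output -> normalized linear amplitude image.

    DAS: envelope detection then peak normalization. SLSC: negative
    coherence sums clamped to zero, then peak normalization — the
    lag-summed coherence map carries no RF carrier, so analytic-signal
    envelope detection would only blur it and bias the axial peak. FFT:
    absolute value then peak normalization. This is the stage on which
    detectability metrics are computed (prior to any log compression).
    """
    if image.stage != "raw":
        raise ValueError("postprocess expects a raw beamformer output")
    v = image.values
    if image.method == "DAS":
        v = envelope(v)
    elif image.method == "SLSC":
        v = np.maximum(v, 0.0)
    else:  # FFT
        v = np.abs(v)
    return normalize(replace(image, values=v, stage="envelope"))


def normalize_display(image: BeamformedImage) -> BeamformedImage:
    """Display pipeline: normalized image, log compressed for FFT/DAS,
    linear for SLSC."""
    norm = postprocess(image) if image.stage == "raw" else normalize(image)
    if image.method in ("FFT", "DAS"):
        return log_compress(norm)
    return norm


# ---------------------------------------------------------------------------
# Image IO
# ---------------------------------------------------------------------------

def write_tiff(image: BeamformedImage, path: str) -> None:
    import tifffile

    tifffile.imwrite(path, image.values.astype(np.float32))


def write_png(image: BeamformedImage, path: str,
              dynamic_range_db: float = DISPLAY_DYNAMIC_RANGE_DB) -> None:
    """8-bit display rendering with a fixed dynamic range per method:
    [-DR, 0] dB for compressed images, [0, 1] linear for SLSC."""
    import imageio.v3 as iio

    disp = normalize_display(image) if image.stage in ("raw", "normalized") else image
    v = disp.values
    if disp.stage == "compressed":
        v = np.clip((v + dynamic_range_db) / dynamic_range_db, 0.0, 1.0)
    else:
        v = np.clip(v, 0.0, 1.0)
    iio.imwrite(path, (v * 255).astype(np.uint8))
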