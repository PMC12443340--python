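"""Initial pressure and RF channel-data synthesis.

Converts a fluence map into the photoacoustic initial pressure
``p0 = Phi * mu_a * Gamma`` (thinned by a random binary absorber map), and
records it at a linear transducer array as band-limited RF channel data.

The forward acoustic operator is a homogeneous-medium spherical-wave
superposition at an effective sound speed: each source voxel contributes an
impulse at its one-way time of flight to each element, with geometric
amplitude decay, optional element directivity and path attenuation, and the
per-element trace is convolved with the transducer impulse response. This
preserves the clutter mechanism of interest (strong skin-origin initial
pressure overlying the target) while leaving speed-of-sound aberration
unmodeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import fftconvolve

from .optics import FluenceMap
from .phantom import GridSpec

__all__ = [
    "AbsorberMask", "InitialPressureMap", "TransducerArray", "ChannelData",
    "make_absorber_mask", "initial_pressure", "impulse_response",
    "simulate_channels", "add_channel_noise", "save_channels", "load_channels",
]

#: Effective homogeneous sound speed for the forward model and beamforming.
DEFAULT_SOUND_SPEED = 1540.0  # m/s


@dataclass
class AbsorberMask:
    """Binary absorber map: i.i.d. Bernoulli(density) per voxel."""

    mask: np.ndarray
    density: float
    seed: int


def make_absorber_mask(shape: tuple[int, ...], density: float = 0.5,
                       seed: int = 0) -> AbsorberMask:
    """Seeded binary absorber map in which a ``density`` fraction of pixels
    are absorbers (0.5 by default)."""
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = (rng.random(shape) < density).astype(np.uint8)
    return AbsorberMask(mask=mask, density=density, seed=seed)


@dataclass
class InitialPressureMap:
    """Per-voxel initial pressure in normalized units."""

    p0: np.ndarray
    grid: GridSpec
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.p0 < 0):
            raise ValueError("initial pressure must be non-negative")


def initial_pressure(
    phi: FluenceMap,
    mua_map: np.ndarray,
    gamma: float = 1.0,
    mask: AbsorberMask | None = None,
) -> InitialPressureMap:
    """Voxelwise initial pressure ``Phi * mu_a * Gamma``, optionally thinned
    by a binary absorber mask. The Grueneisen parameter Gamma defaults to 1
    for every tissue."""
    if mua_map.shape != phi.phi.shape:
        raise ValueError("mu_a map grid does not match the fluence grid")
    p0 = phi.phi * mua_map * gamma
    if mask is not None:
        if mask.mask.shape != p0.shape:
            raise ValueError("absorber mask grid does not match")
        p0 = p0 * mask.mask
    return InitialPressureMap(p0=p0, grid=phi.grid, gamma=gamma)


@dataclass(frozen=True)
class TransducerArray:
    """Linear array: 128 elements at 0.3 mm pitch, 7 MHz center frequency,
    4.9 MHz bandwidth, sampled at 40 MHz (an L14-5/38-style probe)."""

    n_elements: int = 128
    pitch_mm: float = 0.3
    center_frequency_hz: float = 7e6
    bandwidth_hz: float = 4.9e6
    sampling_frequency_hz: float = 40e6

    def __post_init__(self) -> None:
        if min(self.n_elements, self.pitch_mm, self.center_frequency_hz,
               self.bandwidth_hz, self.sampling_frequency_hz) <= 0:
            raise ValueError("all transducer parameters must be positive")
        if self.bandwidth_hz >= 2 * self.center_frequency_hz:
            raise ValueError("bandwidth must be below twice the center frequency")

    @property
    def element_positions_mm(self) -> np.ndarray:
        """Lateral element centers (mm), uniformly spaced and centered on 0."""
        n = self.n_elements
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch_mm


@dataclass
class ChannelData:
    """RF samples per element over time. ``t0`` is the time of the first
    sample relative to the laser firing instant (one-way propagation)."""

    rf: np.ndarray  # [element, time]
    sampling_frequency_hz: float
    t0: float
    speed_of_sound: float
    element_positions_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=np.float64)
        if self.rf.ndim != 2 or self.rf.shape[1] == 0:
            raise ValueError("rf must be a non-empty [element, time] array")
        if not np.all(np.isfinite(self.rf)):
            raise ValueError("rf must be finite")


def impulse_response(array: TransducerArray) -> np.ndarray:
    """Transducer impulse response: a Gaussian-modulated cosine.

    The -6 dB two-sided spectral width equals the array bandwidth and the
    peak spectral magnitude at the center frequency is normalized to one.
    The pulse has odd length with an even (time-symmetric) envelope centered
    at the middle sample, so convolution with ``mode='same'`` leaves the
    time of flight unshifted.
    """
    fs = array.sampling_frequency_hz
    fc = array.center_frequency_hz
    # -6 dB amplitude points of a Gaussian spectrum: full width 2.351 sigma_f
    sigma_f = array.bandwidth_hz / (2.0 * math.sqrt(2.0 * math.log(10.0 ** 0.3)))
    sigma_t = 1.0 / (2.0 * math.pi * sigma_f)
    half = int(math.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    pulse = np.exp(-t ** 2 / (2.0 * sigma_t ** 2)) * np.cos(2.0 * math.pi * fc * t)
    spec = np.abs(np.fft.rfft(pulse, n=1 << 14))
    return pulse / spec.max()


def _directivity(sin_theta: np.ndarray, array: TransducerArray,
                 c: float) -> np.ndarray:
    """Hard-baffle far-field element factor: sinc of the lateral angle for
    an element width equal to the pitch."""
    wavelength_mm = c / array.center_frequency_hz * 1e3
    return np.sinc(array.pitch_mm * sin_theta / wavelength_mm)


def simulate_channels(
    p0: InitialPressureMap,
    array: TransducerArray | None = None,
    c_eff: float = DEFAULT_SOUND_SPEED,
    *,
    attenuation_on: bool = False,
    alpha_map: np.ndarray | None = None,
    directivity_on: bool = True,
    amplitude_mode: str | None = None,
) -> ChannelData:
    """Forward-project an initial pressure map to RF channel data.

    Each nonzero voxel contributes a delta at its one-way delay ``d/c_eff``
    per element, with amplitude ``p0/d`` (3D mode) or ``p0/sqrt(d)`` (2D
    mode, the default for planar grids), optionally scaled by element
    directivity and by single-frequency path attenuation
    ``10**(-alpha * fc * d / 20)`` using the mean attenuation coefficient
    (dB/(MHz cm)) sampled along the straight path from ``alpha_map``. The
    per-element traces are then convolved with the transducer impulse
    response. The operator is linear in ``p0``.
    """
    if array is None:
        array = TransducerArray()
    if c_eff <= 0:
        raise ValueError("sound speed must be positive")
    grid = p0.grid
    if amplitude_mode is None:
        amplitude_mode = "2d" if grid.ndim == 2 else "3d"
    if amplitude_mode not in ("2d", "3d"):
        raise ValueError("amplitude_mode must be '2d' or '3d'")

    nz_idx = np.nonzero(p0.p0)
    if len(nz_idx[0]) == 0:
        raise ValueError("initial pressure is empty")
    amps0 = p0.p0[nz_idx]
    src_z = grid.axis_coords(0)[nz_idx[0]]
    src_x = grid.axis_coords(1)[nz_idx[1]]
    src_y = grid.axis_coords(2)[nz_idx[2]] if grid.ndim == 3 else np.zeros_like(src_x)
    if np.any(src_z < 0):
        raise ValueError("sources must lie below the array plane")

    el_x = array.element_positions_mm
    fs = array.sampling_frequency_hz

    dz = src_z[:, None]
    dx = src_x[:, None] - el_x[None, :]
    dy = src_y[:, None]
    d = np.sqrt(dz * dz + dx * dx + dy * dy)  # mm
    d = np.maximum(d, grid.voxel_size / 2.0)

    amp = amps0[:, None] / (d if amplitude_mode == "3d" else np.sqrt(d))
    if directivity_on:
        sin_theta = np.sqrt(dx * dx + dy * dy) / d
        amp = amp * _directivity(sin_theta, array, c_eff)
    if attenuation_on:
        if alpha_map is None:
            raise ValueError("attenuation_on requires an alpha_map")
        alpha_path = _mean_alpha_along_paths(alpha_map, grid, src_z, src_x,
                                             src_y, el_x)
        fc_mhz = array.center_frequency_hz / 1e6
        amp = amp * 10.0 ** (-alpha_path * fc_mhz * (d / 10.0) / 20.0)

    delay_idx = d * 1e-3 / c_eff * fs  # fractional sample index
    pulse = impulse_response(array)
    n_t = int(np.ceil(delay_idx.max())) + len(pulse) + 2

    i0 = np.floor(delay_idx).astype(np.int64)
    frac = delay_idx - i0
    el_idx = np.broadcast_to(np.arange(array.n_elements), d.shape)
    flat0 = (el_idx * n_t + i0).ravel()
    rf = np.bincount(flat0, weights=(amp * (1.0 - frac)).ravel(),
                     minlength=array.n_elements * n_t)
    rf += np.bincount(flat0 + 1, weights=(amp * frac).ravel(),
                      minlength=array.n_elements * n_t)
    rf = rf.reshape(array.n_elements, n_t)
    rf = fftconvolve(rf, pulse[None, :], mode="same", axes=1)

    return ChannelData(
        rf=rf, sampling_frequency_hz=fs, t0=0.0, speed_of_sound=c_eff,
        element_positions_mm=el_x,
        meta={"grid_shape": grid.shape, "grid_voxel": grid.voxel_size,
              "grid_origin": grid.origin})


def _mean_alpha_along_paths(alpha_map, grid, src_z, src_x, src_y, el_x,
                            n_samples: int = 16):
    """Midpoint-rule mean of the attenuation coefficient along each straight
    source-to-element path (2D grids only; elevation ignored)."""
    ts = (np.arange(n_samples) + 0.5) / n_samples
    z0 = grid.origin[0]
    x0 = grid.origin[1]
    inv = 1.0 / grid.voxel_size
    acc = np.zeros((len(src_z), len(el_x)))
    for t in ts:
        pz = t * src_z[:, None] + 0.0
        px = el_x[None, :] + t * (src_x[:, None] - el_x[None, :])
        iz = np.clip(((pz - z0) * inv).astype(np.int64), 0, grid.shape[0] - 1)
        ix = np.clip(((px - x0) * inv).astype(np.int64), 0, grid.shape[1] - 1)
        acc += alpha_map[iz, ix]
    return acc / n_samples


def add_channel_noise(data: ChannelData, snr_db: float = 20.0,
                      seed: int = 0) -> ChannelData:
    """Add i.i.d. zero-mean Gaussian channel noise at the given SNR.

    The noise standard deviation is set so that
    ``20*log10(rms(rf)/rms_noise) = snr_db`` over the full record;
    ``snr_db = inf`` returns the input unchanged.
    """
    if np.isinf(snr_db):
        return ChannelData(rf=data.rf.copy(),
                           sampling_frequency_hz=data.sampling_frequency_hz,
                           t0=data.t0, speed_of_sound=data.speed_of_sound,
                           element_positions_mm=data.element_positions_mm,
                           meta=dict(data.meta))
    rms = float(np.sqrt(np.mean(data.rf ** 2)))
    if rms == 0.0:
        raise ValueError("channel SNR is undefined for all-zero rf")
    sigma = rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noisy = data.rf + sigma * rng.standard_normal(data.rf.shape)
    return ChannelData(rf=noisy, sampling_frequency_hz=data.sampling_frequency_hz,
                       t0=data.t0, speed_of_sound=data.speed_of_sound,
                       element_positions_mm=data.element_positions_mm,
                       meta=dict(data.meta))


def save_channels(data: ChannelData, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=data.rf)
        f.create_dataset("element_positions_mm", data=data.element_positions_mm)
        f.attrs["fs"] = data.sampling_frequency_hz
        f.attrs["t0"] = data.t0
        f.attrs["c"] = data.speed_of_sound
        for k in ("grid_shape", "grid_voxel", "grid_origin"):
            if k in data.meta:
                f.attrs[k] = data.meta[k]


def load_channels(path: str) -> ChannelData:
    with h5py.File(path, "r") as f:
        rf = f["rf"][...]
        el = f["element_positions_mm"][...]
        meta = {k: f.attrs[k] for k in ("grid_shape", "grid_voxel", "grid_origin")
                if k in f.attrs}
        return ChannelData(rf=rf, sampling_frequency_hz=float(f.attrs["fs"]),
                           t0=float(f.attrs["t0"]), speed_of_sound=float(f.attrs["c"]),
                           element_positions_mm=el, meta=meta)
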