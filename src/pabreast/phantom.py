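"""Layered breast phantom construction.

Builds the voxelized tissue label volumes used throughout the pipeline: a
water standoff over a thin skin layer over breast interior (fat /
fibroglandular), with an embedded spherical blood target or a parametric
vessel structure. Also owns the per-tissue optical and acoustic property
tables and the ITA (individual typology angle) skin-tone model, in which
skin optical absorption increases exponentially as ITA decreases (darker
skin, higher melanin content).

Conventions
-----------
* Physical coordinates are in mm. The axial coordinate ``z`` increases
  downward from the transducer face at ``z = 0`` (the top of the volume).
* Label arrays are indexed ``[axial, lateral]`` in 2D and
  ``[axial, lateral, elevation]`` in thin-3D mode.
* Voxel membership is decided by a voxel-center test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "WATER", "SKIN", "FAT", "FIBROGLANDULAR", "BLOOD", "LABEL_NAMES",
    "SUPPORTED_WAVELENGTHS_NM", "SIMULATED_ITAS", "ITA_CATEGORIES",
    "ANISOTROPY", "REFRACTIVE_INDEX",
    "SkinToneSpec", "OpticalProperties", "AcousticProperties",
    "GridSpec", "TissueLabelVolume", "VesselGeometry",
    "ita_category", "skin_mua", "tissue_properties", "property_arrays",
    "build_sphere_phantom", "make_point_fixture",
    "make_vessel_geometry", "voxelize_vessel", "voxelize_stl",
    "save_volume", "load_volume",
]

# ---------------------------------------------------------------------------
# Tissue labels and constants
# ---------------------------------------------------------------------------

WATER, SKIN, FAT, FIBROGLANDULAR, BLOOD = 0, 1, 2, 3, 4
LABEL_NAMES = {
    WATER: "water",
    SKIN: "skin",
    FAT: "fat",
    FIBROGLANDULAR: "fibroglandular",
    BLOOD: "blood",
}
_NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

SUPPORTED_WAVELENGTHS_NM = (757, 800, 1064)

#: Anisotropy factor and refractive index, standardized across all media.
ANISOTROPY = 0.9
REFRACTIVE_INDEX = 1.37

#: The 18 simulated ITA values: three per skin tone category, light to dark.
SIMULATED_ITAS = (60, 58, 56, 50, 47, 43, 38, 35, 30,
                  26, 20, 12, 5, -10, -20, -33, -45, -54)

#: Skin tone categories ordered light to dark. Boundaries follow the
#: half-open convention of the source table, e.g. Light is (41, 55].
ITA_CATEGORIES = ("Very Light", "Light", "Intermediate", "Tan", "Brown", "Dark")

# Optical absorption (mm^-1) by wavelength; skin is formula-driven.
_MUA_TABLE = {
    WATER: {757: 0.0029, 800: 0.0022, 1064: 0.0144},
    FAT: {757: 0.005, 800: 0.005, 1064: 0.005},
    FIBROGLANDULAR: {757: 0.004, 800: 0.004, 1064: 0.004},
    BLOOD: {757: 0.3042, 800: 0.4370, 1064: 0.5484},
}
# Optical scattering (mm^-1) by wavelength.
_MUS_TABLE = {
    WATER: {757: 1.0, 800: 1.0, 1064: 1.0},
    SKIN: {757: 20.6104, 800: 19.0949, 1064: 13.6070},
    FAT: {757: 8.5436, 800: 8.3016, 1064: 7.1575},
    FIBROGLANDULAR: {757: 13.0649, 800: 11.8491, 1064: 7.1567},
    BLOOD: {757: 8.5436, 800: 8.3016, 1064: 7.1575},
}
# Acoustic: speed of sound (m/s), density (kg/m^3), attenuation (dB/(MHz cm)).
_ACOUSTIC_TABLE = {
    WATER: (1500.0, 1000.0, 0.0025),
    SKIN: (1650.0, 1150.0, 0.35),
    FAT: (1470.0, 937.0, 0.60),
    FIBROGLANDULAR: (1515.0, 1040.0, 0.75),
    BLOOD: (1584.0, 1040.0, 0.20),
}


# ---------------------------------------------------------------------------
# Skin tone model
# ---------------------------------------------------------------------------

def ita_category(ita: float) -> str:
    """Map an individual typology angle (degrees) to its skin tone category.

    Boundary values resolve per the published inequalities: Very Light is
    ITA > 55, Light is (41, 55], Intermediate (28, 41], Tan (10, 28],
    Brown [-30, 10], and Dark ITA < -30.
    """
    ita = float(ita)
    if not np.isfinite(ita):
        raise ValueError(f"ITA must be finite, got {ita}")
    if ita > 55:
        return "Very Light"
    if ita > 41:
        return "Light"
    if ita > 28:
        return "Intermediate"
    if ita > 10:
        return "Tan"
    if ita >= -30:
        return "Brown"
    return "Dark"


def skin_mua(wavelength_nm: float, ita: float) -> float:
    """Skin optical absorption coefficient (mm^-1).

    Empirical melanin model: ``45.4 * 10**(-0.004*lambda) * 10**(-0.014*ITA)``
    with wavelength in nm and ITA in degrees. Strictly decreasing in both
    arguments — darker skin (lower ITA) absorbs more.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 45.4 * 10.0 ** (-0.004 * wavelength_nm) * 10.0 ** (-0.014 * ita)


@dataclass(frozen=True)
class SkinToneSpec:
    """A skin tone, identified by its ITA value; category is derived."""

    ita: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.ita <= 90.0):
            raise ValueError(f"ITA {self.ita} outside [-90, 90] degrees")

    @property
    def category(self) -> str:
        return ita_category(self.ita)

    def mua(self, wavelength_nm: float) -> float:
        return skin_mua(wavelength_nm, self.ita)


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalProperties:
    mua: float  # absorption coefficient, mm^-1
    mus: float  # scattering coefficient, mm^-1
    g: float = ANISOTROPY  # anisotropy factor
    n: float = REFRACTIVE_INDEX  # refractive index

    def __post_init__(self) -> None:
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class AcousticProperties:
    c: float      # speed of sound, m/s
    rho: float    # density, kg/m^3
    alpha: float  # attenuation, dB/(MHz cm)

    def __post_init__(self) -> None:
        if self.c <= 0 or self.rho <= 0 or self.alpha < 0:
            raise ValueError("acoustic properties must be physical")


def _interp_loglinear(table: dict[int, float], wavelength_nm: float) -> float:
    lams = np.array(sorted(table))
    vals = np.array([table[int(l)] for l in lams])
    if not lams[0] <= wavelength_nm <= lams[-1]:
        raise ValueError(f"wavelength {wavelength_nm} nm outside table range")
    return float(np.exp(np.interp(wavelength_nm, lams, np.log(vals))))


def tissue_properties(
    label: int | str,
    wavelength_nm: float,
    skin_tone: SkinToneSpec | None = None,
    *,
    interpolate: bool = False,
) -> tuple[OpticalProperties, AcousticProperties]:
    """Optical and acoustic properties for one tissue label at one wavelength.

    Skin absorption requires a ``skin_tone``; all other values come straight
    from the property tables. Wavelengths outside {757, 800, 1064} nm raise
    unless ``interpolate=True``, in which case tabulated coefficients are
    log-linearly interpolated (skin absorption is formula-driven and needs
    no interpolation).
    """
    if isinstance(label, str):
        try:
            label = _NAME_TO_LABEL[label]
        except KeyError:
            raise ValueError(f"unknown tissue label {label!r}") from None
    if label not in LABEL_NAMES:
        raise ValueError(f"unknown tissue label {label!r}")

    exact = wavelength_nm in SUPPORTED_WAVELENGTHS_NM
    if not exact and not interpolate:
        raise ValueError(
            f"wavelength {wavelength_nm} nm unsupported; pass interpolate=True "
            f"or use one of {SUPPORTED_WAVELENGTHS_NM}")

    if label == SKIN:
        if skin_tone is None:
            raise ValueError("skin properties require a SkinToneSpec")
        mua = skin_mua(wavelength_nm, skin_tone.ita)
    else:
        tbl = _MUA_TABLE[label]
        mua = tbl[wavelength_nm] if exact else _interp_loglinear(tbl, wavelength_nm)
    tbl = _MUS_TABLE[label]
    mus = tbl[wavelength_nm] if exact else _interp_loglinear(tbl, wavelength_nm)

    c, rho, alpha = _ACOUSTIC_TABLE[label]
    return OpticalProperties(mua=mua, mus=mus), AcousticProperties(c=c, rho=rho, alpha=alpha)


def property_arrays(
    wavelength_nm: float,
    skin_tone: SkinToneSpec,
    *,
    interpolate: bool = False,
) -> dict[str, np.ndarray]:
    """Per-label property lookup arrays indexed by tissue label.

    Returns arrays ``mua``, ``mus``, ``g`` (optical, mm^-1) and ``c``,
    ``rho``, ``alpha`` (acoustic) of length ``len(LABEL_NAMES)``, for fast
    voxelwise mapping from a label volume.
    """
    n = len(LABEL_NAMES)
    out = {k: np.zeros(n) for k in ("mua", "mus", "g", "c", "rho", "alpha")}
    for label in LABEL_NAMES:
        opt, ac = tissue_properties(label, wavelength_nm, skin_tone,
                                    interpolate=interpolate)
        out["mua"][label] = opt.mua
        out["mus"][label] = opt.mus
        out["g"][label] = opt.g
        out["c"][label] = ac.c
        out["rho"][label] = ac.rho
        out["alpha"][label] = ac.alpha
    return out


# ---------------------------------------------------------------------------
# Grids and volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: shape ``(nz, nx)`` or ``(nz, nx, ny)``, isotropic
    voxel size in mm, and the physical coordinate (mm) of the first voxel
    center along each axis."""

    shape: tuple[int, ...]
    voxel_size: float
    origin: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.shape) not in (2, 3) or len(self.origin) != len(self.shape):
            raise ValueError("shape and origin must both be 2D or 3D")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.voxel_size * np.arange(self.shape[axis])

    @property
    def extent_mm(self) -> tuple[float, ...]:
        return tuple(n * self.voxel_size for n in self.shape)

    @classmethod
    def breast_2d(cls, voxel_mm: float = 0.15, lateral_mm: float = 45.0,
                  axial_mm: float = 15.0) -> "GridSpec":
        """Imaging-plane slice of the breast volume, laterally centered on
        the array with the volume top (array face) at z = 0."""
        nz = int(round(axial_mm / voxel_mm))
        nx = int(round(lateral_mm / voxel_mm))
        half = voxel_mm / 2.0
        return cls(shape=(nz, nx), voxel_size=voxel_mm,
                   origin=(half, -(nx - 1) / 2.0 * voxel_mm))

    @classmethod
    def breast_3d(cls, voxel_mm: float = 0.15, lateral_mm: float = 45.0,
                  axial_mm: float = 15.0, elevation_mm: float = 3.0) -> "GridSpec":
        nz = int(round(axial_mm / voxel_mm))
        nx = int(round(lateral_mm / voxel_mm))
        ny = int(round(elevation_mm / voxel_mm))
        half = voxel_mm / 2.0
        return cls(shape=(nz, nx, ny), voxel_size=voxel_mm,
                   origin=(half, -(nx - 1) / 2.0 * voxel_mm,
                           -(ny - 1) / 2.0 * voxel_mm))


@dataclass
class TissueLabelVolume:
    """Voxelized tissue label map plus grid metadata.

    ``labels`` holds one of the five tissue labels per voxel; ``target_center``
    is the physical (mm) center of the embedded blood target when one exists.
    """

    labels: np.ndarray
    grid: GridSpec
    target_center: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError("labels shape does not match grid")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown labels present: {sorted(bad)}")

    @property
    def voxel_size(self) -> float:
        return self.grid.voxel_size

    def label_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _center_meshes(grid: GridSpec) -> list[np.ndarray]:
    axes = [grid.axis_coords(i) for i in range(grid.ndim)]
    return list(np.meshgrid(*axes, indexing="ij"))


def _layered_background(
    grid: GridSpec,
    skin_top_mm: float,
    skin_thickness_mm: float,
    interior: str,
    fat_blob_seed: int | None,
    n_fat_blobs: int,
) -> np.ndarray:
    z = grid.axis_coords(0)
    labels = np.full(grid.shape, FIBROGLANDULAR, dtype=np.int8)
    if interior == "fat":
        labels[:] = FAT
    elif interior != "fibroglandular":
        raise ValueError(f"unknown interior rule {interior!r}")
    if fat_blob_seed is not None and n_fat_blobs > 0:
        rng = np.random.default_rng(fat_blob_seed)
        meshes = _center_meshes(grid)
        lo = skin_top_mm + skin_thickness_mm
        hi = z[-1]
        for _ in range(n_fat_blobs):
            cz = rng.uniform(lo, hi)
            others = [rng.uniform(grid.axis_coords(i)[0], grid.axis_coords(i)[-1])
                      for i in range(1, grid.ndim)]
            r = rng.uniform(0.5, 2.0)
            d2 = (meshes[0] - cz) ** 2
            for i, c in enumerate(others, start=1):
                d2 = d2 + (meshes[i] - c) ** 2
            labels[(d2 <= r * r) & (meshes[0] >= lo)] = FAT
    labels[z < skin_top_mm, ...] = WATER
    in_skin = (z >= skin_top_mm) & (z < skin_top_mm + skin_thickness_mm)
    labels[in_skin, ...] = SKIN
    return labels


def build_sphere_phantom(
    diameter_mm: float,
    grid: GridSpec | None = None,
    *,
    skin_thickness_mm: float = 1.4,
    target_depth_mm: float = 10.0,
    depth_below_skin_mm: float = 8.6,
    interior: str = "fibroglandular",
    fat_blob_seed: int | None = None,
    n_fat_blobs: int = 0,
) -> TissueLabelVolume:
    """Layered breast phantom with a spherical blood target.

    The water standoff extends from the volume top (z = 0, the transducer
    face) down to the skin surface at ``target_depth - depth_below_skin``
    (1.4 mm by default); the skin layer of ``skin_thickness_mm`` sits below
    it, and the breast interior fills the remainder. The blood target is
    centered laterally at depth ``target_depth_mm`` and contains exactly the
    voxels whose centers lie within ``diameter/2`` of the target center. In
    2D mode the sphere reduces to its equatorial disk in the imaging plane.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    if grid is None:
        grid = GridSpec.breast_2d()
    skin_top = target_depth_mm - depth_below_skin_mm
    if skin_top < 0:
        raise ValueError("target depth below skin exceeds total target depth")
    r = diameter_mm / 2.0
    z_max_edge = grid.shape[0] * grid.voxel_size
    if target_depth_mm - r <= skin_top + skin_thickness_mm:
        raise ValueError("target would intersect the skin layer")
    if target_depth_mm + r >= z_max_edge:
        raise ValueError("target would intersect the bottom volume boundary")

    labels = _layered_background(grid, skin_top, skin_thickness_mm, interior,
                                 fat_blob_seed, n_fat_blobs)
    center = (target_depth_mm,) + (0.0,) * (grid.ndim - 1)
    meshes = _center_meshes(grid)
    d2 = sum((m - c) ** 2 for m, c in zip(meshes, center))
    sphere = d2 <= r * r
    if not sphere.any():
        # degenerate sub-voxel sphere: label at least the nearest voxel center
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        sphere[idx] = True
    labels[sphere] = BLOOD
    return TissueLabelVolume(labels=labels, grid=grid, target_center=center)


def make_point_fixture(grid: GridSpec | None = None,
                       depth_mm: float = 10.0) -> TissueLabelVolume:
    """All-water volume with a single blood voxel at the given depth,
    centered laterally — the point-target fixture used for resolution and
    localization checks."""
    if grid is None:
        grid = GridSpec.breast_2d()
    labels = np.full(grid.shape, WATER, dtype=np.int8)
    idx = [int(np.argmin(np.abs(grid.axis_coords(0) - depth_mm)))]
    for ax in range(1, grid.ndim):
        idx.append(int(np.argmin(np.abs(grid.axis_coords(ax)))))
    labels[tuple(idx)] = BLOOD
    center = tuple(float(grid.axis_coords(ax)[i]) for ax, i in enumerate(idx))
    return TissueLabelVolume(labels=labels, grid=grid, target_center=center)


# ---------------------------------------------------------------------------
# Vessel structures
# ---------------------------------------------------------------------------

@dataclass
class VesselGeometry:
    """Tube geometry along a polyline centerline with a per-point radius
    profile; ``branches`` holds child vessels that union into the parent."""

    centerline: np.ndarray  # (N, 3) points in (z, x, y) mm
    radius_profile: np.ndarray  # (N,) radii in mm
    branches: list["VesselGeometry"] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        # drop consecutive duplicate points (zero-length segments)
        keep = np.ones(len(self.centerline), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1) > 1e-12
        self.centerline = self.centerline[keep]
        self.radius_profile = self.radius_profile[keep]
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 distinct points")
        if len(self.radius_profile) != len(self.centerline):
            raise ValueError("radius profile length must match centerline")
        if np.any(self.radius_profile <= 0):
            raise ValueError("radii must be positive")


def make_vessel_geometry(kind: str, *, depth_mm: float = 10.0,
                         extent_mm: float = 20.0) -> VesselGeometry:
    """Parametric in-plane vessel structures.

    ``splayed`` (benign-lesion feature): a 0.5 mm diameter proximal vessel
    feeding two distal branches that taper from 0.5 to 0.75 mm diameter.
    ``claw`` (malignant-lesion feature): a main vessel spanning 0.5 to
    1.25 mm diameter with a ~0.3 mm waist at the center, plus branching
    vessels of diameter <= 0.4 mm.
    """
    h = extent_mm / 2.0
    if kind == "splayed":
        main = VesselGeometry(
            centerline=[[depth_mm, -h, 0.0], [depth_mm, 0.0, 0.0]],
            radius_profile=[0.25, 0.25])
        for dz in (-1.5, 1.5):
            main.branches.append(VesselGeometry(
                centerline=[[depth_mm, 0.0, 0.0], [depth_mm + dz, h, 0.0]],
                radius_profile=[0.25, 0.375]))
        return main
    if kind == "claw":
        zs = depth_mm + 1.2 * np.sin(np.linspace(0, np.pi, 9))
        xs = np.linspace(-h, h, 9)
        radii = np.interp(xs, [-h, 0.0, h], [0.25, 0.15, 0.625])
        main = VesselGeometry(
            centerline=np.column_stack([zs, xs, np.zeros(9)]),
            radius_profile=radii)
        for frac, dz in ((0.3, -2.5), (0.55, -3.0), (0.8, -2.0)):
            x0 = -h + frac * extent_mm
            z0 = float(np.interp(x0, xs, zs))
            main.branches.append(VesselGeometry(
                centerline=[[z0, x0, 0.0], [z0 + dz, x0 + 2.5, 0.0]],
                radius_profile=[0.2, 0.15]))
        return main
    raise ValueError(f"unknown vessel kind {kind!r}")


def _tube_mask(geometry: VesselGeometry, grid: GridSpec) -> np.ndarray:
    """Voxel-center-in-tube test against an interpolated polyline radius."""
    meshes = _center_meshes(grid)
    if grid.ndim == 2:
        pts = np.stack([meshes[0].ravel(), meshes[1].ravel(),
                        np.zeros(meshes[0].size)], axis=1)
    else:
        pts = np.stack([m.ravel() for m in meshes], axis=1)
    mask = np.zeros(pts.shape[0], dtype=bool)
    cl, rad = geometry.centerline, geometry.radius_profile
    for i in range(len(cl) - 1):
        a, b = cl[i], cl[i + 1]
        ab = b - a
        L2 = float(ab @ ab)
        t = np.clip((pts - a) @ ab / L2, 0.0, 1.0)
        closest = a + t[:, None] * ab
        dist = np.linalg.norm(pts - closest, axis=1)
        r_local = rad[i] + t * (rad[i + 1] - rad[i])
        mask |= dist <= r_local
    out = mask.reshape(grid.shape)
    for child in geometry.branches:
        out |= _tube_mask(child, grid)
    return out


def _geometry_bounds(geometry: VesselGeometry) -> tuple[np.ndarray, np.ndarray]:
    lo = (geometry.centerline - geometry.radius_profile[:, None]).min(axis=0)
    hi = (geometry.centerline + geometry.radius_profile[:, None]).max(axis=0)
    for child in geometry.branches:
        clo, chi = _geometry_bounds(child)
        lo, hi = np.minimum(lo, clo), np.maximum(hi, chi)
    return lo, hi


def voxelize_vessel(
    geometry: VesselGeometry,
    grid: GridSpec | None = None,
    *,
    background: str = "breast",
    skin_thickness_mm: float = 1.4,
    skin_top_mm: float = 1.4,
) -> TissueLabelVolume:
    """Rasterize a vessel geometry into a tissue label volume.

    A voxel is blood iff its center lies within the local tube radius of the
    (interpolated) centerline of the vessel or any branch. ``background``
    selects the surrounding medium: the layered breast model or plain water.
    """
    if grid is None:
        grid = GridSpec.breast_2d()
    lo, hi = _geometry_bounds(geometry)
    g_lo = np.array([grid.axis_coords(i)[0] - grid.voxel_size / 2
                     for i in range(grid.ndim)])
    g_hi = np.array([grid.axis_coords(i)[-1] + grid.voxel_size / 2
                     for i in range(grid.ndim)])
    if np.any(lo[:grid.ndim] < g_lo) or np.any(hi[:grid.ndim] > g_hi):
        raise ValueError("vessel geometry extends outside the grid")
    if background == "breast":
        labels = _layered_background(grid, skin_top_mm, skin_thickness_mm,
                                     "fibroglandular", None, 0)
    elif background == "water":
        labels = np.full(grid.shape, WATER, dtype=np.int8)
    else:
        raise ValueError(f"unknown background {background!r}")
    mask = _tube_mask(geometry, grid)
    labels[mask] = BLOOD
    centroid = tuple(float(c) for c in geometry.centerline.mean(axis=0)[:grid.ndim])
    return TissueLabelVolume(labels=labels, grid=grid, target_center=centroid)


def voxelize_stl(path: str, grid: GridSpec, *,
                 background: str = "water") -> TissueLabelVolume:
    """Voxelize a (binary) STL vessel mesh by a point-in-mesh test.

    Optional alternative to the parametric generators; requires ``trimesh``.
    Mesh coordinates are interpreted as (z, x, y) in mm on the grid's frame.
    """
    import trimesh  # local import: optional path

    mesh = trimesh.load(path, force="mesh")
    meshes = _center_meshes(grid)
    if grid.ndim == 2:
        pts = np.stack([meshes[0].ravel(), meshes[1].ravel(),
                        np.zeros(meshes[0].size)], axis=1)
    else:
        pts = np.stack([m.ravel() for m in meshes], axis=1)
    inside = mesh.contains(pts).reshape(grid.shape)
    if background == "water":
        labels = np.full(grid.shape, WATER, dtype=np.int8)
    elif background == "breast":
        labels = _layered_background(grid, 1.4, 1.4, "fibroglandular", None, 0)
    else:
        raise ValueError(f"unknown background {background!r}")
    labels[inside] = BLOOD
    return TissueLabelVolume(labels=labels, grid=grid, target_center=None)


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

def save_volume(volume: TissueLabelVolume, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=volume.labels)
        f.create_dataset("voxel_size", data=volume.grid.voxel_size)
        f.create_dataset("origin", data=np.asarray(volume.grid.origin))
        if volume.target_center is not None:
            f.create_dataset("target_center", data=np.asarray(volume.target_center))


def load_volume(path: str) -> TissueLabelVolume:
    with h5py.File(path, "r") as f:
        labels = f["labels"][...]
        voxel = float(f["voxel_size"][()])
        origin = tuple(float(v) for v in f["origin"][...])
        center = None
        if "target_center" in f:
            center = tuple(float(v) for v in f["target_center"][...])
    grid = GridSpec(shape=labels.shape, voxel_size=voxel, origin=origin)
    return TissueLabelVolume(labels=labels, grid=grid, target_center=center)
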