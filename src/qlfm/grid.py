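"""Depth-dependent resolution model and the multiscale sampling grid.

Light-field resolution degrades away from the native objective plane, so a
large axially extended volume does not need uniform sampling: axial slabs
far from focus can be sampled at power-of-two multiples of the native
lens-grid pitch (laterally) and proportionally larger axial steps, while
staying at Nyquist with respect to the modelled resolution. This is what
makes complete-space modelling (slabs out to hundreds of um for background
rejection) affordable.

Resolution is modelled as R(z) = alpha*exp(beta*|z|) + gamma, fitted by
least squares to measured or simulated bead widths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .config import OpticalConfig
from .errors import ContractError

__all__ = [
    "ResolutionModel",
    "fit_resolution_model",
    "analytic_resolution_model",
    "resolution_model_from_psf",
    "Slab",
    "MultiscaleGrid",
    "MultiscaleVolume",
    "build_grid",
    "uniform_grid",
    "resample_between_grids",
    "upsample_lateral",
    "downsample_lateral",
]


# ---------------------------------------------------------------------------
# resolution model
# ---------------------------------------------------------------------------

def _expo(z, alpha, beta, gamma):
    return alpha * np.exp(beta * np.abs(z)) + gamma


@dataclass
class ResolutionModel:
    """Exponential depth-dependence of lateral and axial resolution (um).

    ``lateral_fit`` and ``axial_fit`` are (alpha, beta, gamma) of
    R(z) = alpha*exp(beta*|z|) + gamma; ``high_res_half_range`` is the |z|
    below which resolution is treated as constant (the snapshot
    high-resolution range).
    """

    lateral_fit: tuple[float, float, float]
    axial_fit: tuple[float, float, float]
    high_res_half_range: float
    lateral_residual: float = 0.0
    axial_residual: float = 0.0
    degenerate: bool = False

    def lateral(self, z) -> np.ndarray:
        return _expo(np.asarray(z, dtype=float), *self.lateral_fit)

    def axial(self, z) -> np.ndarray:
        return _expo(np.asarray(z, dtype=float), *self.axial_fit)


def _fit_one(depths: np.ndarray, widths: np.ndarray) -> tuple[tuple[float, float, float], float, bool]:
    if np.ptp(widths) < 1e-9 * max(np.mean(widths), 1e-12):
        return (0.0, 0.0, float(np.mean(widths))), 0.0, True
    gamma0 = 0.8 * float(widths.min())
    near = widths[np.argmin(np.abs(depths))]
    alpha0 = max(near - gamma0, 1e-3)
    zmax = float(np.max(np.abs(depths)))
    beta0 = max(math.log(max((widths.max() - gamma0) / alpha0, 1.01)) / max(zmax, 1e-6), 1e-6)
    popt, _ = curve_fit(
        _expo,
        depths,
        widths,
        p0=(alpha0, beta0, gamma0),
        sigma=widths,  # relative weighting so near-focus widths are honoured
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = float(np.linalg.norm(_expo(depths, *popt) - widths))
    return (float(popt[0]), float(popt[1]), float(popt[2])), resid, False


def fit_resolution_model(
    depths,
    fwhm_lateral,
    fwhm_axial,
    high_res_half_range: float | None = None,
) -> ResolutionModel:
    """Least-squares exponential fit of resolution-vs-depth measurements.

    Requires >= 4 depth samples with positive widths. Constant data yields a
    gamma-only fit flagged ``degenerate``. When ``high_res_half_range`` is
    not given it is taken as the |z| where lateral resolution has doubled.
    """
    depths = np.asarray(depths, dtype=float)
    lat = np.asarray(fwhm_lateral, dtype=float)
    ax = np.asarray(fwhm_axial, dtype=float)
    if depths.size < 4:
        raise ContractError("need at least 4 depth samples to fit the resolution model")
    if np.any(lat <= 0) or np.any(ax <= 0):
        raise ContractError("FWHM values must be positive")
    lat_fit, lat_res, deg_l = _fit_one(depths, lat)
    ax_fit, ax_res, deg_a = _fit_one(depths, ax)
    if high_res_half_range is None:
        # resolution is "treated as constant" while within 20% of its
        # focal value: R(z) <= 1.2 R(0)
        a, b, g = lat_fit
        r0 = a + g
        if a > 0 and b > 0 and 1.2 * r0 > g:
            high_res_half_range = math.log((1.2 * r0 - g) / a) / b
        else:
            high_res_half_range = float(np.max(np.abs(depths)))
    return ResolutionModel(
        lateral_fit=lat_fit,
        axial_fit=ax_fit,
        high_res_half_range=float(high_res_half_range),
        lateral_residual=lat_res,
        axial_residual=ax_res,
        degenerate=deg_l or deg_a,
    )


def _geometric_widths(config: OpticalConfig, depths: np.ndarray, axial_ratio: float):
    """Marginal-ray blur combined in quadrature with the lens-sampling floor."""
    na, n = config.objective_na, config.immersion_index
    blur = 2.0 * np.abs(depths) * na / math.sqrt(n * n - na * na)
    floor = 2.0 * config.lens_pitch_sample
    lat = np.sqrt(blur**2 + floor**2)
    return lat, axial_ratio * lat


def analytic_resolution_model(
    config: OpticalConfig,
    z_max: float,
    axial_ratio: float = 3.0,
    n_samples: int = 9,
) -> ResolutionModel:
    """Resolution model from ray-optics blur plus the sampling floor.

    Lateral resolution is the geometric marginal-ray blur diameter combined
    in quadrature with twice the lens pitch at the sample plane (the
    realignment sampling limit); axial resolution is ``axial_ratio`` x
    lateral, reflecting the axial elongation of the light-field PSF.
    """
    # geometric spacing concentrates samples near focus where the fit
    # must reproduce the (sampling-limited) resolution floor
    depths = abs(z_max) * (np.geomspace(1.0, 21.0, n_samples) - 1.0) / 20.0
    lat, ax = _geometric_widths(config, depths, axial_ratio)
    return fit_resolution_model(depths, lat, ax)


def resolution_model_from_psf(
    config: OpticalConfig,
    simulator=None,
    probe_depths=None,
    axial_ratio: float = 3.0,
) -> ResolutionModel:
    """Self-calibrated model: exponential fit to the simulated PSF's own
    lateral width-vs-depth curve (combined with the lens-sampling floor)."""
    from .metrics import fwhm as _fwhm
    from .psf import PSFSimulator

    sim = simulator or PSFSimulator(config)
    if probe_depths is None:
        hr = 4.0 * config.lens_pitch_sample  # rough scale only
        probe_depths = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 7.0, 12.0]) * hr
    probe_depths = np.asarray(probe_depths, dtype=float)
    widths = []
    for z in probe_depths:
        patch = sim.sensor_patch(z)
        profile = patch.sum(axis=0)
        w_mla = _fwhm(profile, sim.config.sensor_pixel_mla)
        widths.append(w_mla / config.effective_magnification)
    widths = np.asarray(widths)
    floor = 2.0 * config.lens_pitch_sample
    lat = np.sqrt(widths**2 + floor**2)
    return fit_resolution_model(probe_depths, lat, axial_ratio * lat)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Slab:
    """One axial slab: [z_start, z_end) sampled uniformly."""

    z_start: float
    z_end: float
    axial_step: float
    lateral_step: float
    lateral_shape: tuple[int, int]

    @property
    def n_z(self) -> int:
        return max(1, int(round((self.z_end - self.z_start) / self.axial_step)))

    @property
    def z_centers(self) -> np.ndarray:
        return self.z_start + self.axial_step * (0.5 + np.arange(self.n_z))

    @property
    def voxel_volume(self) -> float:
        return self.axial_step * self.lateral_step**2

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_z, *self.lateral_shape)


@dataclass(frozen=True)
class MultiscaleGrid:
    """Ordered axial slabs tiling [z_min, z_max] with depth-dependent sampling.

    ``lens_pitch_sample`` is the reference (finest) lateral step; slab
    lateral steps are power-of-two multiples of it. ``num_lenses`` fixes the
    reference lateral extent (the lens-grid field of view).
    """

    slabs: tuple[Slab, ...]
    lens_pitch_sample: float
    num_lenses: tuple[int, int]

    def __post_init__(self) -> None:
        for a, b in zip(self.slabs[:-1], self.slabs[1:]):
            if abs(a.z_end - b.z_start) > 1e-9:
                raise ContractError("slabs must tile the axial range without gaps or overlaps")

    @property
    def z_min(self) -> float:
        return self.slabs[0].z_start

    @property
    def z_max(self) -> float:
        return self.slabs[-1].z_end

    def factor(self, slab: Slab) -> int:
        q = slab.lateral_step / self.lens_pitch_sample
        qi = int(round(q))
        if abs(q - qi) > 1e-6 or qi < 1:
            raise ContractError(f"slab lateral step {slab.lateral_step} is not an integer multiple of the lens pitch")
        return qi

    def voxel_count(self) -> int:
        return int(sum(np.prod(s.shape) for s in self.slabs))

    def all_z_centers(self) -> np.ndarray:
        return np.concatenate([s.z_centers for s in self.slabs])

    def lateral_coords(self, slab: Slab) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) centres of slab cells, aligned with the lens grid."""
        step0 = self.lens_pitch_sample
        out = []
        for axis in range(2):
            nl = self.num_lenses[axis]
            q = self.factor(slab)
            nc = slab.lateral_shape[axis]
            off = (nc * q - nl) // 2
            centres = (np.arange(nc) * q + (q - 1) / 2.0 - off - (nl - 1) / 2.0) * step0
            out.append(centres)
        return out[0], out[1]

    def describe(self) -> str:
        lines = []
        for s in self.slabs:
            lines.append(
                f"[{s.z_start:8.1f},{s.z_end:8.1f}) um  dz={s.axial_step:6.2f}  "
                f"dxy={s.lateral_step:6.2f}  shape={s.shape}"
            )
        return "\n".join(lines)


def uniform_grid(
    z_min: float,
    z_max: float,
    axial_step: float,
    lateral_step: float,
    lateral_shape: tuple[int, int],
    lens_pitch_sample: float | None = None,
    num_lenses: tuple[int, int] | None = None,
) -> MultiscaleGrid:
    """Single-slab grid at uniform sampling (degenerate multiscale grid)."""
    slab = Slab(z_min, z_max, axial_step, lateral_step, tuple(lateral_shape))
    return MultiscaleGrid(
        slabs=(slab,),
        lens_pitch_sample=lens_pitch_sample if lens_pitch_sample is not None else lateral_step,
        num_lenses=tuple(num_lenses) if num_lenses is not None else tuple(lateral_shape),
    )


def build_grid(
    z_min: float,
    z_max: float,
    model: ResolutionModel,
    config: OpticalConfig,
    scan_positions=None,
    max_factor: int | None = None,
) -> MultiscaleGrid:
    """Construct the multiscale complete-space grid for [z_min, z_max].

    Sampling rule: lateral step = modelled lateral resolution / 2 (Nyquist),
    quantised to power-of-two multiples of the lens pitch at the sample
    plane, doubling at most once per slab transition; axial step = modelled
    axial resolution / 2, rounded so each slab holds an integer number of
    planes. With ``scan_positions`` the effective distance from focus is
    taken to the nearest scan position, so the finely sampled region covers
    the whole scanned range.
    """
    if not z_min < z_max:
        raise ContractError(f"z_min ({z_min}) must be below z_max ({z_max})")
    step0 = config.lens_pitch_sample
    positions = np.asarray(scan_positions, dtype=float) if scan_positions is not None else np.zeros(1)
    hr = model.high_res_half_range
    if max(abs(z_min), abs(z_max)) > 50 * max(hr, 1.0):
        warnings.warn("z range extends far beyond the modelled resolution range; extrapolating", stacklevel=2)

    def dist(z):
        return np.min(np.abs(np.asarray(z)[..., None] - positions), axis=-1)

    nl_min = min(config.num_lenses)
    cap = max_factor or max(1, 2 ** int(math.floor(math.log2(max(nl_min / 3.0, 1.0)))))

    def factor_at(d: float) -> int:
        if d <= hr:
            return 1
        r = float(model.lateral(d))
        q = 1
        while 2 * q * step0 * 2 <= r and 2 * q <= cap:
            q *= 2
        return q

    # candidate boundaries: transition distances around each scan position
    bounds = {z_min, z_max}
    alpha, beta, gamma = model.lateral_fit
    ks = int(math.log2(cap)) if cap > 1 else 0
    for k in range(1, ks + 1):
        target = 2 ** (k + 1) * step0  # R at which factor 2^k becomes admissible
        if alpha > 0 and beta > 0 and target > gamma + alpha:
            d_k = math.log((target - gamma) / alpha) / beta
        elif target <= gamma + alpha:
            continue
        else:
            continue
        d_k = max(d_k, hr)
        for s in positions:
            for b in (s - d_k, s + d_k):
                if z_min < b < z_max:
                    bounds.add(round(b, 6))
    # the high-resolution range itself is a boundary
    for s in positions:
        for b in (s - hr, s + hr):
            if z_min < b < z_max:
                bounds.add(round(b, 6))
    bounds = sorted(bounds)
    # cluster interior boundaries closer than one fine axial step and keep
    # each cluster's mean (symmetric ranges stay symmetric)
    ax0 = max(float(model.axial(0.0)) / 2.0, 1e-3)
    interior = bounds[1:-1]
    clusters: list[list[float]] = []
    for b in interior:
        if clusters and b - clusters[-1][-1] < ax0:
            clusters[-1].append(b)
        else:
            clusters.append([b])
    merged = [bounds[0]]
    for cl in clusters:
        m = sum(cl) / len(cl)
        if m - bounds[0] >= ax0 and bounds[-1] - m >= ax0:
            merged.append(m)
    merged.append(bounds[-1])

    slabs = []
    for z0, z1 in zip(merged[:-1], merged[1:]):
        # the boundary construction guarantees Nyquist admissibility at the
        # slab's near edge, so the midpoint decides the factor
        mid_d = float(np.min(dist(np.array([(z0 + z1) / 2.0]))))
        q = factor_at(mid_d)
        ax = max(float(model.axial(mid_d)) / 2.0, ax0) * (1 if q == 1 else 1.0)
        span = z1 - z0
        n = max(1, int(round(span / ax)))
        shape = tuple(int(math.ceil(n_l / q)) for n_l in config.num_lenses)
        slabs.append(Slab(z0, z1, span / n, q * step0, shape))
    # enforce monotone non-decreasing steps with distance from focus
    grid = MultiscaleGrid(slabs=tuple(slabs), lens_pitch_sample=step0, num_lenses=tuple(config.num_lenses))
    return grid


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

class MultiscaleVolume:
    """Per-slab 3D intensity fields (photons per voxel) on a MultiscaleGrid."""

    def __init__(self, grid: MultiscaleGrid, slab_data: list[np.ndarray] | None = None):
        self.grid = grid
        if slab_data is None:
            slab_data = [np.zeros(s.shape) for s in grid.slabs]
        if len(slab_data) != len(grid.slabs):
            raise ContractError("slab_data count does not match grid slabs")
        for arr, s in zip(slab_data, grid.slabs):
            if tuple(arr.shape) != s.shape:
                raise ContractError(f"slab data shape {arr.shape} != grid slab shape {s.shape}")
        self.slab_data = [np.asarray(a, dtype=float) for a in slab_data]

    # -- basic algebra ------------------------------------------------------
    @classmethod
    def zeros(cls, grid: MultiscaleGrid) -> "MultiscaleVolume":
        return cls(grid)

    def copy(self) -> "MultiscaleVolume":
        return MultiscaleVolume(self.grid, [a.copy() for a in self.slab_data])

    def map(self, fn) -> "MultiscaleVolume":
        return MultiscaleVolume(self.grid, [fn(a) for a in self.slab_data])

    def binary(self, other: "MultiscaleVolume", fn) -> "MultiscaleVolume":
        if other.grid is not self.grid and other.grid != self.grid:
            raise ContractError("volumes live on different grids")
        return MultiscaleVolume(
            self.grid, [fn(a, b) for a, b in zip(self.slab_data, other.slab_data)]
        )

    def __add__(self, other):
        return self.binary(other, np.add)

    def __sub__(self, other):
        return self.binary(other, np.subtract)

    def __mul__(self, other):
        if isinstance(other, MultiscaleVolume):
            return self.binary(other, np.multiply)
        return self.map(lambda a: a * other)

    __rmul__ = __mul__

    def total(self) -> float:
        return float(sum(a.sum() for a in self.slab_data))

    def max(self) -> float:
        return float(max(a.max() for a in self.slab_data))

    def dot(self, other: "MultiscaleVolume") -> float:
        return float(sum(np.vdot(a, b).real for a, b in zip(self.slab_data, other.slab_data)))

    def norm(self) -> float:
        return math.sqrt(self.dot(self))

    def clip_nonneg(self) -> "MultiscaleVolume":
        return self.map(lambda a: np.maximum(a, 0.0))


# ---------------------------------------------------------------------------
# lateral up/down sampling between slab grids and the lens grid (adjoint pair)
# ---------------------------------------------------------------------------

def upsample_lateral(arr: np.ndarray, q: int, out_shape: tuple[int, int]) -> np.ndarray:
    """Block-replicate the last two axes by q and crop centrally to out_shape."""
    if q == 1:
        return arr
    rep = np.repeat(np.repeat(arr, q, axis=-2), q, axis=-1)
    oy = (rep.shape[-2] - out_shape[0]) // 2
    ox = (rep.shape[-1] - out_shape[1]) // 2
    return rep[..., oy : oy + out_shape[0], ox : ox + out_shape[1]]


def downsample_lateral(arr: np.ndarray, q: int, out_shape: tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`upsample_lateral`: zero-pad centrally then sum-pool."""
    if q == 1:
        return arr
    ny, nx = out_shape
    full = (ny * q, nx * q)
    pad = np.zeros(arr.shape[:-2] + full, dtype=arr.dtype)
    oy = (full[0] - arr.shape[-2]) // 2
    ox = (full[1] - arr.shape[-1]) // 2
    pad[..., oy : oy + arr.shape[-2], ox : ox + arr.shape[-1]] = arr
    return pad.reshape(arr.shape[:-2] + (ny, q, nx, q)).sum(axis=(-3, -1))


# ---------------------------------------------------------------------------
# resampling between grids
# ---------------------------------------------------------------------------

def resample_between_grids(volume: MultiscaleVolume, dst: MultiscaleGrid) -> MultiscaleVolume:
    """Mass-preserving resampling of a volume onto another grid.

    Values are converted to densities (per um^3), linearly interpolated in
    z and bilinearly in (y, x) with nearest-edge clamping, then multiplied
    by the destination voxel volume. Identical grids return a bitwise copy;
    smooth fields keep their integral within ~1%.
    """
    src = volume.grid
    if src == dst:
        return volume.copy()
    if dst.z_min > src.z_min + 1e-6 or dst.z_max < src.z_max - 1e-6:
        raise ContractError(
            f"destination grid [{dst.z_min}, {dst.z_max}] does not cover the source "
            f"range [{src.z_min}, {src.z_max}]"
        )
    # global stack of source planes as densities with their coordinates
    planes = []  # (z, y_coords, x_coords, density2d)
    for slab, data in zip(src.slabs, volume.slab_data):
        yc, xc = src.lateral_coords(slab)
        dv = slab.voxel_volume
        for iz, z in enumerate(slab.z_centers):
            planes.append((float(z), yc, xc, data[iz] / dv))
    planes.sort(key=lambda p: p[0])
    z_src = np.array([p[0] for p in planes])

    def sample_plane(idx: int, yq: np.ndarray, xq: np.ndarray) -> np.ndarray:
        _, yc, xc, dens = planes[idx]
        yq = np.clip(yq, yc[0], yc[-1])
        xq = np.clip(xq, xc[0], xc[-1])
        iy = np.clip(np.searchsorted(yc, yq) - 1, 0, len(yc) - 2)
        ix = np.clip(np.searchsorted(xc, xq) - 1, 0, len(xc) - 2)
        wy = (yq - yc[iy]) / (yc[iy + 1] - yc[iy])
        wx = (xq - xc[ix]) / (xc[ix + 1] - xc[ix])
        wy = wy[:, None]
        wx = wx[None, :]
        iy = iy[:, None]
        ix = ix[None, :]
        return (
            dens[iy, ix] * (1 - wy) * (1 - wx)
            + dens[iy + 1, ix] * wy * (1 - wx)
            + dens[iy, ix + 1] * (1 - wy) * wx
            + dens[iy + 1, ix + 1] * wy * wx
        )

    out = []
    for slab in dst.slabs:
        yq, xq = dst.lateral_coords(slab)
        dv = slab.voxel_volume
        data = np.empty(slab.shape)
        for iz, z in enumerate(slab.z_centers):
            j = int(np.clip(np.searchsorted(z_src, z) - 1, 0, len(z_src) - 2))
            w = (z - z_src[j]) / (z_src[j + 1] - z_src[j])
            w = float(np.clip(w, 0.0, 1.0))
            d = (1 - w) * sample_plane(j, yq, xq) + w * sample_plane(j + 1, yq, xq)
            data[iz] = d * dv
        out.append(data)
    return MultiscaleVolume(dst, out)
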