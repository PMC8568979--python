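"""Synthetic phantoms and capture simulation.

Emulates the bench experiments used to characterise the instrument:
sub-diffraction or few-micron fluorescent beads suspended in agarose, an
intralipid-like smooth scattering medium, and a nonuniform out-of-focus
background confined to the coarse complete-space slabs. Captures are
simulated by running the phantom through the scattering model and the
wave-optics forward projection, mapping views back to the sensor, and
applying Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import OpticalConfig, preset_20x_na05
from .errors import ContractError
from .grid import MultiscaleGrid, MultiscaleVolume
from .phase_space import PhaseSpaceViews, RawLightFieldFrame, inverse_realign
from .projection import ProjectionOperator
from .psf import PhaseSpacePSF
from .scattering import ScatterOperator, ScatteringPotential, scattered_intensity

__all__ = [
    "NoiseParams",
    "make_bead_phantom",
    "make_scattering_phantom",
    "simulate_capture",
]


@dataclass
class NoiseParams:
    """Sensor noise: Poisson shot noise and additive Gaussian read noise.

    ``peak_counts`` rescales the noiseless frame so its maximum equals this
    photon count before drawing shot noise (None = use intensities as
    counts). ``read_sigma`` defaults to a typical sCMOS read noise.
    """

    poisson: bool = True
    read_sigma: float = 1.6
    peak_counts: float | None = None

    def __post_init__(self) -> None:
        if self.read_sigma < 0:
            raise ContractError("read_sigma must be >= 0")
        if self.peak_counts is not None and self.peak_counts <= 0:
            raise ContractError("peak_counts must be positive")


def _slab_of_depth(grid: MultiscaleGrid, z: float) -> int:
    for i, s in enumerate(grid.slabs):
        if s.z_start - 1e-9 <= z < s.z_end + (1e-9 if i == len(grid.slabs) - 1 else 0):
            return i
    raise ContractError(f"depth {z} outside grid range [{grid.z_min}, {grid.z_max}]")


def _fine_slab_indices(grid: MultiscaleGrid) -> list[int]:
    return [i for i, s in enumerate(grid.slabs) if grid.factor(s) == 1]


def make_bead_phantom(
    grid: MultiscaleGrid,
    n_beads: int,
    bead_diameter: float,
    intensity: float,
    seed: int,
    z_range: tuple[float, float] | None = None,
    lateral_margin: float = 0.15,
) -> tuple[MultiscaleVolume, np.ndarray]:
    """Random fluorescent beads rendered into a multiscale volume.

    Beads are placed uniformly (seeded) within ``z_range`` (default: the
    finely sampled slabs) and within the central (1 - 2*margin) fraction of
    the lateral field of view. ``intensity`` is emission per um^3; each
    rendered bead integrates to sphere volume x intensity (a bead smaller
    than half a voxel becomes a trilinearly split point source carrying the
    same total). Returns the volume and the exact continuous positions
    (z, y, x) in um.
    """
    if bead_diameter < 0:
        raise ContractError("bead_diameter must be >= 0")
    rng = np.random.default_rng(seed)
    vol = MultiscaleVolume.zeros(grid)
    if n_beads == 0:
        return vol, np.zeros((0, 3))
    if z_range is None:
        fine = _fine_slab_indices(grid)
        z_lo = min(grid.slabs[i].z_start for i in fine)
        z_hi = max(grid.slabs[i].z_end for i in fine)
    else:
        z_lo, z_hi = z_range
    ny, nx = grid.num_lenses
    step0 = grid.lens_pitch_sample
    half_y = ny * step0 / 2.0
    half_x = nx * step0 / 2.0
    if n_beads > grid.voxel_count():
        raise ContractError(f"{n_beads} beads exceed the {grid.voxel_count()} grid voxels")
    pos = np.column_stack(
        [
            rng.uniform(z_lo, z_hi, n_beads),
            rng.uniform(-half_y * (1 - 2 * lateral_margin), half_y * (1 - 2 * lateral_margin), n_beads),
            rng.uniform(-half_x * (1 - 2 * lateral_margin), half_x * (1 - 2 * lateral_margin), n_beads),
        ]
    )
    radius = bead_diameter / 2.0
    total = intensity * max(4.0 / 3.0 * math.pi * radius**3, 1e-12) if radius > 0 else intensity
    for p in pos:
        _render_bead(vol, p, radius, intensity, total)
    return vol, pos


def _render_bead(vol: MultiscaleVolume, pos, radius: float, intensity: float, total: float) -> None:
    grid = vol.grid
    z, y, x = pos
    si = _slab_of_depth(grid, z)
    slab = grid.slabs[si]
    data = vol.slab_data[si]
    zc = slab.z_centers
    yc, xc = grid.lateral_coords(slab)
    small = radius < 0.5 * min(slab.axial_step, slab.lateral_step)
    if small:
        _deposit_trilinear(data, zc, yc, xc, (z, y, x), total)
        return
    # supersampled sphere rasterisation (antialiased partial-voxel coverage)
    ss = 4
    zi = np.where(np.abs(zc - z) <= radius + slab.axial_step)[0]
    yi = np.where(np.abs(yc - y) <= radius + slab.lateral_step)[0]
    xi = np.where(np.abs(xc - x) <= radius + slab.lateral_step)[0]
    if len(zi) == 0 or len(yi) == 0 or len(xi) == 0:
        return
    off = (np.arange(ss) + 0.5) / ss - 0.5
    oz = off * slab.axial_step
    ol = off * slab.lateral_step
    for iz in zi:
        for iy in yi:
            for ix in xi:
                dz = zc[iz] + oz[:, None, None] - z
                dy = yc[iy] + ol[None, :, None] - y
                dx = xc[ix] + ol[None, None, :] - x
                frac = np.mean(dz * dz + dy * dy + dx * dx <= radius * radius)
                if frac > 0:
                    data[iz, iy, ix] += intensity * frac * slab.voxel_volume


def _deposit_trilinear(data, zc, yc, xc, pos, total) -> None:
    z, y, x = pos
    idx = []
    wts = []
    for c, coords in zip((z, y, x), (zc, yc, xc)):
        if len(coords) == 1:
            idx.append((0, 0))
            wts.append((1.0, 0.0))
            continue
        j = int(np.clip(np.searchsorted(coords, c) - 1, 0, len(coords) - 2))
        w = float(np.clip((c - coords[j]) / (coords[j + 1] - coords[j]), 0.0, 1.0))
        idx.append((j, j + 1))
        wts.append((1.0 - w, w))
    for a in range(2):
        for b in range(2):
            for c_ in range(2):
                w = wts[0][a] * wts[1][b] * wts[2][c_]
                if w > 0:
                    data[idx[0][a], idx[1][b], idx[2][c_]] += total * w


def make_scattering_phantom(
    grid: MultiscaleGrid,
    n_beads: int = 10,
    bead_diameter: float = 2.0,
    bead_intensity: float = 50.0,
    scattering_level: float = 0.05,
    background_intensity: float = 5.0,
    seed: int = 0,
) -> tuple[MultiscaleVolume, ScatteringPotential, dict]:
    """Bead-in-scattering-medium phantom with nonuniform far background.

    Returns (emission volume, scattering potential, truth dict). The
    potential is a seeded smooth (low-pass random) non-negative field whose
    mean equals ``scattering_level`` exactly; the out-of-focus background is
    a smooth nonuniform layer confined to the coarse slabs
    (``background_intensity`` = mean photons per voxel there).
    """
    if scattering_level < 0:
        raise ContractError("scattering_level must be >= 0")
    rng = np.random.default_rng(seed)
    emission, positions = make_bead_phantom(
        grid, n_beads, bead_diameter, bead_intensity, seed=rng.integers(2**31)
    )
    # smooth non-negative scattering potential over the whole grid
    F = ScatteringPotential(grid)
    if scattering_level > 0:
        for i, slab in enumerate(grid.slabs):
            noise = rng.standard_normal(slab.shape)
            smooth = gaussian_filter(noise, sigma=(1.0, 2.0, 2.0), mode="nearest")
            field = smooth - smooth.min() + 0.1
            F.slab_data[i] = field
        mean = np.mean(np.concatenate([a.ravel() for a in F.slab_data]))
        for i in range(len(F.slab_data)):
            F.slab_data[i] *= scattering_level / mean
    # nonuniform background in the coarse (out-of-focus) slabs only
    coarse = [i for i, s in enumerate(grid.slabs) if grid.factor(s) > 1]
    for i in coarse:
        shape = grid.slabs[i].shape
        noise = rng.standard_normal(shape)
        layer = gaussian_filter(noise, sigma=(1.0, 1.5, 1.5), mode="nearest")
        layer = layer - layer.min() + 0.3
        layer *= background_intensity / layer.mean()
        emission.slab_data[i] += layer
    truth = {
        "positions": positions,
        "bead_intensity": bead_intensity,
        "scattering_level": scattering_level,
        "background_slabs": coarse,
    }
    return emission, F, truth


def simulate_capture(
    volume: MultiscaleVolume,
    potential: ScatteringPotential | None,
    psf: PhaseSpacePSF,
    config: OpticalConfig,
    noise: NoiseParams | None = None,
    seed: int = 0,
    scatter_op: ScatterOperator | None = None,
) -> tuple[RawLightFieldFrame, PhaseSpaceViews]:
    """Simulate one raw light-field frame of a phantom.

    views = forward(volume + scattered(volume, F)); the frame is the
    inverse realignment of the views; optional Poisson shot noise then
    additive Gaussian read noise, both seeded. Returns (noisy frame,
    noiseless views). The PSF must be grid-matched and unbinned
    (sensor-resolution angular sampling).
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    total = volume
    if potential is not None and potential.max() > 0:
        total = volume + scattered_intensity(volume, potential, operator=scatter_op)
    views = ProjectionOperator(psf, volume.grid).forward(total)
    views = np.maximum(views, 0.0)
    frame = inverse_realign(PhaseSpaceViews(views=views, config=config))
    img = frame.sensor_image
    if noise.peak_counts is not None and img.max() > 0:
        img = img * (noise.peak_counts / img.max())
    if noise.poisson:
        img = rng.poisson(img).astype(float)
    if noise.read_sigma > 0:
        img = img + rng.normal(0.0, noise.read_sigma, img.shape)
    noisy = RawLightFieldFrame(sensor_image=img, config=config)
    return noisy, PhaseSpaceViews(views=views, config=config)
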