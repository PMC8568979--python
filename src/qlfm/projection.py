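"""Linear projection between multiscale volumes and phase-space views.

For each angular component the measurement is the sum over depth planes of
the plane image convolved with that plane's phase-space kernel, each plane
convolved at its own slab sampling and then resampled to the lens grid.
``ProjectionOperator`` precomputes kernel FFTs so repeated applications
inside iterative reconstructions are cheap, and implements the exact
adjoint used by every multiplicative/gradient update.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len, rfft2, irfft2

from .errors import ContractError
from .grid import MultiscaleGrid, MultiscaleVolume, downsample_lateral, upsample_lateral
from .psf import PhaseSpacePSF, PSFSimulator

__all__ = ["ProjectionOperator", "psf_for_grid", "forward_project", "backproject"]


def psf_for_grid(
    simulator: PSFSimulator,
    grid: MultiscaleGrid,
    depth_shift: float = 0.0,
) -> PhaseSpacePSF:
    """Phase-space PSF matched to a multiscale grid.

    One kernel per slab z-centre, computed at that slab's lateral sampling.
    ``depth_shift`` displaces the modelled source depths (z -> z - shift),
    which is how axial-scan positions enter the forward model.
    """
    depths, kernels, factors = [], [], []
    for slab in grid.slabs:
        q = grid.factor(slab)
        for z in slab.z_centers:
            depths.append(z)
            factors.append(q)
            kernels.append(simulator.kernel(z - depth_shift, q))
    return PhaseSpacePSF(
        config=simulator.config,
        depth_list=np.asarray(depths),
        kernels=kernels,
        lateral_factors=factors,
        angular_bins=simulator.angular_bins,
    )


def _pad_centre(kern: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad the lateral axes of an odd-sized kernel to a larger odd shape."""
    ky, kx = kern.shape[2:]
    if (ky, kx) == shape:
        return kern
    py = (shape[0] - ky) // 2
    px = (shape[1] - kx) // 2
    return np.pad(kern, ((0, 0), (0, 0), (py, py), (px, px)))


class _SlabConv:
    """Batched same-mode FFT convolutions of slab planes with per-depth,
    per-angle kernels, plus the matching correlation (adjoint)."""

    def __init__(self, planes_shape, kernels: list[np.ndarray]):
        self.ny, self.nx = planes_shape
        ky = max(k.shape[2] for k in kernels)
        kx = max(k.shape[3] for k in kernels)
        kernels = [_pad_centre(k, (ky, kx)) for k in kernels]
        kern = np.stack(kernels)  # (nz, nu, nv, ky, kx)
        self.nz, self.nu, self.nv, self.ky, self.kx = kern.shape
        if self.ky % 2 == 0 or self.kx % 2 == 0:
            raise ContractError("kernels must have odd lateral extent")
        self.fy = next_fast_len(self.ny + self.ky - 1)
        self.fx = next_fast_len(self.nx + self.kx - 1)
        self.kfft = rfft2(kern, s=(self.fy, self.fx))
        self.kfft_flip = rfft2(kern[:, :, :, ::-1, ::-1], s=(self.fy, self.fx))
        self.crop_y = (self.ky - 1) // 2
        self.crop_x = (self.kx - 1) // 2

    def forward(self, planes: np.ndarray) -> np.ndarray:
        """(nz, ny, nx) -> (nu, nv, ny, nx), summed over depth planes."""
        pf = rfft2(planes, s=(self.fy, self.fx))  # (nz, fy, fx)
        prod = np.einsum("zyx,zuvyx->uvyx", pf, self.kfft)
        full = irfft2(prod, s=(self.fy, self.fx))
        return full[
            ...,
            self.crop_y : self.crop_y + self.ny,
            self.crop_x : self.crop_x + self.nx,
        ]

    def forward_angle(self, planes: np.ndarray, iu: int, iv: int) -> np.ndarray:
        pf = rfft2(planes, s=(self.fy, self.fx))
        prod = (pf * self.kfft[:, iu, iv]).sum(axis=0)
        full = irfft2(prod, s=(self.fy, self.fx))
        return full[
            self.crop_y : self.crop_y + self.ny,
            self.crop_x : self.crop_x + self.nx,
        ]

    def adjoint(self, views: np.ndarray) -> np.ndarray:
        """(nu, nv, ny, nx) -> (nz, ny, nx)."""
        vf = rfft2(views, s=(self.fy, self.fx))
        prod = np.einsum("uvyx,zuvyx->zyx", vf, self.kfft_flip)
        full = irfft2(prod, s=(self.fy, self.fx))
        return full[
            :,
            self.crop_y : self.crop_y + self.ny,
            self.crop_x : self.crop_x + self.nx,
        ]

    def adjoint_angle(self, view: np.ndarray, iu: int, iv: int) -> np.ndarray:
        vf = rfft2(view, s=(self.fy, self.fx))
        prod = vf * self.kfft_flip[:, iu, iv]
        full = irfft2(prod, s=(self.fy, self.fx))
        return full[
            :,
            self.crop_y : self.crop_y + self.ny,
            self.crop_x : self.crop_x + self.nx,
        ]


class ProjectionOperator:
    """Linear map volume -> views for one PSF/grid pairing, with adjoint."""

    def __init__(self, psf: PhaseSpacePSF, grid: MultiscaleGrid):
        self.psf = psf
        self.grid = grid
        self.num_lenses = tuple(grid.num_lenses)
        depths = list(np.round(psf.depth_list, 6))
        self._convs = []
        self._factors = []
        idx = 0
        for slab in grid.slabs:
            q = grid.factor(slab)
            zc = np.round(slab.z_centers, 6)
            sel = depths[idx : idx + len(zc)]
            if len(sel) != len(zc) or np.max(np.abs(np.asarray(sel) - zc)) > 1e-4:
                raise ContractError(
                    "PSF depth_list does not match the grid slab z-centres; "
                    "build the PSF with psf_for_grid"
                )
            kerns = psf.kernels[idx : idx + len(zc)]
            for k, f in zip(kerns, psf.lateral_factors[idx : idx + len(zc)]):
                if f != q:
                    raise ContractError("PSF lateral factor does not match slab sampling")
            self._convs.append(_SlabConv(slab.lateral_shape, kerns))
            self._factors.append(q)
            idx += len(zc)
        if idx != len(depths):
            raise ContractError("PSF depth_list has extra depths not present in the grid")
        self.n_angles = psf.n_angles
        self._adjoint_ones_cache: MultiscaleVolume | None = None
        self._adjoint_ones_angle_cache: dict[tuple[int, int], MultiscaleVolume] = {}

    # -- full-aperture maps -------------------------------------------------
    def forward(self, volume: MultiscaleVolume) -> np.ndarray:
        if volume.grid != self.grid:
            raise ContractError("volume grid does not match the projection operator grid")
        nu, nv = self.n_angles
        views = np.zeros((nu, nv, *self.num_lenses))
        for conv, q, data in zip(self._convs, self._factors, volume.slab_data):
            contrib = conv.forward(data)
            views += upsample_lateral(contrib, q, self.num_lenses)
        return views

    def adjoint(self, views: np.ndarray) -> MultiscaleVolume:
        out = []
        for conv, q, slab in zip(self._convs, self._factors, self.grid.slabs):
            v = downsample_lateral(views, q, slab.lateral_shape)
            out.append(conv.adjoint(v))
        return MultiscaleVolume(self.grid, out)

    # -- per-angle maps (for cycled multiplicative updates) ------------------
    def forward_angle(self, volume: MultiscaleVolume, iu: int, iv: int) -> np.ndarray:
        view = np.zeros(self.num_lenses)
        for conv, q, data in zip(self._convs, self._factors, volume.slab_data):
            view += upsample_lateral(conv.forward_angle(data, iu, iv), q, self.num_lenses)
        return view

    def adjoint_angle(self, view: np.ndarray, iu: int, iv: int) -> MultiscaleVolume:
        out = []
        for conv, q, slab in zip(self._convs, self._factors, self.grid.slabs):
            v = downsample_lateral(view[None, None], q, slab.lateral_shape)[0, 0]
            out.append(conv.adjoint_angle(v, iu, iv))
        return MultiscaleVolume(self.grid, out)

    # -- sensitivity images --------------------------------------------------
    def adjoint_ones(self) -> MultiscaleVolume:
        if self._adjoint_ones_cache is None:
            nu, nv = self.n_angles
            self._adjoint_ones_cache = self.adjoint(np.ones((nu, nv, *self.num_lenses)))
        return self._adjoint_ones_cache

    def adjoint_ones_angle(self, iu: int, iv: int) -> MultiscaleVolume:
        key = (iu, iv)
        if key not in self._adjoint_ones_angle_cache:
            self._adjoint_ones_angle_cache[key] = self.adjoint_angle(
                np.ones(self.num_lenses), iu, iv
            )
        return self._adjoint_ones_angle_cache[key]


# -- functional wrappers (one-shot convenience API) --------------------------

def forward_project(volume: MultiscaleVolume, psf: PhaseSpacePSF) -> np.ndarray:
    """Project a multiscale volume into phase-space views (u, v, ly, lx)."""
    return ProjectionOperator(psf, volume.grid).forward(volume)


def backproject(views: np.ndarray, psf: PhaseSpacePSF, grid: MultiscaleGrid) -> MultiscaleVolume:
    """Exact adjoint of :func:`forward_project`."""
    return ProjectionOperator(psf, grid).adjoint(views)
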