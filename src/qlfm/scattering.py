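"""Incoherent first-Born scattering: operator and potential update.

Scattered photons are modelled as an isotropic, single-scattering
redistribution of the emission: the scattered intensity is

    I_s(r) = 1/2 * integral F(r') I(r') / ||r - r'||^2 d^3r'

with F >= 0 the scattering potential energy density. Discretised on a
uniform auxiliary grid this is a 3D convolution of F*I with the kernel
K(dr) = dV / ||dr||^2, whose singular self-voxel value is regularised to
the kernel value at half the voxel diagonal. Scattered light is added to
the emission field before projection through the PSF — it is imaged like
fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.fft import next_fast_len, rfftn, irfftn

from .errors import ContractError
from .grid import MultiscaleGrid, MultiscaleVolume, uniform_grid

__all__ = [
    "ScatteringPotential",
    "ScatterOperator",
    "scattered_intensity",
    "scattered_intensity_direct",
    "update_potential",
    "interp_matrix",
    "scatter_grid_for",
]


class ScatteringPotential(MultiscaleVolume):
    """Non-negative scattering potential F on a multiscale grid."""


# ---------------------------------------------------------------------------
# grid-to-grid interpolation matrices (mass preserving)
# ---------------------------------------------------------------------------

def _flat_offsets(grid: MultiscaleGrid) -> list[int]:
    offs, n = [], 0
    for s in grid.slabs:
        offs.append(n)
        n += int(np.prod(s.shape))
    offs.append(n)
    return offs


def interp_matrix(src: MultiscaleGrid, dst: MultiscaleGrid) -> sparse.csr_matrix:
    """Sparse mass-preserving interpolation from src to dst voxel vectors.

    Values are treated as photons per voxel: converted to density, tri-
    linearly interpolated (nearest-edge clamped), multiplied by the
    destination voxel volume. Identical grids give the identity.
    """
    n_src = src.voxel_count()
    if src == dst:
        return sparse.identity(n_src, format="csr")
    src_offs = _flat_offsets(src)
    planes = []  # (z, flat_base, yc, xc, ny, nx, dv)
    for si, slab in enumerate(src.slabs):
        yc, xc = src.lateral_coords(slab)
        ny, nx = slab.lateral_shape
        for iz, z in enumerate(slab.z_centers):
            planes.append((float(z), src_offs[si] + iz * ny * nx, yc, xc, ny, nx, slab.voxel_volume))
    planes.sort(key=lambda p: p[0])
    z_src = np.array([p[0] for p in planes])

    rows, cols, vals = [], [], []
    dst_offs = _flat_offsets(dst)

    def add_plane(plane, yq, xq, row_idx, weight, dv_dst):
        _, base, yc, xc, ny, nx, dv_src = plane
        yqc = np.clip(yq, yc[0], yc[-1]) if len(yc) > 1 else np.full_like(yq, yc[0])
        xqc = np.clip(xq, xc[0], xc[-1]) if len(xc) > 1 else np.full_like(xq, xc[0])
        if len(yc) > 1:
            iy = np.clip(np.searchsorted(yc, yqc) - 1, 0, ny - 2)
            wy = (yqc - yc[iy]) / (yc[iy + 1] - yc[iy])
        else:
            iy, wy = np.zeros(len(yq), dtype=int), np.zeros(len(yq))
        if len(xc) > 1:
            ix = np.clip(np.searchsorted(xc, xqc) - 1, 0, nx - 2)
            wx = (xqc - xc[ix]) / (xc[ix + 1] - xc[ix])
        else:
            ix, wx = np.zeros(len(xq), dtype=int), np.zeros(len(xq))
        # outer product of the per-axis stencils over the dst lateral grid
        scale = weight * dv_dst / dv_src
        for dy, fy in ((0, 1 - wy), (1, wy)):
            if ny == 1 and dy == 1:
                continue
            for dx, fx in ((0, 1 - wx), (1, wx)):
                if nx == 1 and dx == 1:
                    continue
                w2 = fy[:, None] * fx[None, :] * scale
                col = base + (iy[:, None] + dy) * nx + (ix[None, :] + dx)
                keep = w2 > 1e-12
                rows.append(row_idx[keep])
                cols.append(col[keep])
                vals.append(w2[keep])

    for di, dslab in enumerate(dst.slabs):
        yq, xq = dst.lateral_coords(dslab)
        ny_d, nx_d = dslab.lateral_shape
        lat_idx = np.arange(ny_d * nx_d).reshape(ny_d, nx_d)
        for iz, z in enumerate(dslab.z_centers):
            row_idx = dst_offs[di] + iz * ny_d * nx_d + lat_idx
            if len(z_src) == 1:
                add_plane(planes[0], yq, xq, row_idx, 1.0, dslab.voxel_volume)
                continue
            j = int(np.clip(np.searchsorted(z_src, z) - 1, 0, len(z_src) - 2))
            w = float(np.clip((z - z_src[j]) / (z_src[j + 1] - z_src[j]), 0.0, 1.0))
            if w < 1.0:
                add_plane(planes[j], yq, xq, row_idx, 1.0 - w, dslab.voxel_volume)
            if w > 0.0:
                add_plane(planes[j + 1], yq, xq, row_idx, w, dslab.voxel_volume)
    mat = sparse.coo_matrix(
        (np.concatenate([v.ravel() for v in vals]),
         (np.concatenate([r.ravel() for r in rows]), np.concatenate([c.ravel() for c in cols]))),
        shape=(dst.voxel_count(), n_src),
    )
    return mat.tocsr()


def _flatten(vol: MultiscaleVolume) -> np.ndarray:
    return np.concatenate([a.ravel() for a in vol.slab_data])


def _unflatten(vec: np.ndarray, grid: MultiscaleGrid) -> MultiscaleVolume:
    offs = _flat_offsets(grid)
    data = [
        vec[offs[i] : offs[i + 1]].reshape(s.shape) for i, s in enumerate(grid.slabs)
    ]
    return MultiscaleVolume(grid, data)


def scatter_grid_for(grid: MultiscaleGrid) -> MultiscaleGrid:
    """Uniform auxiliary grid on which the inverse-square kernel acts."""
    step0 = grid.lens_pitch_sample
    lat = 2.0 * step0
    ax = max(lat, min(s.axial_step for s in grid.slabs))
    nz = max(2, int(round((grid.z_max - grid.z_min) / ax)))
    shape = tuple(max(2, int(math.ceil(n / 2))) for n in grid.num_lenses)
    return uniform_grid(
        grid.z_min,
        grid.z_max,
        (grid.z_max - grid.z_min) / nz,
        lat,
        shape,
        lens_pitch_sample=step0,
        num_lenses=grid.num_lenses,
    )


# ---------------------------------------------------------------------------
# the kernel and operator
# ---------------------------------------------------------------------------

def build_inverse_square_kernel(shape, steps, truncate_ratio: float = 1e-4) -> np.ndarray:
    """Full kernel K(dr) = dV/||dr||^2 on offsets spanning a (nz, ny, nx) grid.

    Self-voxel value = K at half the voxel diagonal; entries below
    ``truncate_ratio`` x the nearest-neighbour value are zeroed.
    """
    nz, ny, nx = shape
    dz, dy, dx = steps
    zz = (np.arange(-(nz - 1), nz) * dz)[:, None, None]
    yy = (np.arange(-(ny - 1), ny) * dy)[None, :, None]
    xx = (np.arange(-(nx - 1), nx) * dx)[None, None, :]
    r2 = zz**2 + yy**2 + xx**2
    dv = dz * dy * dx
    half_diag2 = 0.25 * (dz**2 + dy**2 + dx**2)
    with np.errstate(divide="ignore"):
        kern = dv / np.where(r2 > 0, r2, half_diag2)
    nn2 = min(dz, dy, dx) ** 2
    kern[kern < truncate_ratio * (dv / nn2)] = 0.0
    return kern


class ScatterOperator:
    """Applies the discretised inverse-square scattering to volumes on a grid.

    Routes the product F*I through a uniform auxiliary grid (identity when
    the grid is already a single uniform slab), convolves with the
    zero-padded FFT of the inverse-square kernel, and routes back. The
    transposes of the two sparse resampling matrices give the adjoint.
    """

    def __init__(self, grid: MultiscaleGrid):
        self.grid = grid
        if len(grid.slabs) == 1:
            self.sg = grid
        else:
            self.sg = scatter_grid_for(grid)
        self.A = interp_matrix(grid, self.sg)  # multiscale -> uniform
        self.B = interp_matrix(self.sg, grid)  # uniform -> multiscale
        slab = self.sg.slabs[0]
        self.sg_shape = slab.shape
        steps = (slab.axial_step, slab.lateral_step, slab.lateral_step)
        kern = build_inverse_square_kernel(self.sg_shape, steps)
        self._fshape = tuple(next_fast_len(s + k - 1) for s, k in zip(self.sg_shape, kern.shape))
        self._kfft = rfftn(kern, s=self._fshape)
        self._crop = tuple(s - 1 for s in self.sg_shape)

    def _conv(self, arr: np.ndarray) -> np.ndarray:
        full = irfftn(rfftn(arr, s=self._fshape) * self._kfft, s=self._fshape)
        sl = tuple(slice(c, c + s) for c, s in zip(self._crop, self.sg_shape))
        return full[sl]

    def apply_product(self, product: MultiscaleVolume) -> MultiscaleVolume:
        """0.5 * K convolved with an (F*I) product volume."""
        vec = self.A @ _flatten(product)
        conv = self._conv(vec.reshape(self.sg_shape))
        out = self.B @ conv.ravel()
        return _unflatten(0.5 * out, self.grid)

    def adjoint_product(self, vol: MultiscaleVolume) -> MultiscaleVolume:
        """Adjoint of :meth:`apply_product` (K is symmetric under flip)."""
        vec = self.B.T @ _flatten(vol)
        conv = self._conv(vec.reshape(self.sg_shape))
        out = self.A.T @ conv.ravel()
        return _unflatten(0.5 * out, self.grid)


def scattered_intensity(
    emission: MultiscaleVolume,
    potential: ScatteringPotential,
    operator: ScatterOperator | None = None,
) -> MultiscaleVolume:
    """Scattered photon field produced by emission through the potential."""
    if emission.grid != potential.grid:
        raise ContractError("emission and potential must share one grid")
    op = operator or ScatterOperator(emission.grid)
    out = op.apply_product(emission * potential)
    return out.map(lambda a: np.maximum(a, 0.0))


def scattered_intensity_direct(
    emission: MultiscaleVolume, potential: ScatteringPotential
) -> MultiscaleVolume:
    """O(N^2) direct-sum evaluation on a single uniform slab (oracle-grade,
    small grids only)."""
    if emission.grid != potential.grid or len(emission.grid.slabs) != 1:
        raise ContractError("direct evaluation requires a shared single-slab grid")
    slab = emission.grid.slabs[0]
    dz, dl = slab.axial_step, slab.lateral_step
    dv = slab.voxel_volume
    half_diag2 = 0.25 * (dz**2 + 2 * dl**2)
    prod = (emission.slab_data[0] * potential.slab_data[0])
    nz, ny, nx = prod.shape
    out = np.zeros_like(prod)
    idx = np.argwhere(prod != 0)
    zc = np.arange(nz) * dz
    yc = np.arange(ny) * dl
    xc = np.arange(nx) * dl
    for (iz, iy, ix) in idx:
        r2 = (
            (zc[:, None, None] - zc[iz]) ** 2
            + (yc[None, :, None] - yc[iy]) ** 2
            + (xc[None, None, :] - xc[ix]) ** 2
        )
        r2[iz, iy, ix] = half_diag2
        out += 0.5 * prod[iz, iy, ix] * dv / r2
    return MultiscaleVolume(emission.grid, [out])


# ---------------------------------------------------------------------------
# potential update
# ---------------------------------------------------------------------------

def update_potential(
    emission: MultiscaleVolume,
    views: np.ndarray,
    projection,
    potential_prev: ScatteringPotential,
    lambda_f: float = 1e-3,
    n_steps: int = 1,
    scatter_op: ScatterOperator | None = None,
    step_init: float | None = None,
    extra_monitor=None,
) -> tuple[ScatteringPotential, float]:
    """Projected-gradient update of F on the misfit
    ``||P(I + S(F, I)) - y||^2 + lambda * ||F||^2`` holding I fixed.

    ``projection`` is a ProjectionOperator; backtracking halves the step
    until the misfit (and any ``extra_monitor(F)``) is non-increasing, so
    the accepted step never degrades the fit. Returns the updated potential
    and the last accepted step size (reuse it as ``step_init`` next call).
    """
    if not np.all(np.isfinite(views)):
        raise ContractError("views contain non-finite values")
    if not hasattr(projection, "forward"):  # a PhaseSpacePSF was passed
        from .projection import ProjectionOperator

        projection = ProjectionOperator(projection, emission.grid)
    op = scatter_op or ScatterOperator(emission.grid)
    lam = lambda_f * float(np.mean(views)) ** 2  # relative to data scale

    def misfit(F: ScatteringPotential) -> float:
        T = emission + op.apply_product(emission * F)
        r = projection.forward(T) - views
        return float(np.sum(r * r)) + lam * F.dot(F)

    F = potential_prev.copy()
    loss = misfit(F)
    t = step_init
    for _ in range(n_steps):
        T = emission + op.apply_product(emission * F)
        resid = projection.forward(T) - views
        g_vol = projection.adjoint(resid)
        grad = (emission * op.adjoint_product(g_vol)).map(lambda a: 2.0 * a)
        grad = grad + F.map(lambda a: 2.0 * lam * a)
        gmax = grad.map(np.abs).max()
        if gmax == 0.0:
            break
        # the misfit is quadratic in F, so the optimal step along the
        # gradient is exact: t* = |g|^2 / (2 |J g|^2 + 2 lam |g|^2)
        g2 = grad.dot(grad)
        Jg = projection.forward(op.apply_product(emission * grad))
        denom = 2.0 * float(np.sum(Jg * Jg)) + 2.0 * lam * g2
        if denom > 0:
            t = g2 / denom
        elif t is None:
            t = (F.max() + emission.max() * 1e-3 + 1e-12) / gmax
        accepted = False
        for _bt in range(25):
            cand = ScatteringPotential(
                F.grid, [(a - t * g) for a, g in zip(F.slab_data, grad.slab_data)]
            ).clip_nonneg()
            cand = ScatteringPotential(cand.grid, cand.slab_data)
            new_loss = misfit(cand)
            ok = new_loss <= loss * (1 + 1e-12)
            if ok and extra_monitor is not None:
                ok = extra_monitor(cand)
            if ok:
                F, loss, accepted = cand, new_loss, True
                break
            t *= 0.5
        if not accepted:
            break
    return ScatteringPotential(F.grid, F.slab_data), (t if t is not None else 0.0)
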