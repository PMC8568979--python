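"""Pixel realignment between raw sensor frames and 4D phase-space views.

A raw light-field frame interleaves position (which microlens) and angle
(which pixel behind that lens). Realignment is a pure permutation for
integral lens centres: ``views[u, v, j, i]`` collects the sensor pixel at
lens (j, i) with intra-lens offset (u, v), producing one low-resolution
image of the sample per viewing angle. Photon counts are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .config import OpticalConfig
from .errors import ContractError, GeometryError
from .psf import bin_kernel_angles, symmetric_angle_groups

__all__ = ["RawLightFieldFrame", "PhaseSpaceViews", "realign", "inverse_realign", "bin_views"]


@dataclass
class RawLightFieldFrame:
    """A raw sensor frame plus the lens-grid geometry needed to realign it.

    ``lens_grid_origin`` is the (row, col) sub-pixel sensor coordinate of the
    centre of microlens (0, 0); rectification (finding it) is upstream of
    this package.
    """

    sensor_image: np.ndarray
    config: OpticalConfig
    lens_grid_origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.sensor_image = np.asarray(self.sensor_image, dtype=float)
        if self.sensor_image.ndim != 2:
            raise ContractError("sensor_image must be 2D")
        if self.lens_grid_origin is None:
            h = self.config.angular_half
            self.lens_grid_origin = (float(h), float(h))


@dataclass
class PhaseSpaceViews:
    """4D realigned measurement: (angular u, angular v, lens row, lens col)."""

    views: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=float)
        if self.views.ndim != 4:
            raise ContractError("views must be 4D (u, v, lens_y, lens_x)")

    @property
    def angular_count(self) -> tuple[int, int]:
        return self.views.shape[:2]

    @property
    def lens_shape(self) -> tuple[int, int]:
        return self.views.shape[2:]

    def total(self) -> float:
        return float(self.views.sum())


def realign(frame: RawLightFieldFrame) -> PhaseSpaceViews:
    """Realign a raw frame into angular components.

    For non-integral lens centres the sensor is first resampled onto an
    integral grid with bilinear interpolation (monotone, non-negativity
    preserving); for integral centres the operation is an exact permutation.
    """
    cfg = frame.config
    ppl = cfg.pixels_per_lens
    h = cfg.angular_half
    n_ly, n_lx = cfg.num_lenses
    oy, ox = frame.lens_grid_origin
    img = frame.sensor_image

    integral = abs(oy - round(oy)) < 1e-9 and abs(ox - round(ox)) < 1e-9
    if integral:
        r0 = int(round(oy)) - h
        c0 = int(round(ox)) - h
        if r0 < 0 or c0 < 0 or r0 + n_ly * ppl > img.shape[0] or c0 + n_lx * ppl > img.shape[1]:
            raise GeometryError(
                f"lens grid ({n_ly}x{n_lx} lenses, {ppl} px/lens, origin {frame.lens_grid_origin}) "
                f"extends beyond the {img.shape} sensor"
            )
        region = img[r0 : r0 + n_ly * ppl, c0 : c0 + n_lx * ppl]
    else:
        rows = oy - h + np.arange(n_ly * ppl)
        cols = ox - h + np.arange(n_lx * ppl)
        if rows[0] < -0.5 or cols[0] < -0.5 or rows[-1] > img.shape[0] - 0.5 or cols[-1] > img.shape[1] - 0.5:
            raise GeometryError("lens grid extends beyond the sensor")
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        region = map_coordinates(img, [rr, cc], order=1, mode="nearest")
    views = np.ascontiguousarray(
        region.reshape(n_ly, ppl, n_lx, ppl).transpose(1, 3, 0, 2)
    )
    return PhaseSpaceViews(views=views, config=cfg)


def inverse_realign(views: PhaseSpaceViews, config: OpticalConfig | None = None) -> RawLightFieldFrame:
    """Exact inverse permutation of :func:`realign` (integral lens centres).

    The returned frame covers exactly the lens region, with the first lens
    centre at pixel (h, h).
    """
    cfg = config or views.config
    ppl = cfg.pixels_per_lens
    nu, nv = views.angular_count
    if (nu, nv) != (ppl, ppl):
        raise ContractError(
            f"views have {nu}x{nv} angular components but the config expects "
            f"{ppl}x{ppl}; angularly binned views cannot be mapped back to the sensor"
        )
    n_ly, n_lx = views.lens_shape
    if (n_ly, n_lx) != tuple(cfg.num_lenses):
        raise ContractError(f"views lens grid {views.lens_shape} != config num_lenses {cfg.num_lenses}")
    sensor = np.ascontiguousarray(
        views.views.transpose(2, 0, 3, 1).reshape(n_ly * ppl, n_lx * ppl)
    )
    return RawLightFieldFrame(sensor_image=sensor, config=cfg)


def bin_views(views: PhaseSpaceViews, n_bins: int) -> PhaseSpaceViews:
    """Sum angular components into ``n_bins`` x ``n_bins`` symmetric groups.

    Photon counts are conserved; use the matching ``angular_bins`` option of
    the PSF simulator so forward models stay consistent.
    """
    groups = symmetric_angle_groups(views.views.shape[0], n_bins)
    return PhaseSpaceViews(views=bin_kernel_angles(views.views, groups), config=views.config)
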