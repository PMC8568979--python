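"""Quantitative evaluation: SBR, FWHM, Pearson correlation, dF/F0 traces."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .grid import MultiscaleVolume

__all__ = ["Roi", "Trace", "compute_sbr", "fwhm", "pearson", "extract_dff_traces", "roi_mean"]


@dataclass(frozen=True)
class Roi:
    """Axis-aligned box ROI: centre and extent in physical um (z, y, x)."""

    center: tuple[float, float, float]
    extent: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent):
            raise ContractError("ROI extent must be positive")


@dataclass
class Trace:
    """Time series of mean ROI intensity with its dF/F0 baseline.

    F0 is the mean over time points whose raw value lies below 120% of the
    trace average; if no point qualifies, F0 falls back to the plain mean
    and ``baseline_flagged`` is set.
    """

    values: np.ndarray
    frame_rate: float = 1.0
    f0: float = 0.0
    dff: np.ndarray | None = None
    baseline_flagged: bool = False


def roi_mean(volume: MultiscaleVolume, roi: Roi) -> float:
    """Mean voxel intensity inside an ROI (voxels whose centre falls in the box)."""
    grid = volume.grid
    cz, cy, cx = roi.center
    ez, ey, ex = roi.extent
    vals = []
    for slab, data in zip(grid.slabs, volume.slab_data):
        zc = slab.z_centers
        zi = np.where(np.abs(zc - cz) <= ez / 2)[0]
        if len(zi) == 0:
            continue
        yc, xc = grid.lateral_coords(slab)
        yi = np.where(np.abs(yc - cy) <= ey / 2)[0]
        xi = np.where(np.abs(xc - cx) <= ex / 2)[0]
        if len(yi) == 0 or len(xi) == 0:
            continue
        vals.append(data[np.ix_(zi, yi, xi)].ravel())
    if not vals:
        raise ContractError(f"ROI at {roi.center} um contains no voxels of the volume")
    return float(np.mean(np.concatenate(vals)))


def compute_sbr(
    recon: MultiscaleVolume,
    signal_rois: list[Roi],
    background_roi: Roi,
) -> tuple[float, float]:
    """Signal-to-background ratio of a reconstruction.

    Signal = mean over the per-ROI mean intensities of the beads/somas;
    background = mean intensity of a sample-free region. Returns
    (linear ratio, dB) with the 10*log10 intensity convention. A zero
    background yields an inf ratio rather than an error.
    """
    if not signal_rois:
        raise ContractError("need at least one signal ROI")
    sig = float(np.mean([roi_mean(recon, r) for r in signal_rois]))
    bg = roi_mean(recon, background_roi)
    if bg <= 0:
        return math.inf, math.inf
    ratio = sig / bg
    return ratio, 10.0 * math.log10(ratio)


def fwhm(profile, sampling: float = 1.0) -> float:
    """Full width at half maximum of a 1D profile by linear interpolation.

    The half-maximum crossings nearest the peak on each side are located by
    linear interpolation; errors if the profile is flat or the half level is
    never crossed on either side (truncated profile).
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 3:
        raise ContractError("profile must be 1D with at least 3 samples")
    imax = int(np.argmax(p))
    peak = p[imax]
    base = min(p[0], p[-1])
    if peak <= base or np.ptp(p) == 0:
        raise ContractError("profile has no unique interior maximum above its boundaries")
    half = peak / 2.0

    def cross(idx_range, direction):
        prev = imax
        for i in idx_range:
            if p[i] <= half:
                # linear interpolation between i and the previous sample
                frac = (p[prev] - half) / (p[prev] - p[i])
                return prev + direction * frac
            prev = i
        raise ContractError("profile truncated: half maximum not crossed")

    left = cross(range(imax - 1, -1, -1), -1.0)
    right = cross(range(imax + 1, len(p)), +1.0)
    return float((right - left) * sampling)


def pearson(X, Y) -> float:
    """Pearson correlation r = E[(X - X̄)(Y - Ȳ)] / (sigma_X sigma_Y),
    population-normalised."""
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ContractError("series must have equal length >= 2")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ContractError("correlation undefined for zero-variance series")
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return float(np.clip(r, -1.0, 1.0))


def extract_dff_traces(
    series: list[MultiscaleVolume],
    rois: list[Roi],
    frame_rate: float = 1.0,
) -> list[Trace]:
    """Per-ROI dF/F0 traces from a time-ordered volume sequence.

    F(t) is the ROI mean intensity; F0 the mean of {F(t) : F(t) < 1.2 *
    mean(F)}; dF/F0 = (F - F0)/F0. A trace entirely above the threshold is
    flagged and uses the plain mean as baseline.
    """
    if len(series) < 2:
        raise ContractError("need at least 2 time points")
    traces = []
    for roi in rois:
        f = np.array([roi_mean(v, roi) for v in series])
        thresh = 1.2 * f.mean()
        below = f < thresh
        flagged = not below.any()
        f0 = float(f.mean() if flagged else f[below].mean())
        dff = (f - f0) / f0 if f0 != 0 else np.zeros_like(f)
        traces.append(Trace(values=f, frame_rate=frame_rate, f0=f0, dff=dff, baseline_flagged=flagged))
    return traces
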