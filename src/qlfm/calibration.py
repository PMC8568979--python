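"""Phase-retrieval PSF calibration from a single bead image.

Each angular component (u, v) of the light field passes through one
sub-aperture of the pupil, so a local wavefront tilt over that sub-aperture
displaces that component's image of a point source. Calibration therefore:
(1) cross-correlates each captured angular view of an isolated
sub-diffraction bead with the corresponding simulated view to measure
per-angle sub-pixel displacements; (2) converts displacements to local
wavefront slopes and integrates them zonally (Shack-Hartmann style least
squares) into a continuous pupil phase; (3) fits Noll Zernike modes to the
zonal surface; (4) feeds the accumulated coefficients back into the wave
model and repeats until the phase map converges (typically a few
iterations, because the displacement-slope linearisation is only exact for
smooth, moderate aberrations).

Geometry: view displacement d (um, sample plane) relates to the wavefront
W (um) over normalised pupil radius rho as d = (1/NA) dW/drho, the ray
transverse aberration of a focused beam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.fft import fft2, ifft2
from scipy.sparse.linalg import lsqr

from .config import OpticalConfig
from .errors import CalibrationError, ContractError
from .phase_space import PhaseSpaceViews, RawLightFieldFrame, realign
from .psf import PhaseSpacePSF, PSFSimulator
from .zernike import AberrationWavefront, fit_zernike_coefficients, zernike_wavefront

__all__ = [
    "SubapertureShifts",
    "estimate_subaperture_shifts",
    "integrate_shifts_to_wavefront",
    "fit_zernike",
    "CalibrationResult",
    "calibrate_psf",
]


@dataclass
class SubapertureShifts:
    """Per-angle displacement field (lens-grid pixels) with NCC scores."""

    shifts: np.ndarray  # (nu, nv, 2): (dy, dx), captured relative to simulated
    scores: np.ndarray  # (nu, nv) peak normalised cross-correlation
    valid: np.ndarray  # (nu, nv) bool

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def _ncc_shift(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Sub-pixel shift maximising the normalised cross-correlation of a
    relative to b (a ~ b shifted by the returned (dy, dx)); parabolic peak
    interpolation."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0, 0.0, 0.0
    ny, nx = a.shape
    corr = np.real(ifft2(fft2(a) * np.conj(fft2(b)))) / (na * nb)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    score = float(corr[peak])

    def parabolic(cm, c0, cp):
        denom = cm - 2 * c0 + cp
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))

    py, px = peak
    dy = parabolic(corr[(py - 1) % ny, px], corr[py, px], corr[(py + 1) % ny, px])
    dx = parabolic(corr[py, (px - 1) % nx], corr[py, px], corr[py, (px + 1) % nx])
    sy = py + dy
    sx = px + dx
    if sy > ny / 2:
        sy -= ny
    if sx > nx / 2:
        sx -= nx
    return sy, sx, score


def estimate_subaperture_shifts(
    captured: PhaseSpaceViews,
    simulated: PhaseSpacePSF,
    min_score: float = 0.2,
) -> SubapertureShifts:
    """Per-angle sub-pixel displacement between a captured bead image and
    the simulated PSF; angles with peak correlation below ``min_score`` are
    flagged invalid."""
    nu, nv = captured.angular_count
    if (nu, nv) != simulated.n_angles:
        raise ContractError(
            f"captured views have {nu}x{nv} angles, simulated PSF {simulated.n_angles}"
        )
    kern = simulated.kernels[0]
    ly, lx = captured.lens_shape
    shifts = np.zeros((nu, nv, 2))
    scores = np.zeros((nu, nv))
    for iu in range(nu):
        for iv in range(nv):
            sim_view = _embed(kern[iu, iv], (ly, lx))
            dy, dx, s = _ncc_shift(captured.views[iu, iv], sim_view)
            shifts[iu, iv] = (dy, dx)
            scores[iu, iv] = s
    valid = scores >= min_score
    if not valid.any():
        raise CalibrationError(
            "no angular component correlates with the simulated PSF "
            f"(max score {scores.max():.3f} < {min_score}); calibration impossible"
        )
    return SubapertureShifts(shifts=shifts, scores=scores, valid=valid)


def _embed(kern: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Centre-embed (or centre-crop) a kernel into the lens-grid shape."""
    out = np.zeros(shape)
    ky, kx = kern.shape
    src_y = slice(max(0, (ky - shape[0]) // 2), max(0, (ky - shape[0]) // 2) + min(ky, shape[0]))
    src_x = slice(max(0, (kx - shape[1]) // 2), max(0, (kx - shape[1]) // 2) + min(kx, shape[1]))
    dst_y = slice(max(0, (shape[0] - ky) // 2), max(0, (shape[0] - ky) // 2) + min(ky, shape[0]))
    dst_x = slice(max(0, (shape[1] - kx) // 2), max(0, (shape[1] - kx) // 2) + min(kx, shape[1]))
    out[dst_y, dst_x] = kern[src_y, src_x]
    return out


def _pupil_coords(nu: int, nv: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised pupil (rho_y, rho_x) of each angular component and the
    in-pupil mask. Component (u, v) maps to the pupil patch centred at
    (u, v)/u_max."""
    hu, hv = (nu - 1) / 2.0, (nv - 1) / 2.0
    gy = (np.arange(nu) - hu) / max(hu, 0.5)
    gx = (np.arange(nv) - hv) / max(hv, 0.5)
    ry, rx = np.meshgrid(gy, gx, indexing="ij")
    mask = np.hypot(ry, rx) <= 1.0 + 1e-9
    return ry, rx, mask


def integrate_shifts_to_wavefront(
    shifts: SubapertureShifts,
    config: OpticalConfig,
    min_valid_fraction: float = 0.6,
) -> AberrationWavefront:
    """Zonal least-squares integration of sub-aperture slopes to a pupil phase.

    Shifts (lens-grid pixels) are converted to sample-plane displacements
    d = shift * lens_pitch_sample and then to wavefront slopes
    dW/drho = d * NA (W in um, rho normalised); finite-difference equations
    between valid neighbouring sub-apertures are solved in least squares
    with the piston removed. The result carries the phase map on the
    angular grid plus its Zernike fit.
    """
    nu, nv = shifts.shifts.shape[:2]
    ry, rx, in_pupil = _pupil_coords(nu, nv)
    valid = shifts.valid & in_pupil
    n_total = int(in_pupil.sum())
    if valid.sum() < min_valid_fraction * n_total:
        raise CalibrationError(
            f"only {int(valid.sum())}/{n_total} sub-apertures valid "
            f"(need >= {min_valid_fraction:.0%})"
        )
    na = config.objective_na
    pitch = config.lens_pitch_sample
    # view displacement d (sample um) relates to the wavefront as
    # d = -(1/NA) dW/drho under the simulator's pupil phase sign convention
    # (transverse ray aberration of the focused beam)
    slope_y = -shifts.shifts[..., 0] * pitch * na  # dW/drho_y, W in um
    slope_x = -shifts.shifts[..., 1] * pitch * na
    # node numbering over valid sub-apertures
    node = -np.ones((nu, nv), dtype=int)
    ids = np.argwhere(valid)
    for k, (iu, iv) in enumerate(ids):
        node[iu, iv] = k
    n_nodes = len(ids)
    drho_u = ry[1, 0] - ry[0, 0] if nu > 1 else 1.0
    drho_v = rx[0, 1] - rx[0, 0] if nv > 1 else 1.0
    rows, cols, vals, rhs = [], [], [], []
    eq = 0
    for iu in range(nu):
        for iv in range(nv):
            if node[iu, iv] < 0:
                continue
            if iu + 1 < nu and node[iu + 1, iv] >= 0:
                rows += [eq, eq]
                cols += [node[iu + 1, iv], node[iu, iv]]
                vals += [1.0, -1.0]
                rhs.append(0.5 * (slope_y[iu, iv] + slope_y[iu + 1, iv]) * drho_u)
                eq += 1
            if iv + 1 < nv and node[iu, iv + 1] >= 0:
                rows += [eq, eq]
                cols += [node[iu, iv + 1], node[iu, iv]]
                vals += [1.0, -1.0]
                rhs.append(0.5 * (slope_x[iu, iv] + slope_x[iu, iv + 1]) * drho_v)
                eq += 1
    if eq < n_nodes - 1:
        raise CalibrationError(
            f"slope field too sparse to integrate: {eq} difference equations "
            f"for {n_nodes} sub-apertures (disconnected pupil regions)"
        )
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(eq, n_nodes)).tocsr()
    w = lsqr(A, np.asarray(rhs), atol=1e-12, btol=1e-12)[0]
    w -= w.mean()  # remove piston
    lam = config.emission_wavelength
    phase_map = np.full((nu, nv), np.nan)
    phase_map[valid] = 2.0 * math.pi * w / lam  # radians
    rho = np.hypot(ry, rx)
    theta = np.arctan2(ry, rx)
    n_modes = min(15, n_nodes)
    coeffs = fit_zernike_coefficients(phase_map, rho, theta, n_modes)
    return AberrationWavefront(zernike_coefficients=coeffs, pupil_phase_map=phase_map)


def fit_zernike(wavefront: AberrationWavefront, n_modes: int) -> np.ndarray:
    """Project a wavefront's sampled pupil phase onto Noll modes 1..n_modes.

    Returns coefficients in wavelengths. Piston/tip/tilt are reported but
    excluded from the PSF model by convention downstream.
    """
    n = wavefront.pupil_phase_map.shape[0]
    m = wavefront.pupil_phase_map.shape[1]
    gy = np.linspace(-1, 1, n) if n > 1 else np.zeros(1)
    gx = np.linspace(-1, 1, m) if m > 1 else np.zeros(1)
    ry, rx = np.meshgrid(gy, gx, indexing="ij")
    rho = np.hypot(ry, rx)
    theta = np.arctan2(ry, rx)
    return fit_zernike_coefficients(wavefront.pupil_phase_map, rho, theta, n_modes)


@dataclass
class CalibrationResult:
    wavefront: AberrationWavefront
    psf: PhaseSpacePSF
    iterations: int
    converged: bool
    score_history: list = field(default_factory=list)

    def __iter__(self):
        return iter((self.wavefront, self.psf))


def calibrate_psf(
    captured_bead_frame: RawLightFieldFrame,
    config: OpticalConfig,
    bead_depth: float = 0.0,
    n_modes: int = 15,
    tol: float = 1.0 / 50.0,
    max_iterations: int = 10,
    min_score: float = 0.2,
    damping: float = 1.0,
    sim_kwargs: dict | None = None,
) -> CalibrationResult:
    """Iterative phase-retrieval calibration of the system wavefront.

    The captured frame must contain one isolated (caller-cropped)
    sub-diffraction bead near the native objective plane. Iterates
    simulate -> correlate -> integrate -> Zernike fit -> accumulate until
    the RMS wavefront change drops below ``tol`` (wavelengths; default
    lambda/50) or ``max_iterations`` is reached.

    ``bead_depth`` is the bead's axial position (um). A moderately
    defocused bead (a few tens of um at low NA) spreads the PSF over many
    microlenses, which is what gives the per-angle correlations their
    Shack-Hartmann-style slope sensitivity; an in-focus bead keeps all
    energy under one lens and carries almost no sub-aperture information
    at lens-grid sampling.
    """
    captured = realign(captured_bead_frame)
    sim_kwargs = dict(sim_kwargs or {})
    coeffs = np.zeros(n_modes)
    score_history: list[float] = []
    converged = False
    it = 0
    psf = None
    for it in range(1, max_iterations + 1):
        wf = zernike_wavefront(coeffs)
        sim = PSFSimulator(config, wavefront=wf, **sim_kwargs)
        from .psf import compute_psf

        psf = compute_psf(config, [bead_depth], simulator=sim)
        shifts = estimate_subaperture_shifts(captured, psf, min_score=min_score)
        score_history.append(float(shifts.scores[shifts.valid].mean()))
        residual_wf = integrate_shifts_to_wavefront(shifts, config)
        delta = np.zeros(n_modes)
        k = min(n_modes, len(residual_wf.zernike_coefficients))
        delta[:k] = residual_wf.zernike_coefficients[:k]
        delta[:min(3, n_modes)] = 0.0  # piston/tip/tilt: bead position, not aberration
        coeffs = coeffs + damping * delta
        rms_change = math.sqrt(float(np.sum(delta[3:] ** 2))) if n_modes > 3 else 0.0
        if rms_change < tol:
            converged = True
            break
    final_wf = zernike_wavefront(coeffs)
    sim = PSFSimulator(config, wavefront=final_wf, **(sim_kwargs or {}))
    from .psf import compute_psf

    psf = compute_psf(config, [bead_depth], simulator=sim)
    return CalibrationResult(
        wavefront=final_wf,
        psf=psf,
        iterations=it,
        converged=converged,
        score_history=score_history,
    )
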