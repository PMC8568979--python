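"""Zernike polynomials (Noll indexing) and pupil wavefronts.

Coefficients are expressed in units of the emission wavelength; the pupil
phase map is in radians (phase = 2*pi * sum_j c_j Z_j). Noll normalisation
is used throughout: sqrt(n+1) for m = 0 and sqrt(2(n+1)) for the cosine /
sine terms, so every mode has unit RMS over the unit disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "noll_to_nm",
    "zernike",
    "zernike_basis",
    "AberrationWavefront",
    "zernike_wavefront",
    "fit_zernike_coefficients",
]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Map a Noll index j >= 1 to radial order n and signed azimuthal order m.

    Positive m denotes the cosine term, negative m the sine term.
    """
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    n = 0
    j_rem = j - 1
    while j_rem > n:
        n += 1
        j_rem -= n
    m_abs = n - 2 * ((n - j_rem) // 2)
    if m_abs == 0:
        return n, 0
    # Noll: even j -> cosine (m > 0), odd j -> sine (m < 0)
    return n, m_abs if j % 2 == 0 else -m_abs


def _radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the Noll-normalised Zernike mode Z_j at polar pupil coords."""
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n, m = noll_to_nm(j)
    r = _radial(n, abs(m), rho)
    if m == 0:
        return math.sqrt(n + 1) * r
    norm = math.sqrt(2 * (n + 1))
    if m > 0:
        return norm * r * np.cos(m * theta)
    return norm * r * np.sin(-m * theta)


def zernike_basis(n_modes: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Stack of modes Z_1..Z_n_modes evaluated on the given pupil coordinates."""
    return np.stack([zernike(j, rho, theta) for j in range(1, n_modes + 1)])


@dataclass
class AberrationWavefront:
    """Pupil-plane aberration: Zernike coefficients plus a sampled phase map.

    ``pupil_phase_map`` is in radians and NaN outside the unit pupil;
    ``zernike_coefficients`` in emission wavelengths, Noll-indexed from 1.
    The piston term is stored but carries no imaging information and is
    ignored by the forward model.
    """

    zernike_coefficients: np.ndarray
    pupil_phase_map: np.ndarray

    @property
    def pupil_samples(self) -> int:
        return self.pupil_phase_map.shape[0]

    @property
    def n_modes(self) -> int:
        return len(self.zernike_coefficients)

    def phase(self, rho: np.ndarray, theta: np.ndarray, include_piston: bool = False) -> np.ndarray:
        """Phase in radians at arbitrary pupil coordinates, from coefficients."""
        out = np.zeros(np.broadcast(rho, theta).shape, dtype=float)
        for j, c in enumerate(self.zernike_coefficients, start=1):
            if c == 0.0 or (j == 1 and not include_piston):
                continue
            out += c * zernike(j, rho, theta)
        return 2.0 * math.pi * out

    def rms_wavelengths(self, exclude_piston: bool = True) -> float:
        """RMS wavefront error in wavelengths (Noll modes are unit-RMS)."""
        c = np.asarray(self.zernike_coefficients, dtype=float)
        if exclude_piston and len(c) >= 1:
            c = c[1:]
        return float(np.sqrt(np.sum(c**2)))


def _pupil_grid(pupil_samples: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.linspace(-1.0, 1.0, pupil_samples)
    yy, xx = np.meshgrid(x, x, indexing="ij")
    rho = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    return rho, theta, rho <= 1.0


def zernike_wavefront(coefficients, pupil_samples: int = 256) -> AberrationWavefront:
    """Build a wavefront from Noll-ordered coefficients (in wavelengths).

    An empty coefficient list yields a flat wavefront. The returned phase map
    covers the unit disk on a ``pupil_samples``-wide Cartesian grid (NaN
    outside the pupil).
    """
    if pupil_samples < 16:
        raise ConfigurationError(f"pupil_samples must be >= 16, got {pupil_samples}")
    c = np.atleast_1d(np.asarray(coefficients, dtype=float)) if len(list(coefficients)) else np.zeros(0)
    if c.size and not np.all(np.isfinite(c)):
        raise ConfigurationError("Zernike coefficients must be finite")
    rho, theta, mask = _pupil_grid(pupil_samples)
    phase = np.zeros_like(rho)
    for j, cj in enumerate(c, start=1):
        if cj != 0.0:
            phase += cj * zernike(j, rho, theta)
    phase *= 2.0 * math.pi
    phase[~mask] = np.nan
    return AberrationWavefront(zernike_coefficients=c.copy(), pupil_phase_map=phase)


def fit_zernike_coefficients(
    phase: np.ndarray,
    rho: np.ndarray,
    theta: np.ndarray,
    n_modes: int,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares projection of a sampled phase (radians) onto Noll modes.

    Returns coefficients in wavelengths. ``mask`` selects valid samples;
    NaNs in ``phase`` are excluded automatically.
    """
    phase = np.asarray(phase, dtype=float)
    valid = np.isfinite(phase)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    valid &= np.asarray(rho) <= 1.0
    nv = int(valid.sum())
    if nv < n_modes:
        raise ConfigurationError(f"n_modes={n_modes} exceeds the {nv} valid pupil samples")
    basis = zernike_basis(n_modes, np.asarray(rho)[valid], np.asarray(theta)[valid])
    coeffs, *_ = np.linalg.lstsq(basis.T, phase[valid], rcond=None)
    return coeffs / (2.0 * math.pi)
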