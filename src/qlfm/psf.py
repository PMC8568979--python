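"""Wave-optics simulation of the light-field PSF.

For a point source at signed depth z (um, z = 0 at the native objective
plane, +z toward the objective) the scalar field is built as a Debye-type
pupil integral: the pupil phase combines high-NA defocus
``k0 * n * z * cos(theta)`` with any aberration wavefront, the pupil is
transformed to the microlens-array plane with a zoomed DFT (chirp-z), each
square 100%-fill microlens applies its thin-lens quadratic phase, the field
is Fresnel-propagated one MLA focal length to the sensor, and the intensity
is box-integrated over camera pixel areas. Realigning the sensor patch per
lens yields the phase-space PSF: one shift-invariant lateral kernel per
angular component (u, v) per depth.

The per-angle shift-invariant (phase-space) approximation replaces the
spatially varying sensor-level PSF; it is what makes large volumes
tractable, at the cost of sub-lens-pitch detail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft2, ifft2, fftfreq, next_fast_len
from scipy.ndimage import uniform_filter
from scipy.signal import czt

from .config import OpticalConfig
from .errors import ConfigurationError, ContractError
from .zernike import AberrationWavefront

__all__ = [
    "PhaseSpacePSF",
    "PSFSimulator",
    "compute_psf",
    "symmetric_angle_groups",
    "bin_kernel_angles",
    "coarsen_kernel",
]


# ---------------------------------------------------------------------------
# zoomed DFT
# ---------------------------------------------------------------------------

def zoom_dft2(a: np.ndarray, theta: float, out_count: int) -> np.ndarray:
    """2D centred zoomed DFT.

    Computes ``U[m1, m2] = sum_{n1,n2} a[n1,n2] exp(i*theta*(m1-m0)*(n1-n0))
    * exp(i*theta*(m2-m0)*(n2-n0))`` with ``n0 = (N-1)/2``, ``m0 = (M-1)/2``
    via Bluestein's algorithm, i.e. a Fourier transform with arbitrary
    output spacing encoded in ``theta = k * dx_out * ds_in``.
    """
    out = _zoom_dft_axis(a, theta, out_count, axis=0)
    return _zoom_dft_axis(out, theta, out_count, axis=1)


def _zoom_dft_axis(a: np.ndarray, theta: float, M: int, axis: int) -> np.ndarray:
    N = a.shape[axis]
    n = np.arange(N)
    m = np.arange(M)
    n0 = (N - 1) / 2.0
    m0 = (M - 1) / 2.0
    pre = np.exp(-1j * theta * m0 * n)
    shape = [1] * a.ndim
    shape[axis] = N
    b = a * pre.reshape(shape)
    c = czt(b, M, w=np.exp(1j * theta), axis=axis)
    post = np.exp(1j * theta * (m0 * n0 - m * n0))
    shape[axis] = M
    return c * post.reshape(shape)


# ---------------------------------------------------------------------------
# angular grouping / kernel resampling helpers
# ---------------------------------------------------------------------------

def symmetric_angle_groups(pixels_per_lens: int, n_bins: int) -> list[np.ndarray]:
    """Split ``pixels_per_lens`` angular indices into ``n_bins`` contiguous
    groups, symmetric about the centre (both odd)."""
    if pixels_per_lens % 2 == 0 or n_bins % 2 == 0:
        raise ConfigurationError("pixels_per_lens and n_bins must both be odd")
    if n_bins > pixels_per_lens:
        raise ConfigurationError("n_bins cannot exceed pixels_per_lens")
    sizes = [pixels_per_lens // n_bins] * n_bins
    rem = pixels_per_lens - sum(sizes)
    centre = n_bins // 2
    if rem % 2 == 1:
        sizes[centre] += 1
        rem -= 1
    i = 0
    while rem > 0:  # hand out mirror pairs, outermost bins first
        sizes[i] += 1
        sizes[n_bins - 1 - i] += 1
        rem -= 2
        i = (i + 1) % max(centre, 1)
    bounds = np.cumsum([0] + sizes)
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(n_bins)]


def bin_kernel_angles(kern: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Sum kernel (or view) angular axes 0 and 1 over index groups."""
    u_binned = np.stack([kern[g].sum(axis=0) for g in groups])
    return np.stack([u_binned[:, g].sum(axis=1) for g in groups], axis=1)


def coarsen_kernel(kern: np.ndarray, q: int) -> np.ndarray:
    """Kernel for a slab sampled ``q`` x coarser than the lens grid.

    A coarse voxel is a q x q block of lens cells at uniform density, so the
    coarse kernel is the lens-grid kernel mean-filtered over the block
    footprint and subsampled at block centres (odd count, centre preserved).
    """
    if q == 1:
        return kern
    sm = uniform_filter(kern, size=(1, 1, q, q), mode="constant")
    c = (kern.shape[2] - 1) // 2
    t = c // q
    idx = c + q * np.arange(-t, t + 1)
    return sm[:, :, idx[:, None], idx[None, :]]


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

@dataclass
class PhaseSpacePSF:
    """Per-angular-component, per-depth lateral convolution kernels.

    ``kernels[d]`` has shape (nu, nv, ky, kx) and acts at lateral sampling
    ``lateral_factors[d]`` x the lens pitch at the sample plane. Kernels are
    jointly normalised so the total detected energy at z = 0 is 1.
    """

    config: OpticalConfig
    depth_list: np.ndarray
    kernels: list[np.ndarray]
    lateral_factors: list[int]
    angular_bins: int | None = None

    def __post_init__(self) -> None:
        self.depth_list = np.asarray(self.depth_list, dtype=float)
        if len(self.kernels) != len(self.depth_list) or len(self.lateral_factors) != len(self.depth_list):
            raise ContractError("depth_list, kernels and lateral_factors must have equal length")
        for k in self.kernels:
            if k.ndim != 4 or k.shape[2] % 2 == 0 or k.shape[3] % 2 == 0:
                raise ContractError("kernels must be 4D with odd lateral extent")

    @property
    def n_angles(self) -> tuple[int, int]:
        return self.kernels[0].shape[:2]

    def energy(self) -> np.ndarray:
        """Total detected energy per depth (coarse kernels weighted by q^2)."""
        return np.array(
            [k.sum() * q * q for k, q in zip(self.kernels, self.lateral_factors)]
        )

    def validate_energy(self, lo: float = 0.9, hi: float = 1.01) -> None:
        # hi allows ~1%: far-defocus disks are compact while the in-focus
        # Airy tails lose a little energy outside the finite window
        e = self.energy()
        i0 = int(np.argmin(np.abs(self.depth_list)))
        rel = e / e[i0]
        if np.any(rel < lo) or np.any(rel > hi):
            bad = np.where((rel < lo) | (rel > hi))[0]
            raise ConfigurationError(
                f"PSF energy bookkeeping violated at depths {self.depth_list[bad]} "
                f"(relative energies {rel[bad]}); enlarge the kernel support"
            )


class PSFSimulator:
    """Computes and caches phase-space PSF kernels for one configuration.

    Parameters
    ----------
    config : OpticalConfig
    wavefront : AberrationWavefront, optional
        Pupil aberration added to the defocus phase (piston ignored).
    osamp : int
        Sub-pixel sampling factor for box integration over camera pixels.
    pupil_samples : int
        Minimum pupil grid width; enlarged automatically when the defocus or
        window phase would otherwise alias. Kernels change by <1% when this
        is doubled at the default geometry.
    angular_bins : int, optional
        If set (odd), sensor pixels behind each lens are summed into
        angular_bins x angular_bins angular groups.
    """

    def __init__(
        self,
        config: OpticalConfig,
        wavefront: AberrationWavefront | None = None,
        osamp: int = 2,
        pupil_samples: int = 256,
        angular_bins: int | None = None,
        support_margin: float = 1.35,
        extra_lenses: int = 4,
        max_support: int = 201,
    ) -> None:
        self.config = config
        self.wavefront = wavefront
        self.osamp = int(osamp)
        self.pupil_samples = int(pupil_samples)
        self.angular_bins = angular_bins
        self.support_margin = support_margin
        self.extra_lenses = extra_lenses
        self.max_support = max_support
        self._groups = (
            symmetric_angle_groups(config.pixels_per_lens, angular_bins)
            if angular_bins
            else None
        )
        self._patch_cache: dict[int, np.ndarray] = {}
        self._kernel_cache: dict[tuple[int, int], np.ndarray] = {}
        self._norm: float | None = None

    # -- geometry helpers ---------------------------------------------------
    def blur_radius(self, z: float) -> float:
        """Geometric marginal-ray blur radius at the sample plane (um)."""
        c = self.config
        return abs(z) * c.objective_na / math.sqrt(
            c.immersion_index**2 - c.objective_na**2
        )

    def support_lenses(self, z: float) -> int:
        c = self.config
        dia = 2.0 * self.blur_radius(z) / c.lens_pitch_sample
        n = int(math.ceil(dia * self.support_margin)) + self.extra_lenses
        n = min(max(n, 7), self.max_support)
        return n if n % 2 == 1 else n + 1

    def _pupil_count(self, z: float, window_half: float) -> int:
        c = self.config
        k0 = 2 * math.pi / c.emission_wavelength
        na, n_imm = c.objective_na, c.immersion_index
        slope_win = k0 * window_half * c.image_side_na
        s = na / n_imm
        slope_def = k0 * abs(z) * na * s / math.sqrt(1 - s * s)
        slope_ab = 0.0
        if self.wavefront is not None:
            for j, cj in enumerate(self.wavefront.zernike_coefficients, start=1):
                if j > 1 and cj:
                    # crude slope bound: |grad Z_j| <= 2 n sqrt(n+1)
                    nn = int((math.sqrt(8 * j + 1) - 1) / 2)
                    slope_ab += 2 * math.pi * abs(cj) * 2 * nn * math.sqrt(nn + 1)
        need = int(math.ceil((slope_win + slope_def + slope_ab) * 2 / math.pi * 1.2))
        return max(self.pupil_samples, need)

    # -- field simulation ---------------------------------------------------
    def sensor_patch(self, z: float, support: int | None = None) -> np.ndarray:
        """Camera-pixel intensity patch for a point source at depth z,
        centred on the central microlens. Unnormalised."""
        key = (int(round(z * 1000.0)), support)
        if key in self._patch_cache:
            return self._patch_cache[key]
        c = self.config
        ppl = c.pixels_per_lens
        support = support or self.support_lenses(z)
        n_pix = support * ppl
        n_sim = n_pix * self.osamp
        delta = c.sensor_pixel_mla / self.osamp
        lam = c.emission_wavelength
        k0 = 2 * math.pi / lam

        # pupil field
        n_pup = self._pupil_count(z, window_half=n_sim * delta / 2.0)
        rho1 = np.linspace(-1.0, 1.0, n_pup)
        ryy, rxx = np.meshgrid(rho1, rho1, indexing="ij")
        rho = np.hypot(ryy, rxx)
        mask = rho <= 1.0
        s_obj = np.clip(c.objective_na * rho / c.immersion_index, 0.0, 1.0)
        phase = k0 * c.immersion_index * z * np.sqrt(1.0 - s_obj * s_obj)
        if self.wavefront is not None:
            phase = phase + self.wavefront.phase(rho, np.arctan2(ryy, rxx))
        pupil = np.where(mask, np.exp(1j * phase), 0.0).astype(np.complex128)

        # pupil -> MLA plane (zoomed DFT); spacing delta over n_sim samples
        # normalise so the pupil field carries unit energy regardless of the
        # (depth-dependent) pupil sampling; the sensor patch total is then
        # the detected fraction of the band-limited emission
        ds = c.image_side_na * (rho1[1] - rho1[0])
        pupil *= ds / math.sqrt(float(mask.sum()) * ds * ds)
        u_mla = zoom_dft2(pupil, k0 * delta * ds, n_sim) * ds
        del pupil

        # microlens array: square lenslets, 100% fill, thin-lens phase
        x = (np.arange(n_sim) - (n_sim - 1) / 2.0) * delta
        lens_of = (np.arange(n_sim) // self.osamp) // ppl
        centres = (lens_of - (support - 1) / 2.0) * c.mla_pitch
        xi = x - centres
        t1d = np.exp(-1j * k0 / (2.0 * c.mla_focal_length) * xi * xi)
        u_mla *= t1d[:, None]
        u_mla *= t1d[None, :]

        # Fresnel propagation over one MLA focal length (transfer function)
        pad = next_fast_len(n_sim + 2 * ppl * self.osamp)
        u_pad = np.zeros((pad, pad), dtype=np.complex128)
        off = (pad - n_sim) // 2
        u_pad[off : off + n_sim, off : off + n_sim] = u_mla
        del u_mla
        f = fftfreq(pad, delta)
        h1d = np.exp(-1j * math.pi * lam * c.mla_focal_length * f * f)
        u_pad = ifft2(fft2(u_pad) * h1d[:, None] * h1d[None, :])
        intensity = np.abs(u_pad[off : off + n_sim, off : off + n_sim]) ** 2
        del u_pad

        patch = intensity.reshape(n_pix, self.osamp, n_pix, self.osamp).sum(axis=(1, 3))
        self._patch_cache[key] = patch
        return patch

    def _normalisation(self) -> float:
        if self._norm is None:
            self._norm = float(self.sensor_patch(0.0).sum())
        return self._norm

    def kernel(self, z: float, factor: int = 1) -> np.ndarray:
        """Phase-space kernel (nu, nv, ky, kx) at depth z for a slab sampled
        ``factor`` x the lens pitch, normalised to unit z = 0 energy."""
        key = (int(round(z * 1000.0)), int(factor))
        if key in self._kernel_cache:
            return self._kernel_cache[key]
        patch = self.sensor_patch(z) / self._normalisation()
        ppl = self.config.pixels_per_lens
        support = patch.shape[0] // ppl
        kern = np.ascontiguousarray(
            patch.reshape(support, ppl, support, ppl).transpose(1, 3, 0, 2)
        )
        if self._groups is not None:
            kern = bin_kernel_angles(kern, self._groups)
        kern = coarsen_kernel(kern, int(factor))
        self._kernel_cache[key] = kern
        return kern

    def rebinned(self, angular_bins: int | None) -> "PSFSimulator":
        """A simulator with different angular binning sharing this one's
        (expensive) sensor-patch cache."""
        other = PSFSimulator(
            self.config,
            self.wavefront,
            osamp=self.osamp,
            pupil_samples=self.pupil_samples,
            angular_bins=angular_bins,
            support_margin=self.support_margin,
            extra_lenses=self.extra_lenses,
            max_support=self.max_support,
        )
        other._patch_cache = self._patch_cache
        other._norm = self._norm
        return other

    def clear_cache(self) -> None:
        self._patch_cache.clear()
        self._kernel_cache.clear()
        self._norm = None


def compute_psf(
    config: OpticalConfig,
    depth_list,
    wavefront: AberrationWavefront | None = None,
    lateral_factors=None,
    simulator: PSFSimulator | None = None,
    validate: bool = False,
    **sim_kwargs,
) -> PhaseSpacePSF:
    """Simulate the phase-space PSF at the given depths (um).

    ``lateral_factors`` gives the per-depth slab sampling factor (powers of
    two; default all 1 = lens-grid sampling). Raises a configuration error
    when the automatically chosen kernel support cannot hold 99% of the
    z = 0 energy.
    """
    depth_list = np.atleast_1d(np.asarray(depth_list, dtype=float))
    if depth_list.size == 0 or not np.all(np.isfinite(depth_list)):
        raise ContractError("depth_list must be non-empty and finite")
    if lateral_factors is None:
        lateral_factors = [1] * len(depth_list)
    sim = simulator or PSFSimulator(config, wavefront, **sim_kwargs)
    kernels = [sim.kernel(z, q) for z, q in zip(depth_list, lateral_factors)]
    psf = PhaseSpacePSF(
        config=config,
        depth_list=depth_list,
        kernels=kernels,
        lateral_factors=list(lateral_factors),
        angular_bins=sim.angular_bins,
    )
    # z = 0 support sanity: the chosen window must hold >= 99% of the energy
    # an enlarged window would detect.
    i0 = int(np.argmin(np.abs(depth_list)))
    if abs(depth_list[i0]) < 1e-9:
        chosen = sim.support_lenses(0.0)
        e0 = float(sim.sensor_patch(0.0, support=chosen).sum())
        e_ref = float(sim.sensor_patch(0.0, support=chosen + 6).sum())
        if e0 < 0.99 * e_ref:
            raise ConfigurationError(
                f"kernel support ({chosen} lenses) holds only {e0 / e_ref:.3f} of the "
                f"z=0 energy; increase support_margin/extra_lenses (need >= 99%)"
            )
    if validate:
        psf.validate_energy()
    return psf
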