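"""Instrument geometry and reconstruction options.

All lengths are in micrometres. The light-field geometry is fixed by the
microlens array (MLA) pitch and focal length, the relay magnification between
the MLA back focal plane and the camera, and the camera pixel pitch: each
microlens then covers ``pixels_per_lens`` sensor pixels per axis, and every
pixel behind a lens samples one angular component of the light field.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

from .errors import ConfigurationError

__all__ = [
    "OpticalConfig",
    "ReconstructionOptions",
    "preset_40x_na1",
    "preset_20x_na05",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of a light-field microscope.

    Parameters
    ----------
    emission_wavelength:
        Fluorescence emission wavelength (um).
    objective_na:
        Numerical aperture of the objective.
    objective_magnification:
        Nominal magnification of the objective.
    immersion_index:
        Refractive index of the immersion/sample medium.
    mla_pitch, mla_focal_length:
        Microlens array pitch and focal length (um).
    relay_magnification:
        Magnification of the relay between MLA back focal plane and camera.
    camera_pixel_pitch:
        Physical camera pixel size (um).
    num_lenses:
        Number of microlenses modelled per axis, (rows, cols).
    effective_magnification:
        Measured system magnification from sample plane to MLA plane. Real
        systems often deviate from the objective's nominal value (tube-lens
        mismatch); when ``None`` the nominal magnification is used.
    pixels_per_lens:
        Sensor pixels per lens per axis. Derived from the geometry when
        ``None``; must come out odd so a central (chief-ray) angular
        component exists.
    """

    emission_wavelength: float
    objective_na: float
    objective_magnification: float
    immersion_index: float
    mla_pitch: float
    mla_focal_length: float
    relay_magnification: float
    camera_pixel_pitch: float
    num_lenses: tuple[int, int] = (15, 15)
    effective_magnification: float | None = None
    pixels_per_lens: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "emission_wavelength",
            "objective_na",
            "objective_magnification",
            "immersion_index",
            "mla_pitch",
            "mla_focal_length",
            "relay_magnification",
            "camera_pixel_pitch",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ConfigurationError(f"{name} must be a positive finite number, got {value!r}")
        if self.objective_na >= self.immersion_index:
            raise ConfigurationError(
                f"objective_na ({self.objective_na}) must be below the immersion index "
                f"({self.immersion_index})"
            )
        nl = tuple(int(n) for n in self.num_lenses)
        if len(nl) != 2 or any(n < 1 for n in nl):
            raise ConfigurationError(f"num_lenses must be a pair of positive integers, got {self.num_lenses!r}")
        object.__setattr__(self, "num_lenses", nl)
        derived = round(self.mla_pitch * self.relay_magnification / self.camera_pixel_pitch)
        if self.pixels_per_lens is None:
            object.__setattr__(self, "pixels_per_lens", int(derived))
        elif int(self.pixels_per_lens) != derived:
            raise ConfigurationError(
                f"pixels_per_lens={self.pixels_per_lens} inconsistent with geometry "
                f"(pitch*relay/pixel rounds to {derived})"
            )
        if self.pixels_per_lens % 2 == 0:
            raise ConfigurationError(
                f"pixels_per_lens must be odd so a central angular component exists "
                f"(got {self.pixels_per_lens}); adjust the relay magnification or pixel pitch"
            )
        if self.effective_magnification is None:
            object.__setattr__(self, "effective_magnification", float(self.objective_magnification))
        # NA matching between objective image side and the microlens acceptance
        # angle; mismatch wastes pixels or crosstalks lenses but is not fatal.
        image_na = self.objective_na / self.objective_magnification
        lens_na = self.mla_pitch / (2.0 * self.mla_focal_length)
        if abs(image_na - lens_na) > 0.2 * lens_na:
            warnings.warn(
                f"NA mismatch: objective image-side NA {image_na:.4f} vs microlens "
                f"acceptance {lens_na:.4f} (>20%)",
                stacklevel=2,
            )

    # -- derived geometry ---------------------------------------------------
    @property
    def lens_pitch_sample(self) -> float:
        """Sample-plane area covered by one microlens, per axis (um)."""
        return self.mla_pitch / self.effective_magnification

    @property
    def image_side_na(self) -> float:
        """Numerical aperture on the MLA side (sine of the marginal ray angle)."""
        return self.objective_na / self.effective_magnification

    @property
    def angular_half(self) -> int:
        """Half-width of the angular index range: u, v in [-h, h]."""
        return self.pixels_per_lens // 2

    @property
    def sensor_pixel_mla(self) -> float:
        """Sensor pixel pitch referred to the MLA plane (um).

        Uses pitch/pixels_per_lens so lens and pixel grids are exactly
        commensurate, absorbing the sub-percent rounding of the physical
        relay into the model.
        """
        return self.mla_pitch / self.pixels_per_lens

    def to_dict(self) -> dict:
        d = asdict(self)
        d["num_lenses"] = list(self.num_lenses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            warnings.warn(f"ignoring unknown optical config keys: {sorted(unknown)}", stacklevel=2)
        kwargs = {k: v for k, v in d.items() if k in known}
        missing = {"emission_wavelength", "objective_na", "objective_magnification",
                   "immersion_index", "mla_pitch", "mla_focal_length",
                   "relay_magnification", "camera_pixel_pitch"} - set(kwargs)
        if missing:
            raise ConfigurationError(f"missing mandatory optical config field(s): {sorted(missing)}")
        if "num_lenses" in kwargs:
            kwargs["num_lenses"] = tuple(kwargs["num_lenses"])
        return cls(**kwargs)


def preset_40x_na1(num_lenses: tuple[int, int] = (15, 15)) -> OpticalConfig:
    """x40/1.0 NA water-immersion preset.

    100 um MLA pitch, 2.1 mm MLA focal length, 0.845 relay, 6.5 um camera
    pixels: 13x13 sensor pixels per microlens. The measured effective
    magnification (46.5x) makes one lens cover 2.15 um at the sample plane.
    """
    return OpticalConfig(
        emission_wavelength=0.525,
        objective_na=1.0,
        objective_magnification=40.0,
        immersion_index=1.33,
        mla_pitch=100.0,
        mla_focal_length=2100.0,
        relay_magnification=0.845,
        camera_pixel_pitch=6.5,
        num_lenses=num_lenses,
        effective_magnification=100.0 / 2.15,
    )


def preset_20x_na05(num_lenses: tuple[int, int] = (15, 15)) -> OpticalConfig:
    """x20/0.5 NA preset with the same MLA/relay/camera as the x40 preset.

    The image-side NA (0.025) matches the microlens acceptance (0.0238)
    within 5%, so the light fills the 13x13 angular aperture. One lens
    covers 5 um at the sample plane; the smaller NA keeps out-of-focus blur
    footprints desk-sized, which makes this the default geometry for
    synthetic experiments.
    """
    return OpticalConfig(
        emission_wavelength=0.525,
        objective_na=0.5,
        objective_magnification=20.0,
        immersion_index=1.33,
        mla_pitch=100.0,
        mla_focal_length=2100.0,
        relay_magnification=0.845,
        camera_pixel_pitch=6.5,
        num_lenses=num_lenses,
    )


@dataclass
class ReconstructionOptions:
    """Tunable parameters of the iterative reconstructions.

    ``outer_iterations`` alternations of emission (Richardson-Lucy) and
    scattering-potential updates, with ``inner_rl_iterations`` RL cycles per
    alternation. ``admm_penalty`` is the consensus penalty rho of the
    splitting; ``lambda_f`` the Tikhonov weight on the scattering potential
    (relative to the data scale); ``epsilon_scale`` the division guard as a
    fraction of the view maximum.
    """

    outer_iterations: int = 3
    inner_rl_iterations: int = 10
    admm_penalty: float = 1.0
    lambda_f: float = 1e-3
    epsilon_scale: float = 1e-8
    seed: int = 0
    convergence_tol: float = 1e-4
    angular_order: str = "spiral"  # "spiral" (centre-out cycling) or "joint"
    potential_steps: int = 3

    def __post_init__(self) -> None:
        if self.outer_iterations < 1 or self.inner_rl_iterations < 1:
            raise ConfigurationError("iteration counts must be >= 1")
        if self.admm_penalty <= 0 or self.epsilon_scale <= 0 or self.convergence_tol <= 0:
            raise ConfigurationError("admm_penalty, epsilon_scale and convergence_tol must be > 0")
        if self.lambda_f < 0:
            raise ConfigurationError("lambda_f must be >= 0")
        if self.angular_order not in ("spiral", "joint"):
            raise ConfigurationError("angular_order must be 'spiral' or 'joint'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ReconstructionOptions":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            warnings.warn(f"ignoring unknown reconstruction option keys: {sorted(unknown)}", stacklevel=2)
        return cls(**{k: v for k, v in d.items() if k in known})
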