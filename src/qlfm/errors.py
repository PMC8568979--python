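"""Exception types used across the package."""


class QlfmError(Exception):
    """Base class for package errors."""


class ConfigurationError(QlfmError, ValueError):
    """An optical or reconstruction configuration violates an invariant."""


class ContractError(QlfmError, ValueError):
    """Inputs to an operation are mutually inconsistent (shape/grid mismatch)."""


class GeometryError(QlfmError, ValueError):
    """Requested lens geometry does not fit on the sensor."""


class CalibrationError(QlfmError, RuntimeError):
    """PSF calibration cannot proceed (e.g. no valid sub-apertures)."""
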