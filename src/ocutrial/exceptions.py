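"""Exception hierarchy for ocutrial."""


class OcutrialError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(OcutrialError):
    """A measured input is non-finite or outside its physical domain."""


class InconsistentBiometryError(OcutrialError):
    """Axial segments do not add up to a physically possible eye."""


class OpticsDomainError(OcutrialError):
    """Paraxial vergence propagation left its valid domain (e.g. d2 <= 0)."""


class ConfigError(OcutrialError):
    """A simulation or pipeline configuration is invalid."""


class SchemaError(OcutrialError):
    """An input table violates the expected column schema."""


class CollinearityError(OcutrialError):
    """Mediators are too collinear for a stable decomposition."""


class RankError(OcutrialError):
    """Fewer participants than fixed-effect parameters."""


class ConvergenceWarning(UserWarning):
    """Optimizer did not meet the convergence tolerances."""
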