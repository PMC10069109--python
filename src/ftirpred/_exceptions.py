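"""Package-wide exception types."""


class FTIRPredError(Exception):
    """Base class for all ftirpred errors."""


class ConfigError(FTIRPredError, ValueError):
    """Invalid configuration or parameter value."""


class DomainError(FTIRPredError, ValueError):
    """Input values outside the mathematical domain of an operation."""


class DegenerateChannelError(FTIRPredError, ValueError):
    """One or more spectral channels have zero variance."""

    def __init__(self, wavenumbers):
        self.wavenumbers = list(wavenumbers)
        super().__init__(
            f"zero-variance spectral channels at wavenumbers {self.wavenumbers}"
        )


class MappingError(FTIRPredError, ValueError):
    """Replicate tags or sample ids do not map consistently."""


class PedigreeError(FTIRPredError, ValueError):
    """Invalid pedigree (cycle, missing parent, bad ordering)."""


class DataError(FTIRPredError, ValueError):
    """Degenerate or insufficient data for a model fit."""


class NumericalError(FTIRPredError, RuntimeError):
    """Numerical failure (singular system, non-positive-definite matrix)."""
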