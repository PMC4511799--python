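"""Exception types raised across the pipeline."""


class SSCPUEError(Exception):
    """Base class for all package errors."""


class ConfigError(SSCPUEError):
    """Invalid strata or simulation configuration."""


class MalformedGenotypeError(SSCPUEError):
    """A genotype record violates the two-alleles-or-missing rule."""


class DuplicateIdError(SSCPUEError):
    """A fish_id occurs more than once in one table."""


class CoordinateRangeError(SSCPUEError):
    """Latitude/longitude outside valid decimal-degree ranges."""


class TimestampError(SSCPUEError):
    """Unparseable timestamp in a track or encounter log."""


class GSIError(SSCPUEError):
    """Degenerate input to the mixture model (e.g. a fish with zero
    likelihood under every baseline population)."""


class SeparationError(SSCPUEError):
    """Quasi-complete separation: a factor cell whose responses are all
    zero makes the count-GLM maximum-likelihood estimate diverge."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(
            "all-zero response in factor cell(s): "
            + ", ".join(map(str, self.cells))
        )
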