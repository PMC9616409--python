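"""Exception types raised across the package."""


class FermoptError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedRunCountError(FermoptError, ValueError):
    """Requested Plackett-Burman size has no known cyclic generator."""


class DesignCapacityError(FermoptError, ValueError):
    """More factors requested than the design can estimate."""


class SingularDesignError(FermoptError, ValueError):
    """Model matrix is rank deficient; carries the offending term names."""

    def __init__(self, message: str, collinear_terms=()):
        super().__init__(message)
        self.collinear_terms = tuple(collinear_terms)


class InsufficientRunsError(FermoptError, ValueError):
    """Fewer runs than model parameters."""


class NotEstimableError(FermoptError, ValueError):
    """A dose-response summary (e.g. IC50) cannot be estimated from the data."""


class NoNonToxicDoseError(FermoptError, ValueError):
    """No tested concentration keeps viability above the tolerance threshold."""


class SchemaError(FermoptError, ValueError):
    """An input table does not match the documented CSV schema."""
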