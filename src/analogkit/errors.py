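"""Exception hierarchy shared by all stages of the toolkit."""


class AnalogkitError(Exception):
    """Base class for all toolkit errors."""


class ChemistryError(AnalogkitError):
    """A molecule could not be sanitized / is chemically invalid."""


class AttachmentError(AnalogkitError):
    """A fragment cannot be attached at the requested site."""


class EmptyLibraryError(AnalogkitError):
    """Enumeration produced no products; carries per-site failure counts."""

    def __init__(self, message, failure_counts=None):
        super().__init__(message)
        self.failure_counts = dict(failure_counts or {})


class ConfigError(AnalogkitError):
    """Invalid configuration value, window, pattern or weight."""


class NoTemplateOverlapError(AnalogkitError):
    """Common substructure with the template is below the minimum size."""


class EmbeddingError(AnalogkitError):
    """3D embedding failed after the configured number of retries."""


class DegenerateAlignmentError(AnalogkitError):
    """Fewer than three mapped atoms: superposition is underdetermined."""


class NoTransitionError(AnalogkitError):
    """Melt curve shows no sigmoidal transition."""


class NonLinearTraceError(AnalogkitError):
    """No contiguous window of the kinetic trace is linear enough."""


class FitError(AnalogkitError):
    """Nonlinear regression failed to converge or data are unfittable."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class NoBindingSignalError(AnalogkitError):
    """ITC isotherm carries no measurable heat signal."""


class CensoredValueError(AnalogkitError):
    """Arithmetic requested on a censored (<floor / >ceiling) value."""


class LedgerIntegrityError(AnalogkitError):
    """SAR ledger violates structural invariants (cycles, bad parents)."""


class EmptyInputError(AnalogkitError):
    """Input file contained no valid records."""


class EmptySelectionError(AnalogkitError):
    """Pocket selection matched no atoms."""
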