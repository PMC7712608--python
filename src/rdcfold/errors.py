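"""Exception hierarchy for rdcfold."""


class RdcfoldError(Exception):
    """Base class for all rdcfold errors."""


class ValidationError(RdcfoldError):
    """An argument violates a documented precondition."""


class FormatError(RdcfoldError):
    """A file (or inline string) does not conform to its format."""


class DataError(RdcfoldError):
    """Input data are structurally valid but unusable (missing atoms,
    degenerate geometry, records referencing absent residues, ...)."""


class ConfigError(RdcfoldError):
    """A run configuration is missing or has an invalid mandatory field."""
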