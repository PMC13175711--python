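"""Exception hierarchy. Data errors exit the CLI with code 1."""


class ReefsyncError(Exception):
    """Base class for all package errors."""


class DataValidationError(ReefsyncError):
    """Malformed or out-of-contract input data."""


class DegenerateCommunityError(ReefsyncError):
    """Every taxon is temporally constant; the synchrony index is undefined."""
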