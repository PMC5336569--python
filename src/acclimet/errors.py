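"""Exception hierarchy."""


class AcclimetError(Exception):
    """Base class for package errors."""


class ValidationError(AcclimetError):
    """Invalid configuration, design, or input contract violation."""


class ProcessingOrderError(AcclimetError):
    """A preprocessing step was run out of order or repeated."""


class ReferencingError(AcclimetError):
    """No usable chemical-shift reference peak found."""
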