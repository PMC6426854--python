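"""Exception hierarchy for chaintrace."""


class ChainTraceError(Exception):
    """Base class for all chaintrace errors."""


class FormatError(ChainTraceError):
    """A file or table violates the expected format."""


class ConfigError(ChainTraceError):
    """Inconsistent or incomplete configuration."""


class NoSpecificPrimerError(ChainTraceError):
    """No primer pair satisfying the constraints is specific to the marker.

    Raised by primer design when every candidate pair collides with the
    background set; it signals that the marker contig is not
    strain-discriminative.
    """


class NoANISupportError(ChainTraceError):
    """No genome fragment survived the ANI retention filters."""
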