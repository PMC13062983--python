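"""Exception types shared across the package."""


class WormtraceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WormtraceError):
    """A file did not conform to the expected dialect (CD, TIME, StarryNite zip,
    transform or depth-model serialization)."""
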