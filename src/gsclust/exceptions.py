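"""Exception hierarchy used across the package."""


class GsclustError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GsclustError, ValueError):
    """Malformed input file or table (missing columns, bad lines)."""


class ParameterError(GsclustError, ValueError):
    """Invalid parameter combination supplied by the caller."""


class ResourceError(GsclustError, ValueError):
    """A required resource (PPI network, ontology) was not provided."""


class ConnectivityError(GsclustError, OSError):
    """Network access required but unavailable (and no warm cache)."""
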