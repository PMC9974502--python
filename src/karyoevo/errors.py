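"""Exception hierarchy shared across the package."""


class KaryoevoError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KaryoevoError):
    """Invalid simulation or pipeline configuration."""


class TableFormatError(KaryoevoError):
    """Malformed exchange table (orthogroups, positions, pairs, datasets)."""


class ReconstructionError(KaryoevoError):
    """Inconsistent fusion calls or impossible ancestral chromosome counts."""
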