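"""Exception hierarchy for the pipeline."""


class PdtMriError(Exception):
    """Base class for all package errors."""


class ProtocolError(PdtMriError):
    """Acquisition protocol is inconsistent with the supplied data."""


class ConfigError(PdtMriError):
    """Configuration file is malformed or violates an invariant."""


class GeometryError(PdtMriError):
    """Voxel-grid geometries do not match or do not overlap."""


class FormatError(PdtMriError):
    """An on-disk file does not match its declared structure."""
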