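"""Exception hierarchy shared across the pipeline."""


class GeometryError(ValueError):
    """Raised when two volumes do not share the same voxel grid."""


class DataError(ValueError):
    """Raised for unreadable or non-finite image data."""
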