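"""Exception hierarchy for shapedent."""


class ShapedentError(Exception):
    """Base class for all shapedent errors."""


class MeshFormatError(ShapedentError):
    """A mesh or annotation file violates its declared format."""


class GeometryError(ShapedentError):
    """A geometric precondition is violated (degenerate or mismatched input)."""


class CorrespondenceError(ShapedentError):
    """Meshes expected to share a reference topology do not."""
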