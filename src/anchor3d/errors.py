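"""Exception hierarchy for anchor3d.

All errors derive from :class:`Anchor3DError` so callers can catch the
package's failures with a single except clause; the CLI maps them to
exit code 1 (user/input errors) vs 2 (internal errors).
"""


class Anchor3DError(Exception):
    """Base class for all anchor3d errors."""


class ParameterError(Anchor3DError, ValueError):
    """An input parameter violates its documented constraints."""


class DegeneracyError(Anchor3DError, ValueError):
    """An operation produced or detected degenerate geometry."""


class AnnotationError(Anchor3DError, ValueError):
    """Site annotations are malformed (overlap, bad interval, bad label)."""


class GeometryError(Anchor3DError, ValueError):
    """A geometric construction failed (bad intersection, empty polygon...)."""


class BuildError(Anchor3DError, ValueError):
    """Mesh construction preconditions not met."""


class TopologyError(Anchor3DError, ValueError):
    """Mesh connectivity is invalid (non-manifold weld, open surface...)."""


class LookupError_(Anchor3DError, KeyError):
    """Unknown label or vertex id."""


class TableError(Anchor3DError, ValueError):
    """A coordinate table does not match the model it is applied to."""


class ParseError(Anchor3DError, ValueError):
    """A file could not be parsed; message names the offending line."""
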