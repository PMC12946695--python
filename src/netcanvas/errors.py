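"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`NetcanvasError` so callers can catch the library wholesale, while the
leaf classes also subclass the closest builtin (``ValueError``/``KeyError``/
``TypeError``) to stay idiomatic.
"""


class NetcanvasError(Exception):
    """Base class for all netcanvas errors."""


class StructuralError(NetcanvasError, ValueError):
    """Graph or tree structure is invalid (unknown endpoint, cycle, many roots)."""


class AttributeLengthError(NetcanvasError, ValueError):
    """A per-element attribute sequence does not match the element count."""


class LayoutCoverageError(NetcanvasError, ValueError):
    """A layout is missing coordinates for one or more vertices."""


class LayoutDimensionError(NetcanvasError, ValueError):
    """Layout coordinates mix tuple lengths or use an unsupported dimension."""


class LayoutValueError(NetcanvasError, ValueError):
    """Layout contains non-finite coordinate values."""


class ProviderRegistrationError(NetcanvasError, ValueError):
    """A provider name is already registered."""


class UnsupportedInputError(NetcanvasError, TypeError):
    """No registered provider matches the input object."""


class ConversionError(NetcanvasError, RuntimeError):
    """A provider's converter failed; the cause is chained."""


class StyleLookupError(NetcanvasError, KeyError):
    """Unknown built-in style name."""


class StyleGrammarError(NetcanvasError, ValueError):
    """Unknown element-type key in a style fragment."""


class DegenerateRangeError(NetcanvasError, ValueError):
    """Quantitative colour mapping over constant values with no explicit norm."""


class GeometryError(NetcanvasError, ValueError):
    """Base for edge-geometry failures."""


class DegenerateEdgeError(GeometryError):
    """Coincident endpoints passed to a non-loop geometry."""


class ArityError(GeometryError):
    """Wrong number of control points or waypoints."""


class GeometryRangeError(GeometryError):
    """A geometry parameter is outside its permitted range."""


class FullyClippedError(GeometryError):
    """Marker clipping or arrowhead shortening consumed the whole path."""


class MissingLayoutError(NetcanvasError, ValueError):
    """No layout was supplied and the provider exposes none."""


class ExportFormatError(NetcanvasError, ValueError):
    """Requested export format is not supported."""


class NodeLookupError(NetcanvasError, KeyError):
    """Unknown tree node or vertex id."""


class NewickParseError(NetcanvasError, ValueError):
    """Malformed Newick text; message carries the character position."""
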