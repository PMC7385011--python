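"""Exception hierarchy.

Every error raised by clefscope derives from :class:`ClefscopeError` so
pipeline code can catch one type and re-raise with a stage prefix.
"""


class ClefscopeError(Exception):
    """Base class for all clefscope errors."""


class FormatError(ClefscopeError):
    """A file does not conform to the expected format (e.g. a PDB with no CA atoms)."""


class IntegrityError(ClefscopeError):
    """Parsed data violates an internal invariant (e.g. duplicate residue identifiers)."""


class SerializationError(ClefscopeError):
    """A value cannot be represented in the target format (e.g. PDB field overflow)."""


class MappingError(ClefscopeError):
    """An alignment sequence does not match its structure."""


class PreconditionError(ClefscopeError, ValueError):
    """An operation was called with arguments violating its contract."""


class GeometryError(ClefscopeError):
    """Degenerate geometry: rank-deficient point sets, coincident sphere centers."""


class DisconnectedStructureError(ClefscopeError):
    """The elastic network splits into independent components (> 6 zero modes)."""


class UndefinedCorrelationError(ClefscopeError):
    """A residue has zero displacement variance, so its correlation is undefined."""


class AnnotationError(ClefscopeError):
    """A residue required by an operation carries no domain annotation."""


class ResidueParseError(ClefscopeError):
    """A residue-list token (e.g. ``W554``) could not be parsed."""


class GenerationError(ClefscopeError):
    """Synthetic-structure generation failed (e.g. packing did not converge)."""
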