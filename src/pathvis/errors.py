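"""Exception types shared across the package."""


class PathvisError(Exception):
    """Base class for all package-specific errors."""


class RegistryError(PathvisError):
    """An entity or interaction class is not present in the active registry."""


class MembershipError(PathvisError):
    """A group references an entity id that does not exist in the graph."""


class FormatError(PathvisError):
    """An input file violates its dialect's structural rules."""


class RecordError(PathvisError):
    """A single input record is malformed (index or line reported)."""


class RenderError(PathvisError):
    """The renderer received inconsistent graph/layout inputs."""


class ConfigurationError(PathvisError):
    """Geometry or parameter configuration is unsatisfiable."""
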