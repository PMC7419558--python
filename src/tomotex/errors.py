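"""Exception hierarchy shared across the pipeline stages."""


class TomotexError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(TomotexError, ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class GeometryError(TomotexError, ValueError):
    """A grid or acquisition geometry cannot support the requested operation."""


class PlacementError(TomotexError, RuntimeError):
    """No feasible lesion placement exists for the requested constraints."""


class DegenerateInputError(TomotexError, ValueError):
    """Input is structurally valid but degenerate (empty mask, no trials, ...)."""


class SchemaError(TomotexError, ValueError):
    """Tabulated inputs (spectra, material tables, manifests) are inconsistent."""


class InventoryError(TomotexError, ValueError):
    """The image inventory cannot satisfy a session or stage request."""


class DependencyError(TomotexError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
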