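"""Exception hierarchy for the pathmap toolkit."""


class PathmapError(Exception):
    """Base class for all pathmap errors."""


class ParseError(PathmapError):
    """Input could not be parsed as XML / the expected text format."""


class UnsupportedDialect(PathmapError):
    """XML parsed, but it is not a dialect this toolkit reads."""


class ModelInvalid(PathmapError):
    """A writer was handed a model that fails validation.

    Carries the violation list so callers can report precisely.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "model fails validation: "
            + "; ".join(str(v) for v in self.violations)
        )


class TargetNotFound(PathmapError, KeyError):
    """Referenced element/interaction id does not exist in the model."""


class BundleLinkError(PathmapError):
    """A bundle configuration diagram references a map file that is absent."""

    def __init__(self, missing_name):
        self.missing_name = missing_name
        super().__init__(f"config diagram references missing map {missing_name!r}")


class UnknownNamespace(PathmapError, KeyError):
    """Annotation namespace is not present in the MIRIAM registry."""


class InvalidIdentifier(PathmapError, ValueError):
    """Identifier does not match the registry's validation pattern."""


class FormatError(PathmapError):
    """Tabular input (overlay/table) has an unusable structure, e.g. an
    unknown header column."""


class EmptyDataset(PathmapError):
    """Overlay file contained no valid data rows."""


class ValueOutOfRange(PathmapError, ValueError):
    """Overlay value outside the documented [-1, 1] convention."""


class EmptyRegion(PathmapError):
    """Region selection/render request covers nothing."""


class TileOutOfRange(PathmapError, ValueError):
    """Tile coordinates outside [0, 2^z) at the requested zoom."""
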