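"""Exception hierarchy shared across the package."""


class WetlandBNError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(WetlandBNError):
    """The structure of an input (columns, file layout, config) is wrong."""


class ValidationError(WetlandBNError):
    """Input values violate a declared constraint (range, uniqueness)."""


class ConstantColumnError(WetlandBNError):
    """A rank correlation is undefined because a variable is constant."""

    def __init__(self, name: str | None = None):
        self.name = name
        msg = "correlation undefined: constant vector"
        if name is not None:
            msg += f" (variable {name!r})"
        super().__init__(msg)


class NotPositiveDefiniteError(WetlandBNError):
    """A correlation matrix is not positive definite where one is required."""


class StructureError(WetlandBNError):
    """A network structure is invalid (cycle, unknown node, bad target)."""
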