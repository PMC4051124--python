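"""Exception hierarchy shared across the package."""


class DataError(ValueError):
    """Malformed or inconsistent input data (maps to CLI exit code 2)."""


class UnknownGeneError(DataError):
    """A gene symbol could not be resolved to a network node."""


class AmbiguousAliasError(DataError):
    """An alias maps to more than one canonical gene symbol."""
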