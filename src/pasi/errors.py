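"""Exception types shared across the package."""


class InputError(ValueError):
    """An input table, parameter or label vector violates a documented contract."""


class FormatError(ValueError):
    """A file could not be parsed in its declared format (e.g. malformed KGML)."""


class UnscorablePathwayError(ValueError):
    """A pathway has no measured gene/group nodes and cannot be scored."""
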