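"""Exception hierarchy shared across the pipeline."""


class IterQuantError(Exception):
    """Base class for all iterquant errors."""


class LayoutError(IterQuantError):
    """Plate-layout table is malformed or inconsistent with the plate shape."""


class FormatError(IterQuantError):
    """An input file violates its declared format."""


class ConfigurationError(IterQuantError):
    """Parameters are inconsistent (e.g. index collisions, empty windows)."""


class InputError(IterQuantError):
    """A value passed to an operation is outside its domain."""
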