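"""Exception hierarchy shared across the package."""


class XLTransitError(Exception):
    """Base class for all package errors."""


class ParseError(XLTransitError):
    """An input file (FASTA, PPI table, mapping, catalog, mod CSV) is malformed."""


class ConfigError(XLTransitError):
    """A search configuration names an unknown entity or violates a constraint."""
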