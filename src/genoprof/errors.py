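"""Exception hierarchy shared across the package."""


class GenoprofError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GenoprofError, ValueError):
    """An invalid value in a simulation or pipeline configuration; the
    message names the offending field."""


class ParseError(GenoprofError, ValueError):
    """A malformed input file; the message carries the file and line number."""


class EmptyHistogramError(GenoprofError, ValueError):
    """No valid k-mer window was found in the input reads (for example when
    k exceeds every read length)."""


class NoPeakError(GenoprofError, ValueError):
    """The k-mer spectrum has no genomic (homozygous) peak above the error
    cutoff, typically because sequencing coverage is too low."""
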