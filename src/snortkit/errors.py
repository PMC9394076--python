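"""Exception hierarchy shared by all snortkit modules."""


class SnortkitError(Exception):
    """Base class for all snortkit-specific errors."""


class AnnotationError(SnortkitError):
    """Malformed transcript annotation (overlapping exons, bad intervals...)."""


class MissingAnnotationError(SnortkitError):
    """A transcript id was requested that is absent from the annotation."""


class DegenerateSampleError(SnortkitError):
    """A count-matrix sample is unusable (e.g. all-zero counts)."""


class UndefinedMedianError(SnortkitError):
    """Median enrichment requested on an empty target set."""


class AlphabetError(SnortkitError):
    """A sequence contains characters outside the expected alphabet."""


class PatternError(SnortkitError):
    """An IUPAC consensus pattern contains an invalid code."""


class ConfigError(SnortkitError):
    """An infeasible or inconsistent configuration was supplied."""
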