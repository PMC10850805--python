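"""Exception hierarchy shared across the package.

Every error raised by vulnprior derives from :class:`VulnpriorError`, so
callers (and the CLI) can catch one base class.  Subclasses carry enough
context in their message to locate the offending file, cell, or group.
"""


class VulnpriorError(Exception):
    """Base class for all vulnprior errors."""


class FormatError(VulnpriorError):
    """Malformed label or record (e.g. a gene label with an empty symbol)."""


class SchemaError(VulnpriorError):
    """Structural problem in an input table (duplicate ids, missing columns)."""


class RangeError(SchemaError):
    """A value outside its documented range, with cell coordinates."""


class ConfigError(VulnpriorError):
    """Invalid configuration, rule, or parameter."""


class EmptySetError(VulnpriorError):
    """A gene set that is empty where the caller required membership."""


class AlignmentError(VulnpriorError):
    """Two inputs that must share a line/gene universe do not."""


class InsufficientDataError(VulnpriorError):
    """Too few observations to run the requested procedure."""


class DegenerateDataError(VulnpriorError):
    """Zero-variance or otherwise degenerate data for a statistic."""


class JoinError(VulnpriorError):
    """No overlap between datasets that must be joined on shared ids."""
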