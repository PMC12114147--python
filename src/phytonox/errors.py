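"""Exception hierarchy shared across the package."""


class PhytonoxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhytonoxError):
    """A file or table does not conform to the expected dialect."""


class ConfigurationError(PhytonoxError):
    """A policy, design or config object violates its invariants."""


class DegenerateDataError(PhytonoxError):
    """Input data cannot support the requested computation."""
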