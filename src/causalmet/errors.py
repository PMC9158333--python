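"""Exception types shared across the package."""


class CausalmetError(Exception):
    """Base class for package-specific errors."""


class FormatError(CausalmetError, ValueError):
    """A tabular input does not conform to the expected dialect."""


class EntityClassConflictError(CausalmetError, ValueError):
    """The same identifier is registered with two different entity classes."""


class DegenerateDistributionError(CausalmetError, ValueError):
    """A statistic cannot be computed because the distribution has no spread."""
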