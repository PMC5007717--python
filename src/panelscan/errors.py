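"""Exception hierarchy for panelscan."""


class PanelscanError(Exception):
    """Base class for all panelscan errors."""


class FormatError(PanelscanError):
    """A file does not conform to the expected text format."""


class DataError(PanelscanError):
    """A file parses but contains invalid data values."""


class ContractError(PanelscanError):
    """Arguments violate a function's contract (shapes, alignment, ranges)."""


class DomainError(PanelscanError):
    """A computation is undefined for the given inputs."""


class ConfigError(PanelscanError):
    """A simulation or run configuration is infeasible."""
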