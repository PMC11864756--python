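"""Exception hierarchy shared across the pipeline.

``FormatError`` — the bytes on disk do not parse into the expected table shape.
``DomainError`` — the parsed values violate a scientific precondition.
``ContractError`` — two pipeline objects disagree (e.g. gene sets differ
between a model and the data handed to it).
``LeakageError`` — a held-out-timepoint sample reached a training path.
``ConfigError`` — an impossible configuration value.
"""


class TfInfluenceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TfInfluenceError, ValueError):
    pass


class DomainError(TfInfluenceError, ValueError):
    pass


class ContractError(TfInfluenceError, RuntimeError):
    pass


class LeakageError(ContractError):
    """A sample from the blind-test timepoint entered training."""


class ConfigError(TfInfluenceError, ValueError):
    pass
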