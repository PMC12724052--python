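"""Exception hierarchy shared by all pipeline stages."""


class AdipoProteoError(Exception):
    """Base class for all package errors."""


class FormatError(AdipoProteoError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(AdipoProteoError, ValueError):
    """Parsed content violates a domain invariant."""


class EstimationError(AdipoProteoError):
    """Not enough data to estimate model parameters."""


class QCError(AdipoProteoError):
    """A sample fails a quality-control precondition."""


class ConfigurationError(AdipoProteoError):
    """Inputs are mutually inconsistent or a configured resource is unusable."""


class ContractError(AdipoProteoError):
    """An operation was called on objects that do not belong together."""


class PipelineError(AdipoProteoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
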