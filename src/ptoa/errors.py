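"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value violates its documented constraints.

    The message names the offending field so callers can report it.
    """


class SupportError(ValueError):
    """A statistic was requested outside the support of its distribution."""


class InsufficientReplicationError(ValueError):
    """Too few complete animal pairs to run a paired test."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[stage={stage}] [code={code}] {message}")
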