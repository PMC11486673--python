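"""Exception hierarchy shared across the package."""


class DCEError(Exception):
    """Base class for all dceperf errors."""


class InputError(DCEError):
    """Invalid user-supplied data: shape/timing mismatches, empty masks, bad values."""


class ConfigError(DCEError):
    """Invalid or incomplete configuration."""


class EstimationError(DCEError):
    """A statistical or numerical estimate cannot be formed from the given data."""


class StageError(DCEError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
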