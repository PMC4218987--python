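"""Exception hierarchy shared across the package."""


class RepliprofError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RepliprofError, ValueError):
    """Invalid configuration or parameter value (CLI exit code 2)."""


class StageError(RepliprofError, RuntimeError):
    """A pipeline stage failed on otherwise valid configuration (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
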