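"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Invalid configuration (empty design, bad counts, infeasible targets)."""


class FitError(RuntimeError):
    """A model fit could not be carried out on the given inputs."""


class ScreeningError(ValueError):
    """Predictor screening received an inconsistent group map."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
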