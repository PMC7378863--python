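"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(ValueError):
    """An input table violates the expected on-disk format."""


class DivergenceError(RuntimeError):
    """A simulation produced non-finite abundances."""

    def __init__(self, step: int, taxon: int):
        self.step = step
        self.taxon = taxon
        super().__init__(
            f"non-finite abundance for taxon index {taxon} at step {step}; "
            "reduce interaction strengths, growth rates or the step count"
        )


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
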