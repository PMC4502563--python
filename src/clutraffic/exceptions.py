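"""Exception hierarchy for the clutraffic pipeline.

Per-cell measurement problems (empty Golgi mask, degenerate denominator,
constant channel) are *signals*, recorded as NaN in the output tables; only
conditions that invalidate a whole stage raise.
"""


class ClutrafficError(Exception):
    """Base class for all pipeline errors."""


class PlacementError(ClutrafficError):
    """Cell geometry could not be placed without overlap."""

    def __init__(self, cell_index: int, n_attempts: int):
        self.cell_index = cell_index
        super().__init__(
            f"could not place cell {cell_index} without overlap "
            f"after {n_attempts} attempts; enlarge the image or reduce n_cells"
        )


class ParameterError(ClutrafficError):
    """An argument is outside its documented domain."""


class CoverageError(ClutrafficError):
    """Too few background pixels outside the cell ROIs."""


class DegenerateThresholdError(ClutrafficError):
    """Automatic threshold undefined (constant channel inside the ROI)."""


class MissingControlError(ClutrafficError):
    """No nontransfected control records to estimate the matrix background."""


class DataError(ClutrafficError):
    """A record violates a data invariant (e.g. non-positive normalizer)."""


class IncompletePairError(ClutrafficError):
    """A (genotype, experiment) lacks one of the CM/CL compartments."""


class ReferenceError_(ClutrafficError):
    """The reference (wild-type) genotype is absent from a table."""


class StratificationError(ClutrafficError):
    """Experiment strata of two estimates do not match."""


class UndefinedORError(ClutrafficError):
    """Every stratum has a zero margin; the common odds ratio is undefined."""


class PipelineStageError(ClutrafficError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed ({context}): {cause}")
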