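"""Exception hierarchy."""


class ScariError(Exception):
    """Base class for all package errors."""


class Gff3ParseError(ScariError):
    pass


class FastaError(ScariError):
    pass


class NewickError(ScariError):
    pass


class NomenclatureTableError(ScariError):
    pass


class ConfigError(ScariError):
    pass


class SaturationError(ScariError):
    """p-distance at or beyond the correction's saturation bound."""


class ClusterError(ScariError):
    """Cluster not localizable from the supplied anchors."""


class OrthologConflictError(ScariError):
    """Two query genes claim the same reference gene's number."""


class PipelineStageError(ScariError):
    """Wraps a module error with the pipeline stage it occurred in."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")
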