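"""Exception hierarchy for mycopop."""


class MycopopError(Exception):
    """Base class for all package errors."""


class AlignmentError(MycopopError):
    """Malformed alignment: ragged rows, illegal characters, duplicate ids."""


class AmbiguityCodeError(MycopopError):
    """Unsupported IUPAC ambiguity code (three/four-fold codes are rejected)."""


class PartitionError(MycopopError):
    """Strain/population/lineage assignment problems."""


class DiversityError(MycopopError):
    """Undefined diversity (e.g. sample size below two)."""


class PhasingError(MycopopError):
    """Problems building or phasing diploid genotype matrices."""


class ClonalityError(MycopopError):
    """Problems computing multilocus association statistics."""


class TreeError(MycopopError):
    """Tree construction or scoring problems."""


class ConfigError(MycopopError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(MycopopError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
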