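"""Exception hierarchy for the QSAR pipeline."""


class XaqsarError(Exception):
    """Base class for all package errors."""


class MoleculeParseError(XaqsarError):
    """A SMILES string could not be parsed."""


class ConfigurationError(XaqsarError):
    """Unknown atom class, descriptor mode, or bad config key."""


class CurationError(XaqsarError):
    """Dataset curation left no usable records."""


class PipelineError(XaqsarError):
    """A pipeline stage failed (e.g. all descriptors filtered out)."""


class SingularDesignError(XaqsarError):
    """Rank-deficient design matrix in an OLS fit."""


class SchemaError(XaqsarError):
    """Input table is missing required descriptor columns."""


class UndefinedStatisticError(XaqsarError):
    """A statistic is undefined for the given inputs (e.g. zero variance)."""


class GenerationError(XaqsarError):
    """Synthetic molecule generation could not satisfy the requested motifs."""
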