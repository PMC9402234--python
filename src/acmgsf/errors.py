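"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`AcmgsfError`
so callers can catch the package's failures with one clause; subclasses
name the input surface or contract that was violated.
"""


class AcmgsfError(Exception):
    """Base class for all package errors."""


class ConfigError(AcmgsfError):
    """Invalid configuration (panel, simulation, or pipeline)."""


class PanelValidationError(ConfigError):
    """Gene-panel config failed schema validation; message names the record."""


class UnknownGeneError(AcmgsfError, KeyError):
    """Lookup of a gene that is not in the panel."""


class InfeasibleConfigError(ConfigError):
    """A simulation config whose planted structure cannot exist.

    Raised instead of silently adjusting parameters, e.g. when the cohort is
    too small for any allele count to satisfy both the singleton floor and
    the rare-frequency ceiling.
    """


class CohortIOError(AcmgsfError):
    """Base for ingest/serialization failures."""


class SampleMismatchError(CohortIOError):
    """Sample table and VCF disagree on sample ids."""


class MalformedGenotypeError(CohortIOError):
    """A GT call that is not diploid or not parseable."""


class UnsortedVCFError(CohortIOError):
    """VCF records out of coordinate order within a contig."""


class AnnotationError(CohortIOError):
    """Missing or duplicate annotation row; message names the variant key."""


class VocabularyError(CohortIOError):
    """A categorical field outside its allowed vocabulary."""


class KinshipBoundsError(CohortIOError):
    """Kinship coefficient outside [0, 0.5] or a self-pair."""


class MissingFlagError(AcmgsfError):
    """A database-membership flag is unpopulated where the novelty filter
    requires a definite boolean (no three-valued logic)."""


class MissingScoreError(AcmgsfError):
    """CADD or GERP absent where the deleteriousness filter needs it."""


class ZeroCarrierError(AcmgsfError):
    """Association requested for a variant with no carriers."""
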