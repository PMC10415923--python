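"""Exception hierarchy.

Every user-facing failure raises a :class:`TwinmatchError` subclass so the
CLI can map library errors onto a nonzero exit code uniformly.
"""


class TwinmatchError(ValueError):
    """Base class for all twinmatch errors."""


class ProfileError(TwinmatchError):
    """Invalid molecular profile input (empty table, bad class, bad biomarker)."""


class MatchingError(TwinmatchError):
    """Invalid matching request (empty cohort, empty gene subset, bad cutoff)."""


class BalanceError(TwinmatchError):
    """Propensity/matching failure (no controls, all features dropped)."""


class ContextError(TwinmatchError):
    """Enrichment or spatial-grouping input failure."""


class ComparativeError(TwinmatchError):
    """Comparative-statistics input failure (empty samples, missing gene)."""


class SimulationError(TwinmatchError):
    """Invalid synthetic-cohort configuration."""


class ReportError(TwinmatchError):
    """Trial-table or report construction failure."""
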