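"""Connecting-score matching and digital-twin community construction.

The connecting score of a cohort sample against a case profile is the
fraction of the case's alterations that are also present in the sample:

    score = n_matched / n_case_alterations

Matching operates at one of three resolutions: ``gene`` (symbol only),
``gene_alteration`` (symbol + alteration class) or ``gene_protein``
(symbol + class + protein change; for non-mutation classes this degrades
to gene_alteration, since protein changes only exist for mutations).
Samples at or above a user-chosen score cutoff form the digital-twin
positive (DT+) community; the rest are DT-.
"""

from __future__ import annotations

import enum
import logging
import operator
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import MatchingError
from .profiles import AlterationClass, Biomarkers, GeneAlteration, MolecularProfile

logger = logging.getLogger(__name__)


class MatchLevel(str, enum.Enum):
    GENE = "gene"
    GENE_ALTERATION = "gene_alteration"
    GENE_PROTEIN = "gene_protein"


@dataclass(frozen=True)
class CohortSample:
    """One cohort member: alteration set (origin ignored) + clinical features.

    ``features`` holds gender, tmb, ms_status, cancer_type, survival_time
    (days), survival_event (0/1), a source tag (tumor | cell_line) and any
    additional numeric features.
    """

    sample_id: str
    alterations: frozenset[GeneAlteration]
    features: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ev = self.features.get("survival_event")
        if ev is not None and not pd.isna(ev) and int(ev) not in (0, 1):
            raise MatchingError(f"{self.sample_id}: survival_event must be 0/1, got {ev}")
        t = self.features.get("survival_time")
        if t is not None and not pd.isna(t) and float(t) < 0:
            raise MatchingError(f"{self.sample_id}: survival_time must be >= 0, got {t}")


@dataclass(frozen=True)
class ScoreRow:
    sample_id: str
    score: float
    n_matched: int
    n_case_alterations: int

    @property
    def distance(self) -> float:
        """Display-only complement of the score."""
        return 1.0 - self.score


@dataclass(frozen=True)
class CommunityAssignment:
    scores: tuple[ScoreRow, ...]
    cutoff: float
    dt_positive: frozenset[str]
    dt_negative: frozenset[str]


def alteration_match(
    case_alt: GeneAlteration, sample_alt: GeneAlteration, level: MatchLevel | str
) -> bool:
    """Whether a sample alteration satisfies a case alteration at ``level``."""
    level = MatchLevel(level)
    if case_alt.gene != sample_alt.gene:
        return False
    if level is MatchLevel.GENE:
        return True
    if case_alt.alteration_class is not sample_alt.alteration_class:
        return False
    if level is MatchLevel.GENE_ALTERATION:
        return True
    if case_alt.alteration_class is not AlterationClass.MUTATION:
        return True  # gene_protein degrades to gene_alteration for non-mutations
    return case_alt.protein_change == sample_alt.protein_change


def _restricted_case_alterations(
    profile: MolecularProfile, gene_subset: Iterable[str] | None
) -> list[GeneAlteration]:
    if gene_subset is None:
        alts = sorted(profile.alterations)
    else:
        alts = sorted(profile.restricted(gene_subset))
    if not alts:
        raise MatchingError("no case alterations in selected subset")
    return alts


def connecting_score(
    profile: MolecularProfile,
    sample: CohortSample,
    level: MatchLevel | str = MatchLevel.GENE_ALTERATION,
    gene_subset: Iterable[str] | None = None,
) -> ScoreRow:
    """Score one sample: matched case alterations / total case alterations.

    Each case alteration counts at most once, however many sample
    alterations satisfy it.
    """
    level = MatchLevel(level)
    case_alts = _restricted_case_alterations(profile, gene_subset)
    sample_by_gene: dict[str, list[GeneAlteration]] = {}
    for alt in sample.alterations:
        sample_by_gene.setdefault(alt.gene, []).append(alt)
    n_matched = 0
    for ca in case_alts:
        candidates = sample_by_gene.get(ca.gene, ())
        if any(alteration_match(ca, sa, level) for sa in candidates):
            n_matched += 1
    return ScoreRow(
        sample_id=sample.sample_id,
        score=n_matched / len(case_alts),
        n_matched=n_matched,
        n_case_alterations=len(case_alts),
    )


def score_cohort(
    profile: MolecularProfile,
    samples: Sequence[CohortSample],
    level: MatchLevel | str = MatchLevel.GENE_ALTERATION,
    gene_subset: Iterable[str] | None = None,
) -> list[ScoreRow]:
    """Score every sample; rows sorted by score descending, sample_id ascending."""
    if not samples:
        raise MatchingError("empty cohort")
    rows = [connecting_score(profile, s, level, gene_subset) for s in samples]
    rows.sort(key=lambda r: (-r.score, r.sample_id))
    return rows


def extended_connecting_score(
    profile: MolecularProfile,
    sample: CohortSample,
    level: MatchLevel | str = MatchLevel.GENE_ALTERATION,
    weight: float = 0.5,
    gene_subset: Iterable[str] | None = None,
) -> ScoreRow:
    """Genomic score blended with biomarker agreement.

    combined = weight * genomic + (1 - weight) * (agreeing biomarkers /
    biomarkers present in both case and sample).  TMB and PD-L1 agree
    within a factor of two; MS status agrees on equality.  With no shared
    biomarkers the genomic score is returned unchanged.
    """
    base = connecting_score(profile, sample, level, gene_subset)
    bm: Biomarkers = profile.biomarkers
    shared = 0
    agree = 0

    def _close(a: float, b: float) -> bool:
        a, b = float(a), float(b)
        if a == b:
            return True
        lo, hi = sorted([a, b])
        return lo > 0 and hi / lo <= 2.0

    for name, cmp in (("tmb", _close), ("pdl1", _close), ("ms_status", operator.eq)):
        case_v = getattr(bm, name)
        samp_v = sample.features.get(name)
        if case_v is None or samp_v is None or (not isinstance(samp_v, str) and pd.isna(samp_v)):
            continue
        shared += 1
        if cmp(case_v, samp_v):
            agree += 1
    if shared == 0:
        return base
    combined = weight * base.score + (1 - weight) * (agree / shared)
    return ScoreRow(base.sample_id, combined, base.n_matched, base.n_case_alterations)


# ---------------------------------------------------------------------------
# pre-match filtering

_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    "=": operator.eq,
    "==": operator.eq,
    ">=": operator.ge,
    ">": operator.gt,
    "in": lambda v, allowed: v in allowed,
}

_CRITERION_RE = re.compile(r"^\s*(\w+)\s*(<=|>=|==|<|>|=| in )\s*(.+?)\s*$")


@dataclass(frozen=True)
class Criterion:
    feature: str
    comparator: str
    value: object

    @classmethod
    def parse(cls, text: str) -> "Criterion":
        """Parse e.g. ``"tmb<10"``, ``"ms_status=MSS"``, ``"cancer_type in CRC;READ"``."""
        m = _CRITERION_RE.match(text)
        if not m:
            raise MatchingError(f"cannot parse filter criterion {text!r}")
        feature, comp, raw = m.group(1), m.group(2).strip(), m.group(3)
        if comp == "in":
            value: object = frozenset(v.strip() for v in raw.split(";"))
        else:
            try:
                value = float(raw)
            except ValueError:
                value = raw
        return cls(feature, comp, value)

    def check(self, sample: CohortSample) -> bool:
        v = sample.features.get(self.feature)
        if v is None or (not isinstance(v, str) and pd.isna(v)):
            return False  # missing values fail the criterion (conservative)
        if isinstance(self.value, float) and not isinstance(v, str):
            v = float(v)
        try:
            return bool(_COMPARATORS[self.comparator](v, self.value))
        except TypeError:
            return False


def prematch_filter(
    samples: Sequence[CohortSample],
    criteria: Sequence[Criterion | str | tuple],
) -> list[CohortSample]:
    """Keep samples satisfying *all* criteria (conjunction).

    Samples missing a filtered feature fail that criterion and are dropped
    (logged).  An unknown feature name — absent from every sample — is an
    error; an empty result is a warning, not an error.
    """
    parsed: list[Criterion] = []
    for c in criteria:
        if isinstance(c, Criterion):
            parsed.append(c)
        elif isinstance(c, str):
            parsed.append(Criterion.parse(c))
        else:
            feature, comp, value = c
            if comp == "in" and not isinstance(value, frozenset):
                value = frozenset(value)
            if comp not in _COMPARATORS:
                raise MatchingError(f"unknown comparator {comp!r}")
            parsed.append(Criterion(feature, comp, value))
    known = set()
    for s in samples:
        known.update(s.features)
    for c in parsed:
        if c.feature not in known:
            raise MatchingError(f"unknown feature {c.feature!r} in pre-match filter")
    kept = [s for s in samples if all(c.check(s) for c in parsed)]
    logger.info(
        "prematch_filter: retained %d, dropped %d of %d samples",
        len(kept), len(samples) - len(kept), len(samples),
    )
    if not kept:
        logger.warning("prematch_filter: no samples satisfy the criteria")
    return kept


def split_communities(
    scores: Sequence[ScoreRow], cutoff: float
) -> CommunityAssignment:
    """DT+ = {score >= cutoff}; DT- = the rest.

    A sample exactly at the cutoff is a twin (>= semantics).
    """
    if not scores:
        raise MatchingError("no scores to split")
    if not (0 <= cutoff <= 1):
        raise MatchingError(f"cutoff must be in [0, 1], got {cutoff}")
    pos = frozenset(r.sample_id for r in scores if r.score >= cutoff)
    neg = frozenset(r.sample_id for r in scores) - pos
    logger.info("split_communities: DT+ %d, DT- %d at cutoff %g", len(pos), len(neg), cutoff)
    if not pos:
        logger.warning("split_communities: DT+ community is empty at cutoff %g", cutoff)
    return CommunityAssignment(tuple(scores), cutoff, pos, neg)


def scores_frame(scores: Sequence[ScoreRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in scores],
            "score": [r.score for r in scores],
            "n_matched": [r.n_matched for r in scores],
            "n_case_alterations": [r.n_case_alterations for r in scores],
        }
    )
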