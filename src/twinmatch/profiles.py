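"""Case molecular profiles.

A molecular profiling report (MPR) lists a patient's somatic alterations in
two gene sets: the *key* (main, clinically curated) findings and the
*variants of unknown significance* (VUS).  Their union is the *total
profile*, the query object used for cohort matching.  This module parses
and validates profiles, combines case series into consensus profiles, and
orders medical-event timelines.

Uniqueness is enforced on the (gene, alteration class, protein change)
triple; when the same triple is reported under both origins, the key origin
wins (the key set is the clinically curated one).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ProfileError

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["gene", "alteration_class", "protein_change", "origin"]
TIMELINE_COLUMNS = ["date", "event_class", "label"]


class AlterationClass(str, enum.Enum):
    MUTATION = "mutation"
    AMPLIFICATION = "amplification"
    DELETION = "deletion"
    FUSION = "fusion"
    OTHER = "other"


class Origin(str, enum.Enum):
    KEY = "key"
    VUS = "vus"


class EventClass(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    TREATMENT = "treatment"
    TESTING = "testing"


@dataclass(frozen=True)
class GeneAlteration:
    """One reported alteration.

    ``protein_change`` is only meaningful for mutations; for any other
    alteration class it is coerced to ``None``.  Gene symbols are stored
    uppercased; no alias resolution is attempted.
    """

    gene: str
    alteration_class: AlterationClass
    protein_change: str | None = None
    origin: Origin = Origin.KEY

    def __post_init__(self) -> None:
        gene = str(self.gene).strip().upper()
        if not gene:
            raise ProfileError("gene symbol must be non-empty")
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "alteration_class", AlterationClass(self.alteration_class))
        object.__setattr__(self, "origin", Origin(self.origin))
        pc = self.protein_change
        if pc is not None:
            pc = str(pc).strip() or None
        if self.alteration_class is not AlterationClass.MUTATION:
            pc = None
        object.__setattr__(self, "protein_change", pc)

    @property
    def triple(self) -> tuple[str, str, str | None]:
        """Identity key, ignoring origin."""
        return (self.gene, self.alteration_class.value, self.protein_change)

    def __lt__(self, other: "GeneAlteration") -> bool:
        # None protein changes sort before any string
        key = (self.gene, self.alteration_class.value,
               self.protein_change or "", self.origin.value)
        other_key = (other.gene, other.alteration_class.value,
                     other.protein_change or "", other.origin.value)
        return key < other_key


@dataclass(frozen=True)
class Biomarkers:
    """Optional report-level biomarkers: TMB (mutations/Mb), MS status, PD-L1."""

    tmb: float | None = None
    ms_status: str | None = None  # MSS | MSI-H | MSI-L | unknown
    pdl1: float | None = None

    _MS_VALUES = ("MSS", "MSI-H", "MSI-L", "unknown")

    def __post_init__(self) -> None:
        if self.tmb is not None:
            try:
                tmb = float(self.tmb)
            except (TypeError, ValueError) as exc:
                raise ProfileError(f"malformed TMB value {self.tmb!r}") from exc
            if not tmb >= 0:
                raise ProfileError(f"TMB must be non-negative, got {tmb}")
            object.__setattr__(self, "tmb", tmb)
        if self.ms_status is not None and self.ms_status not in self._MS_VALUES:
            raise ProfileError(
                f"ms_status must be one of {self._MS_VALUES}, got {self.ms_status!r}"
            )
        if self.pdl1 is not None:
            pdl1 = float(self.pdl1)
            if not pdl1 >= 0:
                raise ProfileError(f"PD-L1 must be non-negative, got {pdl1}")
            object.__setattr__(self, "pdl1", pdl1)

    def as_dict(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {}
        for name in ("tmb", "ms_status", "pdl1"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        return out


def _dedupe(alterations: Iterable[GeneAlteration]) -> frozenset[GeneAlteration]:
    """Collapse alterations to unique triples; key origin takes precedence."""
    by_triple: dict[tuple, GeneAlteration] = {}
    for alt in alterations:
        prev = by_triple.get(alt.triple)
        if prev is None or (prev.origin is Origin.VUS and alt.origin is Origin.KEY):
            by_triple[alt.triple] = alt
    return frozenset(by_triple.values())


@dataclass(frozen=True)
class MolecularProfile:
    """A case's alteration sets plus optional biomarkers.

    The total set is the stored ``alterations``; key/VUS views are derived
    by origin.  Triples are unique (key precedence applied at construction
    via :meth:`from_alterations` / :func:`parse_profile`).
    """

    case_id: str
    alterations: frozenset[GeneAlteration]
    biomarkers: Biomarkers = field(default_factory=Biomarkers)

    @classmethod
    def from_alterations(
        cls,
        case_id: str,
        alterations: Iterable[GeneAlteration],
        biomarkers: Biomarkers | None = None,
    ) -> "MolecularProfile":
        alts = _dedupe(alterations)
        if not alts:
            raise ProfileError("empty profile")
        return cls(case_id, alts, biomarkers or Biomarkers())

    @property
    def key_alterations(self) -> frozenset[GeneAlteration]:
        return frozenset(a for a in self.alterations if a.origin is Origin.KEY)

    @property
    def vus_alterations(self) -> frozenset[GeneAlteration]:
        return frozenset(a for a in self.alterations if a.origin is Origin.VUS)

    @property
    def total_alterations(self) -> frozenset[GeneAlteration]:
        return self.alterations

    def gene_set(self, which: str = "total") -> frozenset[str]:
        """Unique gene symbols in the ``key``, ``vus`` or ``total`` view."""
        alts = {
            "key": self.key_alterations,
            "vus": self.vus_alterations,
            "total": self.alterations,
        }[which]
        return frozenset(a.gene for a in alts)

    def restricted(self, genes: Iterable[str]) -> frozenset[GeneAlteration]:
        genes = {g.upper() for g in genes}
        return frozenset(a for a in self.alterations if a.gene in genes)

    def summary(self) -> dict[str, int]:
        return {
            "n_key": len(self.key_alterations),
            "n_vus": len(self.vus_alterations),
            "n_total": len(self.alterations),
        }


def parse_profile(
    table: pd.DataFrame | Sequence[Mapping] | Sequence[tuple],
    biomarkers: Mapping | Biomarkers | None = None,
    case_id: str = "case",
) -> MolecularProfile:
    """Parse a tabular profile (gene, alteration_class, protein_change?, origin).

    Duplicate identical triples collapse to one entry; distinct alterations
    of the same gene are all retained.  Raises :class:`ProfileError` naming
    the offending row on an unknown alteration class or origin.
    """
    frame = _coerce_profile_frame(table)
    if frame.empty:
        raise ProfileError("empty profile")
    alts: list[GeneAlteration] = []
    for idx, row in frame.iterrows():
        try:
            alts.append(
                GeneAlteration(
                    gene=row["gene"],
                    alteration_class=str(row["alteration_class"]).strip().lower(),
                    protein_change=row.get("protein_change"),
                    origin=str(row["origin"]).strip().lower(),
                )
            )
        except (ValueError, ProfileError) as exc:
            raise ProfileError(f"row {idx}: {exc}") from exc
    if isinstance(biomarkers, Mapping):
        biomarkers = Biomarkers(**{k: v for k, v in biomarkers.items() if v is not None})
    return MolecularProfile.from_alterations(case_id, alts, biomarkers)


def _coerce_profile_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        frame = table.copy()
    else:
        rows = list(table)
        if rows and not isinstance(rows[0], Mapping):
            rows = [dict(zip(PROFILE_COLUMNS, r)) for r in rows]
        frame = pd.DataFrame(rows, columns=PROFILE_COLUMNS if not rows else None)
    missing = {"gene", "alteration_class", "origin"} - set(frame.columns)
    if missing and not frame.empty:
        raise ProfileError(f"profile table missing columns: {sorted(missing)}")
    if "protein_change" not in frame.columns:
        frame["protein_change"] = None
    frame["protein_change"] = frame["protein_change"].where(
        frame["protein_change"].notna(), None
    )
    return frame


def build_total_profile(profile: MolecularProfile) -> frozenset[GeneAlteration]:
    """Union of key and VUS alterations (key precedence on shared triples)."""
    return _dedupe(profile.alterations)


def build_consensus_profile(
    cases: Sequence[MolecularProfile],
    min_fraction: float = 0.5,
    case_id: str = "consensus",
) -> MolecularProfile:
    """Consensus profile of a case series.

    An alteration triple enters the consensus when it appears in at least
    ``min_fraction`` of cases (>= comparison over the number of cases); its
    origin is key if any contributing case reported it as key.  With
    ``min_fraction=1`` this is the intersection; with ``min_fraction <=
    1/n_cases`` it is the union.
    """
    if len(cases) < 2:
        raise ProfileError("consensus requires at least 2 cases")
    if not (0 < min_fraction <= 1):
        raise ProfileError(f"min_fraction must be in (0, 1], got {min_fraction}")
    counts: dict[tuple, int] = {}
    key_seen: dict[tuple, bool] = {}
    exemplar: dict[tuple, GeneAlteration] = {}
    for case in cases:
        for alt in case.alterations:
            counts[alt.triple] = counts.get(alt.triple, 0) + 1
            key_seen[alt.triple] = key_seen.get(alt.triple, False) or alt.origin is Origin.KEY
            exemplar[alt.triple] = alt
    n = len(cases)
    chosen = []
    for triple, count in counts.items():
        if count / n >= min_fraction:
            alt = exemplar[triple]
            chosen.append(
                GeneAlteration(
                    alt.gene,
                    alt.alteration_class,
                    alt.protein_change,
                    Origin.KEY if key_seen[triple] else Origin.VUS,
                )
            )
    if not chosen:
        raise ProfileError(
            f"no alteration reaches min_fraction={min_fraction} across {n} cases"
        )
    return MolecularProfile.from_alterations(case_id, chosen)


# ---------------------------------------------------------------------------
# medical-event timelines


@dataclass(frozen=True)
class TimelineEvent:
    date: str  # ISO-8601
    event_class: EventClass
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_class", EventClass(self.event_class))
        try:
            parsed = pd.Timestamp(self.date)
            if pd.isna(parsed):
                raise ValueError("NaT")
        except Exception as exc:
            raise ProfileError(f"unparsable date {self.date!r}") from exc
        object.__setattr__(self, "date", parsed.date().isoformat())


def order_timeline(events: Sequence[TimelineEvent | Mapping]) -> pd.DataFrame:
    """Sort events by date (stable: ties keep input order) with day intervals.

    Returns a frame with columns date, event_class, label, days_since_prev
    (NaN for the first event, 0 for same-day ties).
    """
    if not events:
        raise ProfileError("empty timeline")
    parsed: list[TimelineEvent] = []
    for i, ev in enumerate(events):
        try:
            if not isinstance(ev, TimelineEvent):
                ev = TimelineEvent(**dict(ev))
        except (ProfileError, ValueError) as exc:
            raise ProfileError(f"row {i}: {exc}") from exc
        parsed.append(ev)
    frame = pd.DataFrame(
        {
            "date": [pd.Timestamp(e.date) for e in parsed],
            "event_class": [e.event_class.value for e in parsed],
            "label": [e.label for e in parsed],
        }
    )
    frame = frame.sort_values("date", kind="stable").reset_index(drop=True)
    frame["days_since_prev"] = frame["date"].diff().dt.days
    frame["date"] = frame["date"].dt.date.astype(str)
    return frame


# ---------------------------------------------------------------------------
# TSV round-trip


def profile_to_frame(profile: MolecularProfile) -> pd.DataFrame:
    rows = [
        {
            "gene": a.gene,
            "alteration_class": a.alteration_class.value,
            "protein_change": a.protein_change or "",
            "origin": a.origin.value,
        }
        for a in sorted(profile.alterations)
    ]
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profile_tsv(profile: MolecularProfile, path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path, biomarkers=None, case_id: str | None = None) -> MolecularProfile:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.replace({"": None})
    import os

    cid = case_id or os.path.splitext(os.path.basename(str(path)))[0]
    return parse_profile(frame, biomarkers=biomarkers, case_id=cid)


def read_timeline_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return order_timeline(frame.to_dict("records"))
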