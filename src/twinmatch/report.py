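"""Trial-table construction and the machine-readable community report.

The community report is the quantitative content of a case's
"who-is-like-me" analysis: profile summary, matching parameters, DT+/DT-
community sizes, score distribution, balancing, enrichment, comparative
statistics and annotated clinical trials, with provenance (inputs, seed,
package version).  It is JSON-first with TSV companions; serialization is
deterministic (sorted keys), so a fixed seed and fixed inputs reproduce
the report byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
import re
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import ReportError
from .matching import CommunityAssignment, ScoreRow, scores_frame
from .profiles import MolecularProfile

logger = logging.getLogger(__name__)

_NCT_RE = re.compile(r"^NCT\d{8}$")
_STATUS_VALUES = ("recruiting", "active", "completed", "terminated", "withdrawn", "unknown")


class TrialRecord(BaseModel):
    model_config = {"frozen": True}

    nct_id: str
    status: str = "unknown"
    phase: str = ""
    cancer_type: str = ""
    gene_targets: frozenset[str] = frozenset()

    @field_validator("nct_id")
    @classmethod
    def _check_nct(cls, v: str) -> str:
        if not _NCT_RE.match(v):
            raise ValueError(f"malformed NCT id {v!r} (expected NCT + 8 digits)")
        return v

    @field_validator("status", mode="before")
    @classmethod
    def _check_status(cls, v: str) -> str:
        v = str(v).strip().lower()
        return v if v in _STATUS_VALUES else "unknown"

    @field_validator("gene_targets", mode="before")
    @classmethod
    def _upper_genes(cls, v) -> frozenset[str]:
        if isinstance(v, str):
            v = v.split(";")
        return frozenset(g.strip().upper() for g in v if g and g.strip())


def read_trials_tsv(path) -> list[TrialRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(TrialRecord(**row.to_dict()))
        except Exception as exc:
            raise ReportError(f"trial row {i}: {exc}") from exc
    return records


def build_trial_table(
    trials: Sequence[TrialRecord], profile: MolecularProfile
) -> pd.DataFrame:
    """Annotate trials with their gene-target overlap against the profile.

    Duplicate NCT ids collapse to the first occurrence (warning).  The
    VUS-aware columns let trials reachable only through VUS genes surface
    alongside key-gene trials.
    """
    seen: dict[str, TrialRecord] = {}
    for t in trials:
        if t.nct_id in seen:
            logger.warning("build_trial_table: duplicate trial %s dropped", t.nct_id)
            continue
        seen[t.nct_id] = t
    key = profile.gene_set("key")
    vus = profile.gene_set("vus")
    total = profile.gene_set("total")
    rows = []
    for t in seen.values():
        rows.append(
            {
                "nct_id": t.nct_id,
                "status": t.status,
                "phase": t.phase,
                "cancer_type": t.cancer_type,
                "gene_targets": ";".join(sorted(t.gene_targets)),
                "key_overlap": len(t.gene_targets & key),
                "vus_overlap": len(t.gene_targets & vus),
                "total_overlap": len(t.gene_targets & total),
                "overlap_genes": ";".join(sorted(t.gene_targets & total)),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["nct_id", "status", "phase", "cancer_type", "gene_targets",
                 "key_overlap", "vus_overlap", "total_overlap", "overlap_genes"],
    )
    return frame.sort_values(
        ["total_overlap", "status", "phase", "nct_id"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# report models


class ProfileSummary(BaseModel):
    case_id: str
    n_key: int
    n_vus: int
    n_total: int


class MatchingParams(BaseModel):
    level: str
    cutoff: float
    filters: list[str] = Field(default_factory=list)
    gene_subset: list[str] | None = None


class ScoreSummary(BaseModel):
    minimum: float
    median: float
    maximum: float


class MatchingSection(BaseModel):
    params: MatchingParams
    n_scored: int
    n_dt_positive: int
    n_dt_negative: int
    dt_positive: list[str]
    score_summary: ScoreSummary


class BalanceSection(BaseModel):
    features: list[str]
    n_pairs: int
    n_unmatched_treated: int
    converged: bool
    smd_before: dict[str, float] = Field(default_factory=dict)
    smd_after: dict[str, float] = Field(default_factory=dict)


class Provenance(BaseModel):
    inputs: dict[str, str] = Field(default_factory=dict)
    seed: int | None = None
    version: str = __version__


class CommunityReport(BaseModel):
    case_id: str
    profile: ProfileSummary
    matching: MatchingSection
    balance: BalanceSection | None = None
    enrichment: list[dict] | None = None
    comparisons: dict[str, list[dict]] | None = None
    trials: list[dict] | None = None
    provenance: Provenance


def _score_summary(scores: Sequence[ScoreRow]) -> ScoreSummary:
    vals = sorted(r.score for r in scores)
    n = len(vals)
    median = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
    return ScoreSummary(minimum=vals[0], median=median, maximum=vals[-1])


def build_report(
    profile: MolecularProfile,
    assignment: CommunityAssignment,
    level: str,
    filters: Sequence[str] = (),
    gene_subset: Sequence[str] | None = None,
    balance: BalanceSection | Mapping | None = None,
    enrichment: pd.DataFrame | None = None,
    comparisons: Mapping[str, pd.DataFrame] | None = None,
    trials: pd.DataFrame | None = None,
    inputs: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> CommunityReport:
    """Assemble the community report from module outputs.

    Requires at least the matching stage (the community assignment);
    every other section is optional and omitted when absent.
    """
    if assignment is None or not assignment.scores:
        raise ReportError("matching output (community assignment) is required")
    if isinstance(balance, Mapping):
        balance = BalanceSection(**balance)
    return CommunityReport(
        case_id=profile.case_id,
        profile=ProfileSummary(case_id=profile.case_id, **profile.summary()),
        matching=MatchingSection(
            params=MatchingParams(
                level=str(level),
                cutoff=assignment.cutoff,
                filters=list(filters),
                gene_subset=sorted(gene_subset) if gene_subset else None,
            ),
            n_scored=len(assignment.scores),
            n_dt_positive=len(assignment.dt_positive),
            n_dt_negative=len(assignment.dt_negative),
            dt_positive=sorted(assignment.dt_positive),
            score_summary=_score_summary(assignment.scores),
        ),
        balance=balance,
        enrichment=_frame_records(enrichment),
        comparisons=(
            {name: _frame_records(frame) for name, frame in comparisons.items()}
            if comparisons else None
        ),
        trials=_frame_records(trials),
        provenance=Provenance(inputs=dict(inputs or {}), seed=seed),
    )


def _frame_records(frame: pd.DataFrame | None) -> list[dict] | None:
    if frame is None:
        return None
    records = frame.to_dict("records")
    for rec in records:
        for k, v in rec.items():
            if hasattr(v, "item"):
                rec[k] = v.item()
    return records


def report_json(report: CommunityReport) -> str:
    return json.dumps(report.model_dump(mode="json"), sort_keys=True, indent=2) + "\n"


def load_report(path) -> CommunityReport:
    """Read back a report; pydantic validation enforces the shipped schema."""
    with open(path, encoding="utf-8") as fh:
        return CommunityReport.model_validate(json.load(fh))


def write_report(
    report: CommunityReport,
    out_dir,
    assignment: CommunityAssignment | None = None,
    enrichment: pd.DataFrame | None = None,
    comparisons: Mapping[str, pd.DataFrame] | None = None,
    trials: pd.DataFrame | None = None,
) -> None:
    """Write report.json plus its TSV companions."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        fh.write(report_json(report))
    if assignment is not None:
        scores_frame(assignment.scores).to_csv(
            os.path.join(out_dir, "scores.tsv"), sep="\t", index=False
        )
        communities = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in assignment.scores],
                "community": [
                    "dt_positive" if r.sample_id in assignment.dt_positive else "dt_negative"
                    for r in assignment.scores
                ],
            }
        )
        communities.to_csv(os.path.join(out_dir, "communities.tsv"), sep="\t", index=False)
    if enrichment is not None:
        enrichment.to_csv(os.path.join(out_dir, "enrichment.tsv"), sep="\t", index=False)
    if comparisons:
        frames = []
        for name, frame in comparisons.items():
            tagged = frame.copy()
            tagged.insert(0, "analysis", name)
            frames.append(tagged)
        pd.concat(frames, ignore_index=True).to_csv(
            os.path.join(out_dir, "comparisons.tsv"), sep="\t", index=False
        )
    if trials is not None:
        trials.to_csv(os.path.join(out_dir, "trials.tsv"), sep="\t", index=False)


def export_schema(path) -> None:
    """Write the report JSON schema (generated from the pydantic models)."""
    schema = CommunityReport.model_json_schema()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(schema, fh, indent=2, sort_keys=True)
        fh.write("\n")
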