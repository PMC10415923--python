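"""Cohort bundle I/O.

A cohort directory holds plain TSV tables keyed by sample_id:

* ``mutations.tsv`` — MAF-like long table: sample_id, gene,
  alteration_class, protein_change;
* ``copy_number.tsv`` — gene x sample matrix with GISTIC-style codes
  {-2, -1, 0, 1, 2}; |value| >= threshold (default 2) maps to
  deletion/amplification alterations;
* ``clinical.tsv`` — one row per sample: gender, tmb, ms_status,
  cancer_type, survival_time, survival_event, source, ...;
* optional ``expression.tsv`` (gene x sample), ``markers.tsv``
  (sample x marker), ``ic50.tsv`` (compound x cell line);
* ``manifest.json`` — provenance (config + seed) for simulated bundles.

Samples present in the clinical table but carrying no alteration are kept
as alteration-free cohort members.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MatchingError
from .matching import CohortSample
from .profiles import AlterationClass, GeneAlteration

logger = logging.getLogger(__name__)

MUTATIONS_FILE = "mutations.tsv"
COPY_NUMBER_FILE = "copy_number.tsv"
CLINICAL_FILE = "clinical.tsv"
EXPRESSION_FILE = "expression.tsv"
MARKERS_FILE = "markers.tsv"
IC50_FILE = "ic50.tsv"
MANIFEST_FILE = "manifest.json"


@dataclass
class Cohort:
    """In-memory cohort: samples plus optional molecular tables."""

    samples: list[CohortSample]
    expression: pd.DataFrame | None = None  # genes x samples
    markers: pd.DataFrame | None = None  # samples x markers
    ic50: pd.DataFrame | None = None  # compounds x lines
    gene_universe: frozenset[str] = frozenset()
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise MatchingError("duplicate sample_id in cohort")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def clinical_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [dict(s.features) for s in self.samples], index=self.sample_ids
        )
        frame.index.name = "sample_id"
        return frame

    def subset(self, sample_ids) -> "Cohort":
        wanted = set(sample_ids)
        return Cohort(
            samples=[s for s in self.samples if s.sample_id in wanted],
            expression=self.expression,
            markers=self.markers,
            ic50=self.ic50,
            gene_universe=self.gene_universe,
            manifest=self.manifest,
        )


def _alterations_from_tables(
    mutations: pd.DataFrame | None,
    copy_number: pd.DataFrame | None,
    cn_threshold: int = 2,
) -> tuple[dict[str, set[GeneAlteration]], set[str]]:
    per_sample: dict[str, set[GeneAlteration]] = {}
    genes: set[str] = set()
    if mutations is not None and not mutations.empty:
        for row in mutations.itertuples(index=False):
            pc = getattr(row, "protein_change", None)
            if pc is not None and (pd.isna(pc) or pc == ""):
                pc = None
            alt = GeneAlteration(row.gene, str(row.alteration_class).lower(), pc)
            per_sample.setdefault(str(row.sample_id), set()).add(alt)
            genes.add(alt.gene)
    if copy_number is not None and not copy_number.empty:
        genes.update(g.upper() for g in copy_number.index.astype(str))
        coded = copy_number.apply(pd.to_numeric, errors="coerce")
        for sample in coded.columns:
            col = coded[sample]
            for gene in col.index[col >= cn_threshold]:
                per_sample.setdefault(str(sample), set()).add(
                    GeneAlteration(gene, AlterationClass.AMPLIFICATION)
                )
            for gene in col.index[col <= -cn_threshold]:
                per_sample.setdefault(str(sample), set()).add(
                    GeneAlteration(gene, AlterationClass.DELETION)
                )
    return per_sample, genes


def _read_matrix(path, index_name: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = index_name
    frame.columns = frame.columns.astype(str)
    return frame


def read_cohort(directory, cn_threshold: int = 2) -> Cohort:
    """Assemble a :class:`Cohort` from a bundle directory."""
    path = lambda name: os.path.join(directory, name)  # noqa: E731
    mutations = None
    if os.path.exists(path(MUTATIONS_FILE)):
        mutations = pd.read_csv(path(MUTATIONS_FILE), sep="\t", dtype=str)
    copy_number = None
    if os.path.exists(path(COPY_NUMBER_FILE)):
        copy_number = _read_matrix(path(COPY_NUMBER_FILE), "gene")
    if mutations is None and copy_number is None:
        raise MatchingError(f"no mutation or copy-number table under {directory}")
    per_sample, genes = _alterations_from_tables(mutations, copy_number, cn_threshold)

    clinical = pd.DataFrame()
    if os.path.exists(path(CLINICAL_FILE)):
        clinical = pd.read_csv(path(CLINICAL_FILE), sep="\t", index_col="sample_id")
        clinical.index = clinical.index.astype(str)
    sample_ids = sorted(set(per_sample) | set(clinical.index))

    samples = []
    for sid in sample_ids:
        features = {}
        if sid in clinical.index:
            features = {
                k: (None if pd.isna(v) else v) for k, v in clinical.loc[sid].items()
            }
        samples.append(
            CohortSample(sid, frozenset(per_sample.get(sid, ())), features)
        )

    expression = markers = ic50 = None
    if os.path.exists(path(EXPRESSION_FILE)):
        expression = _read_matrix(path(EXPRESSION_FILE), "gene")
        genes.update(expression.index)
    if os.path.exists(path(MARKERS_FILE)):
        markers = pd.read_csv(path(MARKERS_FILE), sep="\t", index_col="sample_id")
        markers.index = markers.index.astype(str)
    if os.path.exists(path(IC50_FILE)):
        ic50 = _read_matrix(path(IC50_FILE), "compound")
    manifest = {}
    if os.path.exists(path(MANIFEST_FILE)):
        with open(path(MANIFEST_FILE), encoding="utf-8") as fh:
            manifest = json.load(fh)

    return Cohort(
        samples=samples,
        expression=expression,
        markers=markers,
        ic50=ic50,
        gene_universe=frozenset(genes),
        manifest=manifest,
    )


def concat_cohorts(*cohorts: Cohort, source_tags: list[str] | None = None) -> Cohort:
    """Hybrid (tumor + cell-line) matching pool: plain concatenation with a
    ``source`` feature tag per member cohort."""
    samples: list[CohortSample] = []
    genes: set[str] = set()
    for i, cohort in enumerate(cohorts):
        tag = source_tags[i] if source_tags else None
        for s in cohort.samples:
            features = dict(s.features)
            if tag is not None:
                features["source"] = tag
            samples.append(CohortSample(s.sample_id, s.alterations, features))
        genes |= cohort.gene_universe

    def _merge(attr: str, axis: int) -> pd.DataFrame | None:
        frames = [getattr(c, attr) for c in cohorts if getattr(c, attr) is not None]
        if not frames:
            return None
        return pd.concat(frames, axis=axis)

    return Cohort(
        samples=samples,
        expression=_merge("expression", 1),
        markers=_merge("markers", 0),
        ic50=_merge("ic50", 1),
        gene_universe=frozenset(genes),
    )
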