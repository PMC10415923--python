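"""Synthetic cohort generation with planted digital twins.

The generator emulates the tumor/cell-line resources a matching engine
queries — a MAF-like mutation table, a GISTIC-coded copy-number matrix,
clinical annotation with survival, and optional expression, immune-marker
and IC50 tables — with known ground truth planted in:

* ``n_planted`` samples each carry at least
  ``ceil(target_match_rate * |total profile|)`` of the case's alterations
  verbatim (mutations go to the MAF table, amplifications/deletions to the
  copy-number matrix), so the planted ids are recoverable as the DT+
  community at the planted cutoff;
* non-planted samples pick up case alterations only below that threshold
  (their gene-level match count is capped at ``ceil(rate * T) - 1``), so
  at well-separated rates twin recovery is exact;
* a clinical confounder (by default TMB, log-shifted by 0.6 for planted
  samples, pre-match SMD ~ 0.8) exercises propensity balancing;
* survival is exponential with a planted hazard ratio for the DT+ group;
* expression of designated genes is shifted additively in mutant
  carriers; markers and one compound's IC50 are log-shifted for planted
  samples.

A single integer seed drives every table through spawned child
generators, so identical configs produce byte-identical bundles and
partial regeneration is stable.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as cohort_io
from .errors import SimulationError
from .matching import CohortSample
from .profiles import AlterationClass, MolecularProfile

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CLASS_CHOICES = ("mutation", "amplification", "deletion")
_CLASS_PROBS = (0.7, 0.15, 0.15)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 500
    n_planted: int = 10
    target_match_rate: float = 0.8
    n_background_genes: int = 200
    gene_universe: list[str] | None = None  # default GEN0001..GEN{n}
    background_alteration_rate: float = 0.02  # per-gene Bernoulli, non-case genes
    case_pickup_rate: float = 0.02  # per-case-alteration Bernoulli, background samples
    # biomarker model
    tmb_log_mean: float = 1.2
    tmb_log_sd: float = 0.6
    p_mss: float = 0.8
    # confounder between planted / non-planted groups
    confounder_feature: str = "tmb"
    confounder_shift: float = 0.6  # log-scale for tmb, additive otherwise
    # survival model
    median_survival_days: float = 730.0
    hazard_ratio_planted: float = 2.0
    censoring_days: float = 1825.0
    # expression model
    expression_mean: float = 8.0
    expression_sd: float = 1.0
    expression_shift: float = 2.0
    shifted_genes: list[str] | None = None  # default: case mutation genes
    # markers and drug response
    marker_names: tuple[str, ...] = ("CD8", "CD14", "CD19", "neutrophils")
    marker_log_shift: float = -0.5
    compounds: tuple[str, ...] = ("cetuximab", "olaparib", "ceralasertib", "fluorouracil")
    sensitive_compound: str = "cetuximab"
    ic50_log_shift: float = -1.0
    cancer_type: str = "CRC"
    source: str = "tumor"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_samples:
            raise SimulationError(
                f"n_planted ({self.n_planted}) exceeds n_samples ({self.n_samples})"
            )
        for name in ("target_match_rate", "background_alteration_rate",
                     "case_pickup_rate", "p_mss"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class CohortBundle:
    mutations: pd.DataFrame  # sample_id, gene, alteration_class, protein_change
    copy_number: pd.DataFrame  # gene x sample, codes in {-2..2}
    clinical: pd.DataFrame  # indexed by sample_id
    expression: pd.DataFrame | None
    markers: pd.DataFrame | None
    ic50: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    @property
    def planted_ids(self) -> list[str]:
        return list(self.manifest.get("planted_ids", []))

    def to_cohort(self) -> cohort_io.Cohort:
        per_sample, genes = cohort_io._alterations_from_tables(
            self.mutations, self.copy_number
        )
        samples = []
        for sid in self.clinical.index:
            features = {
                k: (None if pd.isna(v) else v) for k, v in self.clinical.loc[sid].items()
            }
            samples.append(CohortSample(sid, frozenset(per_sample.get(sid, ())), features))
        if self.expression is not None:
            genes.update(self.expression.index)
        return cohort_io.Cohort(
            samples=samples,
            expression=self.expression,
            markers=self.markers,
            ic50=self.ic50,
            gene_universe=frozenset(genes),
            manifest=self.manifest,
        )


def _random_protein_change(rng: np.random.Generator) -> str:
    a, b = rng.choice(list(_AA), size=2)
    return f"p.{a}{int(rng.integers(1, 1000))}{b}"


def generate_cohort(profile: MolecularProfile, config: SimConfig) -> CohortBundle:
    """Generate a full cohort bundle with planted twins of ``profile``."""
    case_alts = sorted(profile.alterations)
    if not case_alts:
        raise SimulationError("profile has no alterations")
    T = len(case_alts)
    n_carry = math.ceil(config.target_match_rate * T)
    max_bg_matches = max(n_carry - 1, 0)
    if n_carry == 0:
        logger.warning(
            "generate_cohort: target_match_rate %g plants no alterations; planted "
            "and background samples are not separable", config.target_match_rate,
        )

    seq = np.random.SeedSequence(config.seed)
    rng_ids, rng_alt, rng_clin, rng_surv, rng_expr, rng_mark, rng_ic50 = (
        np.random.default_rng(s) for s in seq.spawn(7)
    )

    width = max(4, len(str(config.n_samples)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(config.n_samples)]
    planted = sorted(
        rng_ids.choice(sample_ids, size=config.n_planted, replace=False).tolist()
    )
    planted_set = set(planted)

    case_genes = {a.gene for a in case_alts}
    if config.gene_universe is not None:
        background_genes = sorted(
            {g.upper() for g in config.gene_universe} - case_genes
        )
    else:
        background_genes = [f"GEN{i + 1:04d}" for i in range(config.n_background_genes)]
    universe = sorted(case_genes | set(background_genes))

    mut_rows: list[dict] = []
    cn = pd.DataFrame(
        0, index=pd.Index(universe, name="gene"), columns=sample_ids, dtype=int
    )

    def _add_alteration(sid: str, gene: str, alt_class: AlterationClass, pc: str | None):
        if alt_class is AlterationClass.AMPLIFICATION:
            cn.loc[gene, sid] = 2
        elif alt_class is AlterationClass.DELETION:
            cn.loc[gene, sid] = -2
        else:
            mut_rows.append(
                {"sample_id": sid, "gene": gene,
                 "alteration_class": alt_class.value, "protein_change": pc or ""}
            )

    for sid in sample_ids:
        if sid in planted_set:
            idx = sorted(rng_alt.choice(T, size=n_carry, replace=False).tolist())
            carried = [case_alts[i] for i in idx]
        else:
            mask = rng_alt.random(T) < config.case_pickup_rate
            carried = [a for a, m in zip(case_alts, mask) if m]
            # cap gene-level matches strictly below the planted threshold
            while carried:
                genes_carried = {a.gene for a in carried}
                n_matches = sum(1 for a in case_alts if a.gene in genes_carried)
                if n_matches <= max_bg_matches:
                    break
                drop_gene = sorted(genes_carried)[0]
                carried = [a for a in carried if a.gene != drop_gene]
        for alt in carried:
            _add_alteration(sid, alt.gene, alt.alteration_class, alt.protein_change)
        noise_mask = rng_alt.random(len(background_genes)) < config.background_alteration_rate
        for gene, hit in zip(background_genes, noise_mask):
            if not hit:
                continue
            alt_class = AlterationClass(
                rng_alt.choice(_CLASS_CHOICES, p=_CLASS_PROBS)
            )
            pc = (
                _random_protein_change(rng_alt)
                if alt_class is AlterationClass.MUTATION else None
            )
            _add_alteration(sid, gene, alt_class, pc)

    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "gene", "alteration_class", "protein_change"]
    )

    # clinical features ------------------------------------------------------
    n = config.n_samples
    is_planted = np.array([sid in planted_set for sid in sample_ids])
    gender = np.where(rng_clin.random(n) < 0.5, "female", "male")
    tmb_mu = np.full(n, config.tmb_log_mean)
    if config.confounder_feature == "tmb":
        tmb_mu = tmb_mu + np.where(is_planted, config.confounder_shift, 0.0)
    tmb = np.exp(rng_clin.normal(tmb_mu, config.tmb_log_sd))
    ms_status = np.where(rng_clin.random(n) < config.p_mss, "MSS", "MSI-H")
    clinical = pd.DataFrame(
        {
            "gender": gender,
            "tmb": tmb,
            "ms_status": ms_status,
            "cancer_type": config.cancer_type,
            "source": config.source,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if config.confounder_feature not in clinical.columns:
        clinical[config.confounder_feature] = rng_clin.normal(0.0, 1.0, n) + np.where(
            is_planted, config.confounder_shift, 0.0
        )

    rate = math.log(2.0) / config.median_survival_days
    rates = np.where(is_planted, rate * config.hazard_ratio_planted, rate)
    raw_t = rng_surv.exponential(1.0 / rates)
    clinical["survival_time"] = np.minimum(raw_t, config.censoring_days)
    clinical["survival_event"] = (raw_t <= config.censoring_days).astype(int)

    # expression -------------------------------------------------------------
    expression = pd.DataFrame(
        rng_expr.normal(config.expression_mean, config.expression_sd,
                        size=(len(universe), n)),
        index=pd.Index(universe, name="gene"),
        columns=sample_ids,
    )
    shifted = config.shifted_genes
    if shifted is None:
        shifted = sorted(
            {a.gene for a in case_alts if a.alteration_class is AlterationClass.MUTATION}
        )
    mut_carriers: dict[str, set[str]] = {}
    for row in mut_rows:
        if row["alteration_class"] == "mutation":
            mut_carriers.setdefault(row["gene"], set()).add(row["sample_id"])
    for gene in shifted:
        gene = gene.upper()
        carriers = [s for s in sample_ids if s in mut_carriers.get(gene, ())]
        if gene in expression.index and carriers:
            expression.loc[gene, carriers] += config.expression_shift

    # markers ----------------------------------------------------------------
    shift = np.where(is_planted, config.marker_log_shift, 0.0)
    markers = pd.DataFrame(
        {
            m: np.exp(rng_mark.normal(2.0 + shift, 0.5))
            for m in config.marker_names
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # IC50 -------------------------------------------------------------------
    mus = rng_ic50.uniform(0.0, 3.0, size=len(config.compounds))
    ic50_log = {
        comp: rng_ic50.normal(mu, 1.0, size=n) for comp, mu in zip(config.compounds, mus)
    }
    if config.sensitive_compound in ic50_log:
        ic50_log[config.sensitive_compound] = (
            ic50_log[config.sensitive_compound] + np.where(is_planted, config.ic50_log_shift, 0.0)
        )
    ic50 = pd.DataFrame(
        {comp: np.exp(v) for comp, v in ic50_log.items()},
        index=pd.Index(sample_ids, name="sample_id"),
    ).T
    ic50.index.name = "compound"

    manifest = {
        "seed": config.seed,
        "config": _config_dict(config),
        "planted_ids": planted,
        "case_id": profile.case_id,
        "n_case_alterations": T,
        "n_carried_planted": n_carry,
        "tables": {
            "mutations": True, "copy_number": True, "clinical": True,
            "expression": True, "markers": True, "ic50": True,
        },
    }
    return CohortBundle(mutations, cn, clinical, expression, markers, ic50, manifest)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_bundle(bundle: CohortBundle, out_dir, force: bool = False) -> None:
    """Write the bundle as the TSV/JSON formats :mod:`twinmatch.io` reads.

    Refuses to overwrite a directory whose manifest records a different
    seed unless ``force`` is set.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, cohort_io.MANIFEST_FILE)
    if os.path.exists(manifest_path) and not force:
        with open(manifest_path, encoding="utf-8") as fh:
            existing = json.load(fh)
        if existing.get("seed") != bundle.manifest.get("seed"):
            raise SimulationError(
                f"{out_dir} already holds a bundle with seed {existing.get('seed')}; "
                "pass force=True to overwrite"
            )
    tables = dict(bundle.manifest.get("tables", {}))
    bundle.mutations.to_csv(
        os.path.join(out_dir, cohort_io.MUTATIONS_FILE), sep="\t", index=False
    )
    bundle.copy_number.to_csv(os.path.join(out_dir, cohort_io.COPY_NUMBER_FILE), sep="\t")
    bundle.clinical.to_csv(os.path.join(out_dir, cohort_io.CLINICAL_FILE), sep="\t")
    for frame, name, key in (
        (bundle.expression, cohort_io.EXPRESSION_FILE, "expression"),
        (bundle.markers, cohort_io.MARKERS_FILE, "markers"),
        (bundle.ic50, cohort_io.IC50_FILE, "ic50"),
    ):
        if frame is not None:
            frame.to_csv(os.path.join(out_dir, name), sep="\t")
            tables[key] = True
        else:
            tables[key] = False
    manifest = dict(bundle.manifest)
    manifest["tables"] = tables
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
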