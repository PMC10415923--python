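"""Shared fixtures and independent oracles.

The oracle functions here are deliberately naive (double loops, full
enumeration) and independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import twinmatch as tm
from twinmatch.matching import CohortSample
from twinmatch.profiles import GeneAlteration


@pytest.fixture
def case_profile() -> tm.MolecularProfile:
    """A CRC-flavored case: three key mutations plus one VUS."""
    return tm.parse_profile(
        [
            ("APC", "mutation", "p.T1556fs", "key"),
            ("TP53", "mutation", "p.R175H", "key"),
            ("KRAS", "mutation", "p.G12D", "key"),
            ("PARP2", "mutation", "p.I333V", "vus"),
        ],
        biomarkers={"tmb": 3.0, "ms_status": "MSS"},
        case_id="case01",
    )


@pytest.fixture(scope="session")
def sim_bundle():
    profile = tm.parse_profile(
        [
            ("APC", "mutation", "p.T1556fs", "key"),
            ("TP53", "mutation", "p.R175H", "key"),
            ("KRAS", "mutation", "p.G12D", "key"),
            ("ERBB2", "amplification", None, "key"),
            ("PARP2", "mutation", "p.I333V", "vus"),
        ],
        case_id="simcase",
    )
    config = tm.SimConfig(n_samples=200, n_planted=8, n_background_genes=60, seed=11)
    return profile, config, tm.generate_cohort(profile, config)


@pytest.fixture(scope="session")
def sim_cohort(sim_bundle):
    _, _, bundle = sim_bundle
    return bundle.to_cohort()


# ---------------------------------------------------------------------------
# oracles


def brute_force_score(profile, sample, level, gene_subset=None):
    """Double-loop connecting-score counter, independent of score_cohort."""
    case_alts = sorted(profile.alterations)
    if gene_subset is not None:
        subset = {g.upper() for g in gene_subset}
        case_alts = [a for a in case_alts if a.gene in subset]
    matched = 0
    for ca in case_alts:
        hit = False
        for sa in sample.alterations:
            if ca.gene != sa.gene:
                continue
            if level == "gene":
                hit = True
            elif level == "gene_alteration":
                hit = hit or ca.alteration_class == sa.alteration_class
            else:  # gene_protein
                if ca.alteration_class == sa.alteration_class:
                    if ca.alteration_class.value != "mutation":
                        hit = True
                    else:
                        hit = hit or ca.protein_change == sa.protein_change
        matched += int(hit)
    return matched, len(case_alts)


def enumerate_hypergeom_upper(N, K, n, k):
    """P(X >= k) by enumerating every n-subset of an N-element universe."""
    universe = list(range(N))
    special = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def enumerate_wilcoxon_p(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(nx + ny), nx):
        u = sum(i + 1 for i in combo) - nx * (nx + 1) / 2
        us.append(u)
    total = len(us)
    n_le = sum(1 for u in us if u <= u_obs)
    n_ge = sum(1 for u in us if u >= u_obs)
    return min(1.0, 2 * min(n_le, n_ge) / total)


def product_limit_by_hand(times, events):
    """Product-limit values at event times, computed step by step."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    times = [times[i] for i in order]
    events = [events[i] for i in order]
    distinct_event_times = sorted({t for t, e in zip(times, events) if e == 1})
    s = 1.0
    out = []
    for t in distinct_event_times:
        n_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1 - d / n_risk
        out.append((t, s, n_risk))
    return out


def random_alteration(rng, genes, with_protein=0.7):
    cls = rng.choice(["mutation", "amplification", "deletion", "fusion"])
    pc = None
    if cls == "mutation" and rng.random() < with_protein:
        pc = f"p.A{int(rng.integers(1, 6))}V"
    return GeneAlteration(str(rng.choice(genes)), cls, pc)


def random_profile_and_sample(rng, n_genes=8):
    genes = [f"G{i}" for i in range(n_genes)]
    n_case = int(rng.integers(1, 7))
    n_sample = int(rng.integers(0, 11))
    case = [random_alteration(rng, genes) for _ in range(n_case)]
    profile = tm.MolecularProfile.from_alterations("rnd", case)
    sample = CohortSample(
        "smp", frozenset(random_alteration(rng, genes) for _ in range(n_sample))
    )
    return profile, sample
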