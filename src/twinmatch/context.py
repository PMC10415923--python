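"""'Find signatures like me': enrichment and chromosomal proximity.

Signature enrichment is one-sided hypergeometric over-representation of a
profile gene set (key, VUS, or total) within a named signature, computed
against a user-selected background gene panel of size N.  With K signature
genes in the background and n query genes in the background, the p-value
for an overlap of k genes is the upper tail P(X >= k), X ~
Hypergeometric(N, K, n).  Benjamini-Hochberg adjustment is applied across
signatures within each gene-set view.

Spatial grouping bins profile genes by chromosome arm from a
gene -> cytoband annotation, surfacing proximity clusters (e.g. several
VUS genes on 13q).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContextError
from .profiles import MolecularProfile, Origin

logger = logging.getLogger(__name__)

_CHROMOSOMES = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_ORDER = {c: i for i, c in enumerate(_CHROMOSOMES)}


@dataclass(frozen=True)
class Signature:
    name: str
    genes: frozenset[str]
    collection: str = ""

    def __post_init__(self) -> None:
        genes = frozenset(g.strip().upper() for g in self.genes if g and g.strip())
        if not genes:
            raise ContextError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", genes)


@dataclass(frozen=True)
class EnrichmentResult:
    signature: str
    gene_set: str  # key | vus | total
    N: int
    K: int
    n: int
    k: int
    p_value: float
    p_adjusted: float
    overlap_genes: frozenset[str]


@dataclass(frozen=True)
class CytobandAnnotation:
    gene: str
    chromosome: str
    arm: str
    band: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.strip().upper())
        chrom = str(self.chromosome).removeprefix("chr")
        if chrom not in _CHROM_ORDER:
            raise ContextError(f"invalid chromosome {self.chromosome!r} for {self.gene}")
        object.__setattr__(self, "chromosome", chrom)
        if self.arm not in ("p", "q"):
            raise ContextError(f"invalid arm {self.arm!r} for {self.gene}")
        if not str(self.band).startswith(chrom + self.arm):
            raise ContextError(
                f"band {self.band!r} does not begin with {chrom}{self.arm} for {self.gene}"
            )


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts signature genes among n draws without replacement from a
    background of N genes containing K signature genes.  Computed through
    the log-gamma based survival function, stable for N up to 1e5.
    """
    if N < 1:
        raise ContextError(f"background size N must be >= 1, got {N}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ContextError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ContextError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_signatures(
    profile: MolecularProfile,
    signatures: Sequence[Signature],
    background: Iterable[str],
    gene_sets: Sequence[str] = ("key", "vus", "total"),
) -> list[EnrichmentResult]:
    """Test each signature against the key / VUS / total gene-set views.

    Query genes outside the background are dropped (standard
    over-representation convention, count logged); signatures with no gene
    in the background are skipped with a warning.  BH adjustment is
    applied within each gene-set view across signatures.  Results are
    sorted by raw p ascending (ties by gene_set, signature name).
    """
    background = frozenset(g.strip().upper() for g in background if g and g.strip())
    if not background:
        raise ContextError("empty background gene panel")
    N = len(background)
    results: list[EnrichmentResult] = []
    for gene_set in gene_sets:
        query_all = profile.gene_set(gene_set)
        query = query_all & background
        if len(query) < len(query_all):
            logger.info(
                "enrich_signatures[%s]: %d query genes outside the background dropped",
                gene_set, len(query_all) - len(query),
            )
        batch: list[EnrichmentResult] = []
        for sig in signatures:
            K = len(sig.genes & background)
            if K == 0:
                logger.warning(
                    "enrich_signatures: signature %r disjoint from background; skipped",
                    sig.name,
                )
                continue
            overlap = sig.genes & query
            p = hypergeom_pvalue(N, K, len(query), len(overlap))
            batch.append(
                EnrichmentResult(
                    signature=sig.name,
                    gene_set=gene_set,
                    N=N,
                    K=K,
                    n=len(query),
                    k=len(overlap),
                    p_value=p,
                    p_adjusted=p,  # replaced below
                    overlap_genes=frozenset(overlap),
                )
            )
        if batch:
            _, adj, _, _ = multipletests([r.p_value for r in batch], method="fdr_bh")
            batch = [
                EnrichmentResult(
                    r.signature, r.gene_set, r.N, r.K, r.n, r.k,
                    r.p_value, float(a), r.overlap_genes,
                )
                for r, a in zip(batch, adj)
            ]
        results.extend(batch)
    results.sort(key=lambda r: (r.p_value, r.gene_set, r.signature))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "signature": r.signature,
                "gene_set": r.gene_set,
                "N": r.N,
                "K": r.K,
                "n": r.n,
                "k": r.k,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "overlap_genes": ";".join(sorted(r.overlap_genes)),
            }
            for r in results
        ],
        columns=[
            "signature", "gene_set", "N", "K", "n", "k",
            "p_value", "p_adjusted", "overlap_genes",
        ],
    )


def spatial_group(
    profile: MolecularProfile, annotation: Sequence[CytobandAnnotation]
) -> pd.DataFrame:
    """Group profile genes by chromosome arm.

    Returns one row per (chromosome, arm) group carrying >= 1 profile
    gene, sorted by member count descending then chromosome order, plus a
    terminal ``unplaced`` row for profile genes without annotation.
    Per-group origin is ``key``, ``vus`` or ``mixed``.
    """
    if not annotation:
        raise ContextError("empty cytoband annotation")
    ann = {a.gene: a for a in annotation}
    origins: dict[str, str] = {}
    for alt in profile.alterations:
        prev = origins.get(alt.gene)
        cur = alt.origin.value
        origins[alt.gene] = cur if prev in (None, cur) else "mixed"
    groups: dict[tuple[str, str], list[str]] = {}
    unplaced: list[str] = []
    for gene in sorted(origins):
        a = ann.get(gene)
        if a is None:
            unplaced.append(gene)
        else:
            groups.setdefault((a.chromosome, a.arm), []).append(gene)
    if not any(g in ann for g in origins):
        raise ContextError("annotation covers no profile gene")

    def group_origin(genes: list[str]) -> str:
        vals = {origins[g] for g in genes}
        return vals.pop() if len(vals) == 1 and "mixed" not in vals else "mixed"

    rows = [
        {
            "group": f"{chrom}{arm}",
            "chromosome": chrom,
            "arm": arm,
            "genes": ";".join(genes),
            "origin": group_origin(genes),
            "count": len(genes),
        }
        for (chrom, arm), genes in groups.items()
    ]
    rows.sort(key=lambda r: (-r["count"], _CHROM_ORDER[r["chromosome"]], r["arm"]))
    if unplaced:
        rows.append(
            {
                "group": "unplaced",
                "chromosome": "",
                "arm": "",
                "genes": ";".join(unplaced),
                "origin": group_origin(unplaced),
                "count": len(unplaced),
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "chromosome", "arm", "genes", "origin", "count"]
    )


# ---------------------------------------------------------------------------
# file readers


def read_signatures(path, collection: str = "") -> list[Signature]:
    """Read signatures from GMT (name, description, genes...) or two-column
    TSV (signature, gene) — auto-detected."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ContextError(f"no signatures in {path}")
    first = lines[0].split("\t")
    if str(path).endswith(".gmt") or len(first) > 2:
        sigs = []
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise ContextError(f"malformed GMT line: {ln!r}")
            sigs.append(Signature(parts[0], frozenset(parts[2:]), collection or parts[1]))
        return sigs
    frame = pd.read_csv(path, sep="\t")
    name_col, gene_col = frame.columns[:2]
    return [
        Signature(str(name), frozenset(sub[gene_col].astype(str)), collection)
        for name, sub in frame.groupby(name_col, sort=True)
    ]


def read_background(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        genes = [ln.strip().upper() for ln in fh if ln.strip()]
    if genes and genes[0].lower() in ("gene", "symbol"):
        genes = genes[1:]
    return frozenset(genes)


def read_cytoband_annotation(path) -> list[CytobandAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "chromosome", "arm", "band"}
    if not required <= set(frame.columns):
        raise ContextError(f"annotation must have columns {sorted(required)}")
    return [
        CytobandAnnotation(r.gene, r.chromosome, r.arm, r.band)
        for r in frame.itertuples(index=False)
    ]
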