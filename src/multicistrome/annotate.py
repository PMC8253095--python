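"""Genomic-context annotation, TSS-proximity peak-to-gene linkage, and
hypergeometric gene-set over-representation with Benjamini-Hochberg control.

Peak-to-gene linkage assigns each region to the gene whose TSS is nearest the
region midpoint, provided the distance is within a window (default 20 kb);
equidistant TSSs all receive the link. The same rule, with a single gene set,
drives the essential-gene enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import Gene, IntervalSet

DEFAULT_TSS_WINDOW = 20_000
DEFAULT_PROMOTER_FLANK = 1_000
DEFAULT_TOP_N = 12

CONTEXT_CATEGORIES = ("promoter", "exon", "intron", "downstream", "distal_intergenic")


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int  # k
    set_size: int  # K (within universe)
    query_size: int  # n
    universe_size: int  # N
    p_value: float
    fdr: float
    overlapping_genes: tuple[str, ...]


def genomic_context(
    regions: IntervalSet,
    genes: list[Gene],
    promoter_flank: int = DEFAULT_PROMOTER_FLANK,
    exons: dict[str, IntervalSet] | None = None,
) -> dict[str, float]:
    """Percentage of regions per genomic category, classified by midpoint.

    Precedence: promoter > exon > intron > downstream > distal intergenic.
    Promoter = [TSS - flank, TSS + flank); downstream = up to ``promoter_flank``
    bp past the gene's 3' end. Without exon annotation the gene body counts as
    intron.
    """
    if len(regions) == 0:
        raise ValueError("cannot compute a context distribution of zero regions")
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    counts = dict.fromkeys(CONTEXT_CATEGORIES, 0)
    for iv in regions:
        mid = iv.midpoint
        cat = "distal_intergenic"
        for g in by_chrom.get(iv.chrom, ()):
            if g.tss - promoter_flank <= mid < g.tss + promoter_flank:
                cat = "promoter"
                break
            if g.start >= 0 and g.start <= mid < g.end:
                in_exon = False
                if exons and g.gene_id in exons:
                    in_exon = any(
                        e.start <= mid < e.end for e in exons[g.gene_id]
                    )
                cat = _higher_precedence(cat, "exon" if in_exon else "intron")
            elif g.start >= 0 and _in_downstream(g, mid, promoter_flank):
                cat = _higher_precedence(cat, "downstream")
        counts[cat] += 1
    total = len(regions)
    return {c: 100.0 * counts[c] / total for c in CONTEXT_CATEGORIES}


def _in_downstream(g: Gene, pos: int, flank: int) -> bool:
    if g.strand == "+":
        return g.end <= pos < g.end + flank
    return g.start - flank <= pos < g.start


_PRECEDENCE = {c: i for i, c in enumerate(CONTEXT_CATEGORIES)}


def _higher_precedence(current: str, candidate: str) -> str:
    return candidate if _PRECEDENCE[candidate] < _PRECEDENCE[current] else current


def link_regions_to_genes(
    regions: IntervalSet,
    genes: list[Gene],
    window: int = DEFAULT_TSS_WINDOW,
) -> tuple[set[str], pd.DataFrame]:
    """Assign each region to its nearest-TSS gene within ``window`` bp.

    Distance is |TSS - region midpoint|. Equidistant TSSs all receive the
    link; the returned gene set is deduplicated. Regions farther than
    ``window`` from every TSS stay unassigned (absent from the table).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    tss_by_chrom: dict[str, tuple[np.ndarray, list[Gene]]] = {}
    for chrom in {g.chrom for g in genes}:
        gs = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: (g.tss, g.gene_id)
        )
        tss_by_chrom[chrom] = (np.array([g.tss for g in gs]), gs)

    rows = []
    linked: set[str] = set()
    for i, iv in enumerate(regions):
        entry = tss_by_chrom.get(iv.chrom)
        if entry is None:
            continue
        tss, gs = entry
        mid = iv.midpoint
        d = np.abs(tss - mid)
        dmin = int(d.min())
        if dmin > window:
            continue
        for j in np.flatnonzero(d == dmin):
            g = gs[int(j)]
            linked.add(g.gene_id)
            rows.append(
                {
                    "region_index": i,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "gene_id": g.gene_id,
                    "distance": dmin,
                }
            )
    return linked, pd.DataFrame(
        rows, columns=["region_index", "chrom", "start", "end", "gene_id", "distance"]
    )


def hypergeometric_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    top_n: int = DEFAULT_TOP_N,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
    n=|query ∩ universe|). Query genes outside the universe are dropped; sets
    are intersected with the universe. BH-adjusted across all tested sets;
    results sorted by FDR then p; the top ``top_n`` are returned.
    """
    if not universe:
        raise ValueError("empty universe")
    query_in = query & universe
    n = len(query_in)
    big_n = len(universe)
    results = []
    for name, members in gene_sets.items():
        members_in = members & universe
        big_k = len(members_in)
        hits = tuple(sorted(query_in & members_in))
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=k,
                set_size=big_k,
                query_size=n,
                universe_size=big_n,
                p_value=min(p, 1.0),
                fdr=np.nan,
                overlapping_genes=hits,
            )
        )
    if results:
        pvals = [r.p_value for r in results]
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    results.sort(key=lambda r: (r.fdr, r.p_value, r.set_name))
    return results[:top_n]


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "genes": ",".join(r.overlapping_genes),
            }
            for r in results
        ]
    )
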