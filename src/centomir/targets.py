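"""Seed-match target scanning and gene-set over-representation.

A miRNA represses transcripts whose 3' UTR carries the reverse complement
of its seed region -- by default bases 2-8 from the miRNA 5' end (a
configurable switch narrows this to 2-7, the other common convention).
The scan reports exact seed-site matches only and, following the usual
stringency heuristic, suppresses genes with fewer than two predicted
sites. Genes hit by several query miRNAs are cross-referenced, since
co-targeting by multiple miRNAs acts additively on repression.

Over-representation of a target list within user-supplied gene sets
(GO-style categories, aging-gene collections, ...) uses the one-sided
hypergeometric upper-tail test with Bonferroni correction over the sets
tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from ._seq import normalize, revcomp

DEFAULT_SEED_SPAN = (2, 8)  # 1-based inclusive positions within the mature miRNA
DEFAULT_MIN_SITES = 2


@dataclass
class SeedSiteHit:
    mirna: str
    gene: str
    utr_positions: tuple[int, ...]  # 1-based starts of the site in the UTR
    co_targeting_mirnas: tuple[str, ...] = ()

    @property
    def n_sites(self) -> int:
        return len(self.utr_positions)


def seed_of(mature: str, seed_span: tuple[int, int] = DEFAULT_SEED_SPAN) -> str:
    lo, hi = seed_span
    mature = normalize(mature)
    if not (1 <= lo <= hi):
        raise ValueError("seed span must satisfy 1 <= start <= end")
    if len(mature) < hi:
        raise ValueError(f"mature sequence shorter than seed span end ({hi})")
    return mature[lo - 1 : hi]


def _site_positions(utr: str, motif: str) -> tuple[int, ...]:
    """All (overlapping) 1-based start positions of motif in utr."""
    positions = []
    i = utr.find(motif)
    while i != -1:
        positions.append(i + 1)
        i = utr.find(motif, i + 1)
    return tuple(positions)


def seed_sites(
    mirna: str,
    mature: str,
    utrs: dict[str, str],
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[SeedSiteHit]:
    """Exact seed-match sites of one miRNA across a UTR collection.

    The site motif is the DNA reverse complement of the seed; genes with
    fewer than ``min_sites`` sites are suppressed.
    """
    motif = revcomp(seed_of(mature, seed_span))
    hits = []
    for gene in sorted(utrs):
        positions = _site_positions(normalize(utrs[gene]), motif)
        if len(positions) >= min_sites:
            hits.append(SeedSiteHit(mirna, gene, positions))
    return hits


def scan_targets(
    matures: dict[str, str],
    utrs: dict[str, str],
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[SeedSiteHit]:
    """Scan a panel of miRNAs and annotate co-targeting across the panel."""
    all_hits: list[SeedSiteHit] = []
    for mirna in sorted(matures):
        all_hits.extend(seed_sites(mirna, matures[mirna], utrs, seed_span, min_sites))
    by_gene: dict[str, list[str]] = {}
    for hit in all_hits:
        by_gene.setdefault(hit.gene, []).append(hit.mirna)
    for hit in all_hits:
        hit.co_targeting_mirnas = tuple(
            m for m in by_gene[hit.gene] if m != hit.mirna
        )
    return all_hits


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe: int
    p_raw: float
    p_adjusted: float
    genes: tuple[str, ...] = ()


def enrichment_test(
    gene_list,
    gene_sets: dict[str, set[str] | list[str]],
    universe,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Every set is intersected with the universe first; the p-value is the
    upper tail P(X >= overlap) for X hypergeometric(universe, set size,
    list size), Bonferroni-adjusted over the number of sets tested.
    Results are sorted by adjusted then raw p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list) & universe
    n_sets = len(gene_sets)
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        overlap = gene_list & members
        p = float(
            stats.hypergeom.sf(
                len(overlap) - 1, len(universe), len(members), len(gene_list)
            )
        )
        p = min(1.0, max(p, 0.0))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=len(overlap),
                set_size=len(members),
                list_size=len(gene_list),
                universe=len(universe),
                p_raw=p,
                p_adjusted=min(1.0, p * n_sets),
                genes=tuple(sorted(overlap)),
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.set_name))
    return results


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_hits_table(path, hits: list[SeedSiteHit]) -> None:
    rows = [
        {
            "mirna": h.mirna,
            "gene": h.gene,
            "n_sites": h.n_sites,
            "utr_positions": ",".join(map(str, h.utr_positions)),
            "co_targeting_mirnas": ",".join(h.co_targeting_mirnas),
        }
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_enrichment_table(path, results: list[EnrichmentResult]) -> None:
    rows = [
        {
            "set_name": r.set_name,
            "overlap": r.overlap,
            "set_size": r.set_size,
            "list_size": r.list_size,
            "universe": r.universe,
            "p_value": r.p_raw,
            "bonferroni_p": r.p_adjusted,
            "genes": ",".join(r.genes),
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
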