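"""Strand-specific, exon-specific intersection of two gene catalogues.

Two genes match only when they sit on the same chromosome and strand and at
least one exon of one overlaps an exon of the other by at least ``min_overlap``
bp (half-open intervals). Gene-level overlap is the union over all isoform
exons of both genes, so a gene whose exon falls entirely inside the other
gene's intron does not match. Matching is a sweep over start-sorted exon
endpoints per (chromosome, strand) with active sets keyed by exon end,
costing O(n log n) plus the number of overlapping exon pairs.
"""

from __future__ import annotations

import heapq
from collections import defaultdict

import pandas as pd

from .errors import CatalogueFormatError
from .features import TranscriptModel

__all__ = ["Catalogue", "merged_exons", "intersect_catalogues"]

Catalogue = list[TranscriptModel]


def merged_exons(catalogue: Catalogue) -> dict[str, list[tuple[str, str, int, int]]]:
    """Per-gene union of isoform exons as (chrom, strand, start, end) tuples."""
    by_gene: dict[str, list] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    for t in catalogue:
        key = (t.chrom, t.strand)
        if meta.setdefault(t.gene_id, key) != key:
            raise CatalogueFormatError(
                f"gene {t.gene_id}: isoforms on different chromosomes/strands"
            )
        by_gene[t.gene_id].extend(t.exons)
    out: dict[str, list[tuple[str, str, int, int]]] = {}
    for gene_id, exons in by_gene.items():
        chrom, strand = meta[gene_id]
        exons.sort()
        merged: list[list[int]] = []
        for s, e in exons:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[gene_id] = [(chrom, strand, s, e) for s, e in merged]
    return out


def intersect_catalogues(
    a: Catalogue, b: Catalogue, min_overlap: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exon-level gene matching between two catalogues.

    Returns ``(matches, counts)``: matched gene pairs with their total exonic
    overlap in bp, and per-gene-of-``a`` match counts (zero allowed).
    """
    if min_overlap < 1:
        raise CatalogueFormatError("min_overlap must be >= 1")
    exons_a = merged_exons(a)
    exons_b = merged_exons(b)

    # bucket exons by (chrom, strand)
    def bucket(exons_by_gene):
        buckets = defaultdict(list)
        for gene_id, exons in exons_by_gene.items():
            for chrom, strand, s, e in exons:
                buckets[(chrom, strand)].append((s, e, gene_id))
        for lst in buckets.values():
            lst.sort()
        return buckets

    ba, bb = bucket(exons_a), bucket(exons_b)
    overlap_bp: dict[tuple[str, str], int] = defaultdict(int)
    for key in set(ba) & set(bb):
        # sweep exons of both catalogues by start; each incoming exon is
        # scored against the still-active exons of the other side, so every
        # overlapping exon pair is counted exactly once
        merged = [(s, e, g, 0) for s, e, g in ba[key]] + [
            (s, e, g, 1) for s, e, g in bb[key]
        ]
        merged.sort()
        active: tuple[list, list] = ([], [])  # per side, heap of (end, start, gene)
        for s, e, g, side in merged:
            mine, other = active[side], active[1 - side]
            while other and other[0][0] <= s:
                heapq.heappop(other)
            for oe, _os, og in other:
                pair = (g, og) if side == 0 else (og, g)
                overlap_bp[pair] += min(e, oe) - s
            heapq.heappush(mine, (e, s, g))
    rows = [
        {"gene_a": ga, "gene_b": gb, "overlap_bp": bp}
        for (ga, gb), bp in sorted(overlap_bp.items())
        if bp >= min_overlap
    ]
    matches = pd.DataFrame(rows, columns=["gene_a", "gene_b", "overlap_bp"])
    n_matches = matches.groupby("gene_a").size() if len(matches) else pd.Series(dtype=int)
    counts = pd.DataFrame(
        {
            "gene_id": sorted(exons_a),
            "n_matches": [int(n_matches.get(g, 0)) for g in sorted(exons_a)],
        }
    )
    return matches, counts
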