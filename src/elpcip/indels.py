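"""Strand-aware classification of InDels relative to gene models.

An InDel is *genic* when its interval overlaps the gene span (overlap takes
precedence), *upstream* when it lies entirely on the gene's 5' side within
``upstream_window`` bp, and *downstream* symmetrically on the 3' side.
Distances are reported as 1-based coordinate differences between the gene
boundary and the nearest InDel base (0 for genic overlaps).  Genes carrying
any classified InDel are intersected with the CIP gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import GeneModel, IndelInterval

__all__ = [
    "IndelClassification",
    "classify_indel",
    "genes_with_indels",
    "intersect_cip_indel",
    "region_percentages",
]

REGIONS = ("upstream", "genic", "downstream")


@dataclass(frozen=True)
class IndelClassification:
    gene_id: str
    indel: IndelInterval
    region: str
    distance: int  # bp from gene boundary to nearest indel base; 0 if genic


def classify_indel(
    gene: GeneModel, indel: IndelInterval, upstream_window: int = 1000
) -> IndelClassification | None:
    """Classify one InDel relative to one gene, or None if out of range."""
    if upstream_window < 0:
        raise ValueError("upstream_window must be >= 0")
    if gene.chrom != indel.chrom:
        return None
    # genic: any overlap with the gene span (0-based half-open intervals)
    if indel.start < gene.end and indel.end > gene.start:
        return IndelClassification(gene.gene_id, indel, "genic", 0)
    if indel.end <= gene.start:
        # indel entirely on the low-coordinate side
        distance = gene.start - indel.end + 1
        region = "upstream" if gene.strand == "+" else "downstream"
    else:
        distance = indel.start - gene.end + 1
        region = "downstream" if gene.strand == "+" else "upstream"
    if distance > upstream_window:
        return None
    return IndelClassification(gene.gene_id, indel, region, distance)


def genes_with_indels(
    genes: Iterable[GeneModel],
    indels: Iterable[IndelInterval],
    upstream_window: int = 1000,
) -> pd.DataFrame:
    """Per-gene region flags: has_upstream, has_genic, has_downstream.

    Every gene appears in the output; an InDel near two genes contributes
    one classification per gene.
    """
    genes = list(genes)
    indels = list(indels)
    by_chrom: dict[str, list[IndelInterval]] = {}
    for v in indels:
        by_chrom.setdefault(v.chrom, []).append(v)
    rows = []
    for g in genes:
        flags = dict.fromkeys(REGIONS, False)
        for v in by_chrom.get(g.chrom, []):
            c = classify_indel(g, v, upstream_window)
            if c is not None:
                flags[c.region] = True
        rows.append(
            {
                "gene_id": g.gene_id,
                "has_upstream": flags["upstream"],
                "has_genic": flags["genic"],
                "has_downstream": flags["downstream"],
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "has_upstream", "has_genic", "has_downstream"])


def intersect_cip_indel(
    cip_genes: Iterable[str], flags: pd.DataFrame
) -> list[str]:
    """CIP genes that also carry at least one classified InDel."""
    flagged = flags.loc[
        flags[["has_upstream", "has_genic", "has_downstream"]].any(axis=1), "gene_id"
    ]
    flagged_set = set(flagged)
    return [g for g in cip_genes if g in flagged_set]


def region_percentages(flags: pd.DataFrame, genes: Iterable[str] | None = None) -> dict[str, float]:
    """Percentage of (optionally subset) genes with an InDel per region.

    Percentages are over all genes in the selection and can sum past 100
    because one gene may carry InDels in several regions.
    """
    sub = flags if genes is None else flags[flags["gene_id"].isin(set(genes))]
    n = len(sub)
    if n == 0:
        raise ValueError("no genes selected")
    return {
        "upstream": 100.0 * sub["has_upstream"].sum() / n,
        "genic": 100.0 * sub["has_genic"].sum() / n,
        "downstream": 100.0 * sub["has_downstream"].sum() / n,
    }
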