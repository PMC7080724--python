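"""Exon / intron / intergenic assignment and per-group distribution tables.

A variant is exonic if it falls inside any annotated exon, intronic if it
falls in a gene span but no exon, and intergenic otherwise (precedence
exon > intron). When several genes overlap the position, the reported
gene_id is the lexicographically smallest and the full overlap list is
retained for recurrence counting.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import UnknownContigError
from .genome import GeneModel, GenomeAssets, Interval  # re-exported module surface
from .variants import VariantCall

REGIONS: Tuple[str, ...] = ("exonic", "intronic", "intergenic")

__all__ = [
    "GenomeAssets",
    "GeneModel",
    "Interval",
    "RegionCall",
    "REGIONS",
    "assign_region",
    "assign_regions",
    "tabulate_distribution",
    "region_calls_to_frame",
]


@dataclass(frozen=True)
class RegionCall:
    """A variant with its genomic-region assignment."""

    variant: VariantCall
    region: str
    gene_id: Optional[str]
    overlapping_gene_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.region == "intergenic"):
            raise ValueError("gene_id must be None exactly for intergenic calls")


def assign_region(variant: VariantCall, assets: GenomeAssets) -> RegionCall:
    """Assign one variant; 1-based pos p is inside [s, e) iff s <= p-1 < e."""
    if variant.contig not in assets.contigs:
        raise UnknownContigError(f"contig {variant.contig!r} not in genome assets")
    pos0 = variant.pos - 1
    exon_genes = assets.exon_genes_at(variant.contig, pos0)
    if exon_genes:
        return RegionCall(variant, "exonic", exon_genes[0], tuple(exon_genes))
    span_genes = assets.span_genes_at(variant.contig, pos0)
    if span_genes:
        return RegionCall(variant, "intronic", span_genes[0], tuple(span_genes))
    return RegionCall(variant, "intergenic", None, ())


def assign_regions(
    variants: Iterable[VariantCall], assets: GenomeAssets
) -> List[RegionCall]:
    return [assign_region(v, assets) for v in variants]


def tabulate_distribution(
    region_calls: Sequence[RegionCall],
    groups: Optional[Mapping[str, str]] = None,
    expected_groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Counts and fractions per region per group.

    ``groups`` maps sample_id -> group label (e.g. condition); by default
    each sample is its own group. ``expected_groups`` forces rows for groups
    with no calls (zero counts, NaN fractions). Fractions sum to 1 per
    non-empty group.
    """
    tallies: Dict[str, Dict[str, int]] = {}
    if expected_groups is not None:
        for g in expected_groups:
            tallies[g] = {r: 0 for r in REGIONS}
    for rc in region_calls:
        sid = rc.variant.sample_id
        group = groups[sid] if groups is not None else sid
        tallies.setdefault(group, {r: 0 for r in REGIONS})[rc.region] += 1
    rows = []
    for group in tallies:
        total = sum(tallies[group].values())
        for region in REGIONS:
            n = tallies[group][region]
            rows.append(
                {
                    "group": group,
                    "region": region,
                    "count": n,
                    "fraction": n / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["group", "region", "count", "fraction"])


def region_calls_to_frame(region_calls: Sequence[RegionCall]) -> pd.DataFrame:
    """Per-variant annotated table for TSV export."""
    return pd.DataFrame(
        [
            {
                "contig": rc.variant.contig,
                "pos": rc.variant.pos,
                "ref": rc.variant.ref,
                "alt": rc.variant.alt,
                "sample_id": rc.variant.sample_id,
                "region": rc.region,
                "gene_id": rc.gene_id if rc.gene_id is not None else "",
                "overlapping_gene_ids": ",".join(rc.overlapping_gene_ids),
            }
            for rc in region_calls
        ],
        columns=[
            "contig", "pos", "ref", "alt", "sample_id",
            "region", "gene_id", "overlapping_gene_ids",
        ],
    )
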