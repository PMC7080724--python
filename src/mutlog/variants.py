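"""Per-sample VCF reading, control subtraction and the somatic filters.

The analysis-ready SNV set is produced in three steps: read biallelic SNVs
from a sample's VCF, remove anything also seen in the non-treated control
(or in a known-polymorphism list), then apply the depth / alt-read / VAF
thresholds. Matching for subtraction is allele-aware — (contig, pos, ref,
alt) — so two different substitutions at one site are never conflated.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
import pysam

from .errors import VcfParseError
from .genome import BASES

logger = logging.getLogger(__name__)

Site = Tuple[str, int, str, str]  # contig, 1-based pos, ref, alt


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV with per-sample depth and alt-read support."""

    contig: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    depth: int
    alt_count: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single ACGT bases: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}] "
                f"at {self.contig}:{self.pos}"
            )

    @property
    def vaf(self) -> float:
        """Mutational frequency: alt reads / total depth (0 when depth is 0)."""
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def site(self) -> Site:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterPolicy:
    """Somatic-filter thresholds.

    A call is kept iff depth >= min_depth AND alt_count >= min_alt AND
    alt_count/depth > min_vaf_exclusive (strictly greater). Defaults encode
    the standard post-calling rules: coverage of at least 6 reads, at least
    2 non-reference reads, and mutational frequency above 10%.
    """

    min_depth: int = 6
    min_alt: int = 2
    min_vaf_exclusive: float = 0.10

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.min_alt < 0:
            raise ValueError("min_depth must be >=1 and min_alt >=0")
        if not (0 <= self.min_vaf_exclusive < 1):
            raise ValueError("min_vaf_exclusive must lie in [0, 1)")


def read_sample_vcf(path: str, sample_id: Optional[str] = None) -> List[VariantCall]:
    """Read biallelic SNV records with DP and AD from a single-sample VCF.

    Multiallelic or non-SNV records are skipped (count logged). A retained
    record missing DP or AD raises :class:`VcfParseError`.
    """
    calls: List[VariantCall] = []
    n_skipped = 0
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise VcfParseError(f"{path}: no sample column in header")
        sample = samples[0]
        label = sample_id if sample_id is not None else sample
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in BASES
                or alts[0] not in BASES
            ):
                n_skipped += 1
                continue
            fmt = rec.samples[sample]
            dp = fmt.get("DP")
            ad = fmt.get("AD")
            if dp is None or ad is None or len(ad) < 2 or ad[0] is None:
                raise VcfParseError(
                    f"{path}: record {rec.contig}:{rec.pos} lacks DP/AD"
                )
            calls.append(
                VariantCall(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alts[0],
                    depth=int(dp),
                    alt_count=int(ad[1]),
                    sample_id=label,
                )
            )
    if n_skipped:
        logger.info("%s: skipped %d multiallelic/non-SNV records", path, n_skipped)
    return calls


def subtract_control(
    treated: Sequence[VariantCall],
    control: Sequence[VariantCall],
    known_sites: Optional[Iterable[Site]] = None,
) -> List[VariantCall]:
    """Drop treated calls whose (contig, pos, ref, alt) occurs in the control
    catalog or a known-polymorphism site list. Order-stable."""
    blocked: Set[Site] = {v.site for v in control}
    if known_sites is not None:
        blocked.update(tuple(s) for s in known_sites)
    return [v for v in treated if v.site not in blocked]


def apply_filters(
    variants: Sequence[VariantCall], policy: FilterPolicy = FilterPolicy()
) -> Tuple[List[VariantCall], List[Tuple[VariantCall, str]]]:
    """Partition calls into (kept, rejected-with-reason).

    Each rejection carries the first failing rule, checked in the order
    depth, alt, vaf. depth=0 is rejected under the depth rule (no division).
    """
    kept: List[VariantCall] = []
    rejected: List[Tuple[VariantCall, str]] = []
    for v in variants:
        if v.depth < policy.min_depth:
            rejected.append((v, "depth"))
        elif v.alt_count < policy.min_alt:
            rejected.append((v, "alt"))
        elif v.vaf <= policy.min_vaf_exclusive:
            rejected.append((v, "vaf"))
        else:
            kept.append(v)
    return kept, rejected


def read_known_sites(path: str) -> List[Site]:
    """Known-polymorphism sites from a VCF or a 4-column TSV (contig,pos,ref,alt)."""
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        return [v.site for v in read_sample_vcf(path)] if _vcf_has_samples(path) else _vcf_sites(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [
        (str(r[0]), int(r[1]), str(r[2]), str(r[3])) for r in df.itertuples(index=False)
    ]


def _vcf_has_samples(path: str) -> bool:
    with pysam.VariantFile(path) as vcf:
        return len(vcf.header.samples) > 0


def _vcf_sites(path: str) -> List[Site]:
    sites: List[Site] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if rec.ref and len(rec.ref) == 1 and len(alt) == 1:
                    sites.append((rec.contig, rec.pos, rec.ref, alt))
    return sites


def variants_to_frame(variants: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": v.contig,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "depth": v.depth,
                "alt_count": v.alt_count,
                "vaf": v.vaf,
                "sample_id": v.sample_id,
            }
            for v in variants
        ],
        columns=["contig", "pos", "ref", "alt", "depth", "alt_count", "vaf", "sample_id"],
    )


def write_variants_tsv(variants: Sequence[VariantCall], path: str) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def write_rejections_tsv(
    rejections: Sequence[Tuple[VariantCall, str]], path: str
) -> None:
    df = variants_to_frame([v for v, _ in rejections])
    df["reason"] = [r for _, r in rejections]
    df.to_csv(path, sep="\t", index=False)
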