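"""Shared genomic containers: contigs, target intervals and gene models.

All internal coordinates are 0-based half-open (BED-native). VCF's 1-based
positions are converted at the I/O boundary, nowhere else.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import pyfaidx
from intervaltree import IntervalTree

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = ("A", "C", "G", "T")


def complement(base: str) -> str:
    return COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene span with sorted, non-overlapping exon blocks."""

    gene_id: str
    contig: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or e <= s:
                raise ValueError(
                    f"exons of {self.gene_id} must be sorted, non-overlapping "
                    f"and inside the gene span"
                )
            prev_end = e

    @property
    def span(self) -> Interval:
        return Interval(self.contig, self.start, self.end, self.gene_id)


@dataclass
class GenomeAssets:
    """Reference sequences + capture targets + gene models.

    The shared coordinate universe for simulation, spectra, region assignment
    and coverage normalization. Interval trees for exon / gene-span lookup are
    built lazily and cached.
    """

    contigs: Dict[str, str]
    target_intervals: List[Interval]
    genes: List[GeneModel]
    _exon_trees: Optional[Dict[str, IntervalTree]] = field(
        default=None, init=False, repr=False, compare=False
    )
    _gene_trees: Optional[Dict[str, IntervalTree]] = field(
        default=None, init=False, repr=False, compare=False
    )
    _site_index: Optional[dict] = field(
        default=None, init=False, repr=False, compare=False
    )

    def validate(self) -> None:
        for iv in self.target_intervals:
            if iv.contig not in self.contigs or iv.end > len(self.contigs[iv.contig]):
                raise ValueError(f"target interval {iv} outside contig bounds")
        for g in self.genes:
            if g.contig not in self.contigs or g.end > len(self.contigs[g.contig]):
                raise ValueError(f"gene {g.gene_id} outside contig bounds")

    def sequence(self, contig: str, start: int, end: int) -> str:
        return self.contigs[contig][start:end]

    def base(self, contig: str, pos0: int) -> str:
        return self.contigs[contig][pos0]

    def _build_trees(self) -> None:
        exon_trees: Dict[str, IntervalTree] = {c: IntervalTree() for c in self.contigs}
        gene_trees: Dict[str, IntervalTree] = {c: IntervalTree() for c in self.contigs}
        for g in self.genes:
            gene_trees[g.contig].addi(g.start, g.end, g.gene_id)
            for s, e in g.exons:
                exon_trees[g.contig].addi(s, e, g.gene_id)
        self._exon_trees = exon_trees
        self._gene_trees = gene_trees

    def exon_genes_at(self, contig: str, pos0: int) -> List[str]:
        """gene_ids whose exons overlap pos0, sorted lexicographically."""
        if self._exon_trees is None:
            self._build_trees()
        return sorted({iv.data for iv in self._exon_trees[contig][pos0]})

    def span_genes_at(self, contig: str, pos0: int) -> List[str]:
        """gene_ids whose spans overlap pos0, sorted lexicographically."""
        if self._gene_trees is None:
            self._build_trees()
        return sorted({iv.data for iv in self._gene_trees[contig][pos0]})


# ---------------------------------------------------------------------------
# plain-text serialization of the toy assets
# ---------------------------------------------------------------------------

FASTA_WIDTH = 60


def write_fasta(contigs: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    fa = pyfaidx.Fasta(path, rebuild=True)
    try:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    finally:
        fa.close()


def write_bed3(intervals: Sequence[Interval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed3(path: str) -> List[Interval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 and str(row[3]) != "." else ""
        out.append(Interval(str(row[0]), int(row[1]), int(row[2]), name))
    return out


def write_bed12(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, e in g.exons) + ","
            fh.write(
                f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            genes.append(GeneModel(f[3], f[0], start, int(f[2]), exons, f[5]))
    return genes


def load_assets(fasta_path: str, targets_path: str, genes_path: str) -> GenomeAssets:
    assets = GenomeAssets(
        contigs=read_fasta(fasta_path),
        target_intervals=read_bed3(targets_path),
        genes=read_bed12(genes_path),
    )
    assets.validate()
    return assets


def save_assets(assets: GenomeAssets, out_dir: str) -> Dict[str, str]:
    """Write FASTA/BED3/BED12 under out_dir; returns relative paths."""
    paths = {
        "reference_fasta": "genome.fa",
        "targets_bed": "targets.bed",
        "genes_bed": "genes.bed",
    }
    write_fasta(assets.contigs, os.path.join(out_dir, paths["reference_fasta"]))
    write_bed3(assets.target_intervals, os.path.join(out_dir, paths["targets_bed"]))
    write_bed12(assets.genes, os.path.join(out_dir, paths["genes_bed"]))
    return paths
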