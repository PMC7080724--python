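"""Strand-collapsed substitution classes and trinucleotide-context spectra.

Every SNV is reported with a pyrimidine (C or T) reference base: a purine-
reference call is reverse-complemented, so complementary events such as C>T
and G>A share one of six classes (COSMIC/SBS convention). The flanking 5'
and 3' reference bases give 16 contexts per class; the full matrix is the
familiar 6 x 16 = 96-bin spectrum. Variants at contig edges (an N flank)
are counted as unclassified, never dropped silently.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import pandas as pd

from .errors import DataIntegrityError
from .genome import BASES, COMPLEMENT, GenomeAssets, reverse_complement
from .variants import VariantCall

#: The six pyrimidine-reference substitution classes, in canonical order.
SUBSTITUTION_CLASSES: Tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Alias labels in reference:complement pair notation, keyed by class.
PAIR_NOTATION: Dict[str, str] = {
    "C>A": "C:G>A:T",
    "C>G": "C:G>G:C",
    "C>T": "C:G>T:A",
    "T>A": "A:T>T:A",
    "T>C": "A:T>G:C",
    "T>G": "A:T>C:G",
}

_PURINES = frozenset("AG")


def classify_substitution(ref: str, alt: str) -> str:
    """Map an ordered base substitution onto its strand-collapsed class.

    The 12 ordered substitutions map 12 -> 6; each class receives exactly
    two ordered pairs (the pyrimidine-reference pair and its complement).
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be one of ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if ref in _PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


class TrinucleotideContext(NamedTuple):
    """Flanking bases around a pyrimidine-collapsed center, read 5'->3'."""

    five_prime: str
    center: str
    three_prime: str

    @property
    def trinuc(self) -> str:
        return self.five_prime + self.center + self.three_prime

    @property
    def classifiable(self) -> bool:
        return self.five_prime in BASES and self.three_prime in BASES


def contexts_for_class(substitution_class: str) -> List[str]:
    """The 16 flanking combinations for a class, lexicographic order."""
    center = substitution_class[0]
    return [f + center + t for f in BASES for t in BASES]


def extract_context(
    assets: GenomeAssets, contig: str, pos: int, ref: str, alt: str
) -> TrinucleotideContext:
    """Pull the collapsed trinucleotide context at a 1-based position.

    The reference base at ``pos`` must equal ``ref``; a mismatch is a
    data-integrity error. If ``ref`` is a purine the whole triplet is
    reverse-complemented so the context reads 5'->3' around the pyrimidine.
    Positions at contig edges yield N flanks (``classifiable`` is False).
    """
    seq = assets.contigs[contig]
    pos0 = pos - 1
    actual = seq[pos0]
    if actual != ref:
        raise DataIntegrityError(
            f"reference mismatch at {contig}:{pos}: expected {ref}, found {actual}"
        )
    five = seq[pos0 - 1] if pos0 >= 1 else "N"
    three = seq[pos0 + 1] if pos0 + 1 < len(seq) else "N"
    if ref in _PURINES:
        triplet = reverse_complement(five + ref + three)
        return TrinucleotideContext(triplet[0], triplet[1], triplet[2])
    return TrinucleotideContext(five, ref, three)


@dataclass
class SpectrumMatrix:
    """Counts over (6 substitution classes x 16 flanking contexts).

    ``sum of counts + n_unclassified`` always equals the number of input
    SNVs; unclassified covers N-flank / contig-edge variants.
    """

    sample_id: str
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    n_unclassified: int = 0

    def total(self) -> int:
        return sum(self.counts.values())

    def class_total(self, substitution_class: str) -> int:
        return sum(
            n for (cls, _), n in self.counts.items() if cls == substitution_class
        )

    def class_fractions(self) -> pd.Series:
        tot = self.total()
        vals = {c: self.class_total(c) / tot if tot else float("nan")
                for c in SUBSTITUTION_CLASSES}
        return pd.Series(vals, name=self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        """96-row long format: class, context, count, fraction, sample_id."""
        tot = self.total()
        rows = []
        for cls in SUBSTITUTION_CLASSES:
            for ctx in contexts_for_class(cls):
                n = self.counts.get((cls, ctx), 0)
                rows.append(
                    {
                        "class": cls,
                        "context": ctx,
                        "count": n,
                        "fraction": n / tot if tot else float("nan"),
                        "sample_id": self.sample_id,
                    }
                )
        return pd.DataFrame(rows)

    def class_matrix(self) -> pd.DataFrame:
        """6 x 16 wide view: rows are classes, columns are 5'_3' flank pairs."""
        data = {}
        for cls in SUBSTITUTION_CLASSES:
            data[cls] = [
                self.counts.get((cls, ctx), 0) for ctx in contexts_for_class(cls)
            ]
        cols = [f"{f}_{t}" for f in BASES for t in BASES]
        return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def build_spectrum(
    variants: Iterable[VariantCall], assets: GenomeAssets, sample_id: Optional[str] = None
) -> SpectrumMatrix:
    """Bin each variant into exactly one (class, context) cell or unclassified."""
    variants = list(variants)
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else ""
    spec = SpectrumMatrix(sample_id=sample_id)
    for v in variants:
        cls = classify_substitution(v.ref, v.alt)
        ctx = extract_context(assets, v.contig, v.pos, v.ref, v.alt)
        if not ctx.classifiable:
            spec.n_unclassified += 1
            continue
        key = (cls, ctx.trinuc)
        spec.counts[key] = spec.counts.get(key, 0) + 1
    return spec


class CpGFraction(NamedTuple):
    value: float
    defined: bool


def cpg_fraction(spectrum: SpectrumMatrix) -> CpGFraction:
    """Fraction of C>T events whose collapsed context has a 3' G (NCG).

    The collapsed context covers both strands by construction, so this is
    the fraction of C>T transitions at CpG dinucleotides. Undefined (NaN,
    defined=False) when the spectrum holds no C>T counts.
    """
    total = spectrum.class_total("C>T")
    if total == 0:
        return CpGFraction(math.nan, False)
    at_cpg = sum(
        n
        for (cls, ctx), n in spectrum.counts.items()
        if cls == "C>T" and ctx[2] == "G"
    )
    return CpGFraction(at_cpg / total, True)


def rank_contexts(
    spectrum: SpectrumMatrix, substitution_class: str, top_k: int
) -> List[Tuple[str, int, float]]:
    """Top contexts of a class by count, ties broken lexicographically.

    Returns (context, count, fraction-of-class) triples.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if substitution_class not in SUBSTITUTION_CLASSES:
        raise ValueError(f"unknown substitution class {substitution_class!r}")
    total = spectrum.class_total(substitution_class)
    entries = [
        (ctx, spectrum.counts.get((substitution_class, ctx), 0))
        for ctx in contexts_for_class(substitution_class)
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return [
        (ctx, n, n / total if total else float("nan"))
        for ctx, n in entries[:top_k]
    ]


def write_spectrum_tsv(spectra: Iterable[SpectrumMatrix], path: str) -> None:
    pd.concat([s.to_frame() for s in spectra], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
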