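"""Self-contained synthetic UV/TSA mutagenesis study with known ground truth.

Generates a toy multi-contig genome, non-overlapping gene models with
exon/intron structure, exome target intervals, per-interval coverage, and
condition-labeled somatic SNV catalogs drawn from parameterized
substitution-class / trinucleotide-context / region distributions. The
default condition panel mirrors an acute-UVB keratinocyte design: four UVB
doses, two harvest times, HDAC-inhibitor (TSA) pretreatment with and
without UVB, and two donors — 14 experimental conditions plus one
non-treated control.

Truth bookkeeping (every variant's generating class, context, region and
gene) is written to a sidecar JSON, never into the VCFs, so the analysis
pipeline cannot read its own answers.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingContextError
from .genome import (
    BASES,
    COMPLEMENT,
    GeneModel,
    GenomeAssets,
    Interval,
    reverse_complement,
    save_assets,
)
from .normalization import CoverageMatrix
from .spectrum import SUBSTITUTION_CLASSES, contexts_for_class
from .variants import FilterPolicy, Site, VariantCall

_PURINES = frozenset("AG")
_REGIONS = ("exonic", "intronic", "intergenic")

# Default UV-like substitution-class probabilities, in canonical class order
# (C>A, C>G, C>T, T>A, T>C, T>G): C>T dominant (~30%), T>C second (~25%).
UV_CLASS_PROBS: Tuple[float, ...] = (0.10, 0.15, 0.30, 0.10, 0.25, 0.10)

# Context weights relative to 1 for the unnamed contexts. ACG/TCG at weight 5
# put exactly half the C>T mass on NCG (CpG) contexts: (2*5+2)/(2*5+14) = 0.5.
UV_CONTEXT_BIAS: Dict[Tuple[str, str], float] = {
    ("C>T", "ACG"): 5.0,
    ("C>T", "TCG"): 5.0,
    ("T>C", "ATT"): 6.0,
    ("T>C", "ATG"): 6.0,
}

# exon / intron / intergenic placement probabilities
UV_REGION_BIAS: Tuple[float, float, float] = (0.10, 0.20, 0.70)
TSA_REGION_BIAS: Tuple[float, float, float] = (0.30, 0.40, 0.30)


@dataclass(frozen=True)
class DepthModel:
    """Per-variant depth and alt-read simulation.

    depth ~ uniform integers on [depth_min, depth_max]; VAF ~ uniform on
    [vaf_min, vaf_max]; alt reads ~ Binomial(depth, VAF). The default range
    straddles the somatic-filter thresholds so boundary behavior is
    exercised by construction.
    """

    depth_min: int = 20
    depth_max: int = 60
    vaf_min: float = 0.20
    vaf_max: float = 0.60

    def draw(self, rng: np.random.Generator) -> Tuple[int, int]:
        depth = int(rng.integers(self.depth_min, self.depth_max + 1))
        vaf = float(rng.uniform(self.vaf_min, self.vaf_max))
        alt = int(rng.binomial(depth, vaf))
        return depth, alt

    def draw_passing(
        self, rng: np.random.Generator, policy: FilterPolicy = FilterPolicy()
    ) -> Tuple[int, int]:
        """Redraw until the call clears the filter thresholds (bounded)."""
        for _ in range(1000):
            depth, alt = self.draw(rng)
            if (
                depth >= policy.min_depth
                and alt >= policy.min_alt
                and depth > 0
                and alt / depth > policy.min_vaf_exclusive
            ):
                return depth, alt
        raise ConfigurationError("depth model cannot produce filter-passing calls")


@dataclass
class ConditionSpec:
    """Generating parameters for one experimental condition's SNV catalog."""

    label: str
    n_variants: int = 250
    class_probs: Tuple[float, ...] = UV_CLASS_PROBS
    context_bias: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(UV_CONTEXT_BIAS)
    )
    region_bias: Tuple[float, float, float] = UV_REGION_BIAS
    depth: DepthModel = field(default_factory=DepthModel)
    donor: str = "D1"

    def __post_init__(self) -> None:
        if len(self.class_probs) != len(SUBSTITUTION_CLASSES):
            raise ConfigurationError("class_probs must have 6 entries")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ConfigurationError("class_probs must sum to 1")
        if abs(sum(self.region_bias) - 1.0) > 1e-9:
            raise ConfigurationError("region_bias must sum to 1")
        if any(w < 0 for w in self.context_bias.values()):
            raise ConfigurationError("context weights must be nonnegative")


def default_conditions() -> List[ConditionSpec]:
    """The 14-condition study design: UVB dose series (10-40 mJ/cm2), 4 h vs
    72 h harvests, TSA+UVB, and TSA alone (incl. a repeat treatment), across
    donors D1 and D2."""
    uv = dict(class_probs=UV_CLASS_PROBS, region_bias=UV_REGION_BIAS)
    tsa = dict(class_probs=UV_CLASS_PROBS, region_bias=TSA_REGION_BIAS)
    return [
        ConditionSpec("UVB10_72h_D1", n_variants=250, donor="D1", **uv),
        ConditionSpec("UVB20_72h_D1", n_variants=250, donor="D1", **uv),
        ConditionSpec("UVB30_72h_D1", n_variants=250, donor="D1", **uv),
        ConditionSpec("UVB40_72h_D1", n_variants=250, donor="D1", **uv),
        ConditionSpec("UVB30_4h_D1", n_variants=150, donor="D1", **uv),
        ConditionSpec("UVB10_72h_D2", n_variants=250, donor="D2", **uv),
        ConditionSpec("UVB20_72h_D2", n_variants=250, donor="D2", **uv),
        ConditionSpec("UVB30_72h_D2", n_variants=250, donor="D2", **uv),
        ConditionSpec("UVB30_4h_D2", n_variants=150, donor="D2", **uv),
        ConditionSpec("TSA_UVB30_D1", n_variants=180, donor="D1", **uv),
        ConditionSpec("TSA_UVB30_D2", n_variants=180, donor="D2", **uv),
        ConditionSpec("TSA_D1", n_variants=200, donor="D1", **tsa),
        ConditionSpec("TSA_D2", n_variants=200, donor="D2", **tsa),
        ConditionSpec("TSA2x_D2", n_variants=215, donor="D2", **tsa),
    ]


@dataclass
class SimulationConfig:
    """Knobs for the whole synthetic study."""

    seed: int = 0
    contig_lengths: Tuple[int, ...] = (60_000, 40_000)
    n_genes: int = 30
    exons_per_gene: int = 3
    exon_length: int = 150
    intron_length: int = 300
    n_target_intervals: int = 140
    target_flank: int = 20
    read_length: int = 100
    conditions: List[ConditionSpec] = field(default_factory=default_conditions)
    polymorphism_count: int = 30
    background_mutation_count: int = 20
    cpg_boost: float = 0.0  # fraction of positions seeded with a CG dinucleotide
    control_label: str = "Control"

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.contig_lengths):
            raise ConfigurationError("contig lengths must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")
        if self.gene_length * self.n_genes >= sum(self.contig_lengths):
            raise ConfigurationError(
                f"total gene footprint {self.gene_length * self.n_genes} bp does "
                f"not fit the {sum(self.contig_lengths)} bp genome"
            )
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("condition labels must be unique")

    @property
    def gene_length(self) -> int:
        return (
            self.exons_per_gene * self.exon_length
            + (self.exons_per_gene - 1) * self.intron_length
        )


@dataclass(frozen=True)
class SimulatedVariant:
    """A VariantCall plus its generating truth (class/context/region/gene)."""

    call: VariantCall
    substitution_class: str
    context: str
    region: str
    gene_id: Optional[str]
    origin: str = "somatic"  # somatic | shared | background


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> GenomeAssets:
    """Toy genome: i.i.d. ACGT contigs (optionally CpG-enriched),
    non-overlapping genes, and target intervals covering every exon plus
    flanks with extra intergenic background intervals.

    Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    contigs: Dict[str, str] = {}
    for i, length in enumerate(config.contig_lengths):
        arr = rng.integers(0, 4, size=length)
        seq = np.array(list("ACGT"))[arr]
        if config.cpg_boost > 0:
            n_sites = int(config.cpg_boost * length)
            sites = rng.integers(0, length - 1, size=n_sites)
            seq[sites] = "C"
            seq[sites + 1] = "G"
        contigs[f"chr{i + 1}"] = "".join(seq)

    gene_len = config.gene_length
    names = list(contigs)
    lengths = np.array([len(contigs[c]) for c in names], dtype=float)
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in names}
    genes: List[GeneModel] = []
    for gi in range(config.n_genes):
        ok = False
        for _ in range(500):
            ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
            contig = names[ci]
            limit = len(contigs[contig]) - gene_len - config.target_flank
            if limit <= config.target_flank:
                continue
            start = int(rng.integers(config.target_flank, limit))
            end = start + gene_len
            if all(end <= s or start >= e for s, e in placed[contig]):
                placed[contig].append((start, end))
                exons = tuple(
                    (
                        start + k * (config.exon_length + config.intron_length),
                        start + k * (config.exon_length + config.intron_length)
                        + config.exon_length,
                    )
                    for k in range(config.exons_per_gene)
                )
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneModel(f"gene{gi + 1:03d}", contig, start, end, exons, strand)
                )
                ok = True
                break
        if not ok:
            raise ConfigurationError(
                f"could not place gene {gi + 1}/{config.n_genes} of {gene_len} bp "
                "after 500 retries; genome too crowded (reduce n_genes or gene size)"
            )
    genes.sort(key=lambda g: (g.contig, g.start))

    targets: List[Interval] = []
    tid = 0
    for g in genes:
        for s, e in g.exons:
            tid += 1
            targets.append(
                Interval(
                    g.contig,
                    max(0, s - config.target_flank),
                    min(len(contigs[g.contig]), e + config.target_flank),
                    f"t{tid:04d}",
                )
            )
    # extra background intervals in gene-free space, up to the requested total
    n_extra = max(0, config.n_target_intervals - len(targets))
    tries = 0
    while n_extra > 0 and tries < 10_000:
        tries += 1
        ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
        contig = names[ci]
        limit = len(contigs[contig]) - config.exon_length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + config.exon_length
        if all(end <= s or start >= e for s, e in placed[contig]) and all(
            t.contig != contig or end <= t.start or start >= t.end for t in targets
        ):
            tid += 1
            targets.append(Interval(contig, start, end, f"t{tid:04d}"))
            n_extra -= 1

    assets = GenomeAssets(contigs=contigs, target_intervals=targets, genes=genes)
    assets.validate()
    return assets


# ---------------------------------------------------------------------------
# variant simulation
# ---------------------------------------------------------------------------

def _region_code_arrays(assets: GenomeAssets) -> Dict[str, np.ndarray]:
    """0 = intergenic, 1 = intronic, 2 = exonic, per contig position."""
    codes = {c: np.zeros(len(s), dtype=np.int8) for c, s in assets.contigs.items()}
    for g in assets.genes:
        codes[g.contig][g.start : g.end] = np.maximum(codes[g.contig][g.start : g.end], 1)
        for s, e in g.exons:
            codes[g.contig][s:e] = 2
    return codes


def _site_index(assets: GenomeAssets) -> Dict[Tuple[str, str], List[Tuple[str, int]]]:
    """(region, collapsed-trinucleotide) -> interior (contig, pos0) sites."""
    if assets._site_index is not None:
        return assets._site_index
    codes = _region_code_arrays(assets)
    index: Dict[Tuple[str, str], List[Tuple[str, int]]] = {}
    for contig, seq in assets.contigs.items():
        code = codes[contig]
        for pos0 in range(1, len(seq) - 1):
            tri = seq[pos0 - 1 : pos0 + 2]
            if tri[1] in _PURINES:
                tri = reverse_complement(tri)
            region = _REGIONS[2 - code[pos0]] if code[pos0] else "intergenic"
            index.setdefault((region, tri), []).append((contig, pos0))
    assets._site_index = index
    return index


def _class_alt(substitution_class: str, ref: str) -> str:
    """Alt base at a site given the collapsed class and the actual ref strand."""
    alt = substitution_class[2]
    return alt if ref in ("C", "T") else COMPLEMENT[alt]


def simulate_condition_variants(
    assets: GenomeAssets, spec: ConditionSpec, seed: int
) -> List[SimulatedVariant]:
    """Draw one condition's somatic SNV catalog.

    Class ~ class_probs; context ~ context_bias within the class (weight 1
    for unnamed contexts); region ~ region_bias; the site is then sampled
    uniformly among genome positions whose collapsed (region, context)
    matches, by lookup against the actual sequence. No duplicate
    (contig, pos) within the sample.
    """
    rng = np.random.default_rng(seed)
    index = _site_index(assets)
    used: set = set()
    out: List[SimulatedVariant] = []
    class_probs = np.asarray(spec.class_probs, dtype=float)
    region_probs = np.asarray(spec.region_bias, dtype=float)

    ctx_tables = {}
    for ci, cls in enumerate(SUBSTITUTION_CLASSES):
        ctxs = contexts_for_class(cls)
        w = np.array([spec.context_bias.get((cls, c), 1.0) for c in ctxs])
        if w.sum() <= 0:
            raise ConfigurationError(f"context weights for {cls} sum to zero")
        ctx_tables[cls] = (ctxs, w / w.sum())

    for _ in range(spec.n_variants):
        region = _REGIONS[int(rng.choice(3, p=region_probs))]
        cls = SUBSTITUTION_CLASSES[int(rng.choice(6, p=class_probs))]
        ctxs, probs = ctx_tables[cls]
        placed = False
        for _attempt in range(200):
            tri = ctxs[int(rng.choice(len(ctxs), p=probs))]
            sites = index.get((region, tri))
            if not sites:
                raise MissingContextError(
                    f"trinucleotide {tri} absent from {region} space of the genome"
                )
            contig, pos0 = sites[int(rng.integers(len(sites)))]
            if (contig, pos0) in used:
                continue
            used.add((contig, pos0))
            ref = assets.base(contig, pos0)
            alt = _class_alt(cls, ref)
            depth, alt_count = spec.depth.draw(rng)
            genes = assets.exon_genes_at(contig, pos0) or assets.span_genes_at(contig, pos0)
            out.append(
                SimulatedVariant(
                    call=VariantCall(
                        contig=contig,
                        pos=pos0 + 1,
                        ref=ref,
                        alt=alt,
                        depth=depth,
                        alt_count=alt_count,
                        sample_id=spec.label,
                    ),
                    substitution_class=cls,
                    context=tri,
                    region=region,
                    gene_id=genes[0] if genes else None,
                )
            )
            placed = True
            break
        if not placed:
            raise ConfigurationError(
                f"could not place a unique {cls} variant in {region} space "
                f"for condition {spec.label}"
            )
    return out


def simulate_polymorphisms_and_control(
    assets: GenomeAssets,
    config: SimulationConfig,
    seed: int,
    exclude_positions: Optional[Iterable[Tuple[str, int]]] = None,
) -> Tuple[List[Site], List[Site]]:
    """Shared (polymorphism) sites plus the control catalog.

    Shared sites appear in every condition's VCF and in the control; the
    control catalog additionally holds background-only mutations. Both are
    bare (contig, pos, ref, alt) sites — per-sample depths are drawn when
    the fixture is materialized. ``exclude_positions`` keeps shared sites
    off 0-based positions already occupied by condition-private variants.
    """
    rng = np.random.default_rng(seed)
    names = list(assets.contigs)
    taken: set = set(exclude_positions or ())

    def draw_sites(n: int) -> List[Site]:
        sites: List[Site] = []
        for _ in range(n):
            for _try in range(1000):
                contig = names[int(rng.integers(len(names)))]
                L = len(assets.contigs[contig])
                pos0 = int(rng.integers(1, L - 1))
                if (contig, pos0) in taken:
                    continue
                taken.add((contig, pos0))
                ref = assets.base(contig, pos0)
                alt = [b for b in BASES if b != ref][int(rng.integers(3))]
                sites.append((contig, pos0 + 1, ref, alt))
                break
            else:
                raise ConfigurationError("could not place shared/background site")
        return sites

    shared = draw_sites(config.polymorphism_count)
    background = draw_sites(config.background_mutation_count)
    return shared, shared + background


def simulate_interval_coverage(
    assets: GenomeAssets,
    config: SimulationConfig,
    per_sample_depth_scale: Mapping[str, float],
    seed: int,
    base_depth: float = 60.0,
    noise: bool = True,
) -> CoverageMatrix:
    """Per-interval read counts around a depth baseline scaled per sample.

    With noise, reads ~ Poisson(base_depth * scale * length / read_length);
    without, the expectation is used exactly (so proportional scales give
    exactly proportional coverage rows). Coverage follows the
    reads x read-length / interval-length formula.
    """
    rng = np.random.default_rng(seed)
    lengths = pd.Series(
        {iv.name: iv.length for iv in assets.target_intervals}, dtype=float
    )
    lam_base = base_depth * lengths / config.read_length
    rows = {}
    for sample, scale in per_sample_depth_scale.items():
        lam = lam_base * float(scale)
        reads = rng.poisson(lam.to_numpy()) if noise else lam.to_numpy()
        rows[sample] = reads * config.read_length / lengths.to_numpy()
    values = pd.DataFrame.from_dict(rows, orient="index", columns=lengths.index)
    return CoverageMatrix(values=values, interval_lengths=lengths)


def plant_gene_hits(
    assets: GenomeAssets,
    hits: Mapping[str, Iterable[str]],
    seed: int,
    policy: FilterPolicy = FilterPolicy(),
) -> Dict[str, List[SimulatedVariant]]:
    """Deterministically plant one filter-passing exonic SNV per requested
    (condition, gene). ``hits`` maps condition label -> gene_ids. Used to
    build fixtures with known recurrent / protected gene sets."""
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in assets.genes}
    depth_model = DepthModel(depth_min=40, depth_max=60, vaf_min=0.40, vaf_max=0.60)
    out: Dict[str, List[SimulatedVariant]] = {}
    for cond, gene_ids in hits.items():
        lst: List[SimulatedVariant] = []
        for gid in gene_ids:
            if gid not in by_id:
                raise ConfigurationError(f"unknown gene_id {gid!r} in planted hits")
            g = by_id[gid]
            s, e = g.exons[0]
            pos0 = int(rng.integers(s, e))
            ref = assets.base(g.contig, pos0)
            alt = [b for b in BASES if b != ref][int(rng.integers(3))]
            depth, alt_count = depth_model.draw_passing(rng, policy)
            tri = assets.sequence(g.contig, pos0 - 1, pos0 + 2)
            if tri[1] in _PURINES:
                tri = reverse_complement(tri)
            cls = f"{'C' if ref in 'CG' else 'T'}>{alt if ref in 'CT' else COMPLEMENT[alt]}"
            lst.append(
                SimulatedVariant(
                    call=VariantCall(g.contig, pos0 + 1, ref, alt, depth, alt_count, cond),
                    substitution_class=cls,
                    context=tri,
                    region="exonic",
                    gene_id=gid,
                )
            )
        out[cond] = lst
    return out


# ---------------------------------------------------------------------------
# whole-study orchestration + fixture writing
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    """Everything the pipeline consumes, plus the generating truth."""

    config: SimulationConfig
    assets: GenomeAssets
    condition_variants: Dict[str, List[SimulatedVariant]]
    shared_sites: List[Site]
    control_sites: List[Site]
    coverage: CoverageMatrix
    depth_scales: Dict[str, float]


def simulate_study(
    config: SimulationConfig,
    planted_hits: Optional[Mapping[str, Iterable[str]]] = None,
) -> StudyFixture:
    """Run the full generator: genome, per-condition catalogs, shared and
    control sites, and coverage. Child seeds are spawned deterministically
    from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    n_conditions = len(config.conditions)
    children = ss.generate_state(n_conditions + 3, dtype=np.uint32)
    assets = generate_genome(config)
    condition_variants: Dict[str, List[SimulatedVariant]] = {}
    for i, spec in enumerate(config.conditions):
        condition_variants[spec.label] = simulate_condition_variants(
            assets, spec, int(children[i])
        )
    if planted_hits:
        planted = plant_gene_hits(assets, planted_hits, int(children[n_conditions + 1]))
        for cond, lst in planted.items():
            if cond not in condition_variants:
                raise ConfigurationError(f"planted condition {cond!r} not in panel")
            taken = {(sv.call.contig, sv.call.pos) for sv in lst}
            kept = [
                sv
                for sv in condition_variants[cond]
                if (sv.call.contig, sv.call.pos) not in taken
            ]
            condition_variants[cond] = kept + lst
    occupied = {
        (sv.call.contig, sv.call.pos - 1)
        for lst in condition_variants.values()
        for sv in lst
    }
    shared, control = simulate_polymorphisms_and_control(
        assets, config, int(children[n_conditions]), exclude_positions=occupied
    )
    scale_rng = np.random.default_rng(int(children[n_conditions + 2]))
    sample_ids = [c.label for c in config.conditions] + [config.control_label]
    depth_scales = {s: float(scale_rng.uniform(0.5, 2.0)) for s in sample_ids}
    coverage = simulate_interval_coverage(
        assets, config, depth_scales, seed=int(children[n_conditions + 2])
    )
    return StudyFixture(
        config=config,
        assets=assets,
        condition_variants=condition_variants,
        shared_sites=shared,
        control_sites=control,
        coverage=coverage,
        depth_scales=depth_scales,
    )


def _write_vcf(
    path: str,
    sample_id: str,
    records: Sequence[Tuple[str, int, str, str, int, int]],
    contigs: Mapping[str, str],
) -> None:
    """Minimal single-sample VCF v4.2 with DP and AD FORMAT fields."""
    order = {c: i for i, c in enumerate(contigs)}
    records = sorted(records, key=lambda r: (order[r[0]], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mutlog-simulate\n")
        for name, seq in contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
        )
        for contig, pos, ref, alt, depth, alt_count in records:
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tDP:AD\t"
                f"{depth}:{depth - alt_count},{alt_count}\n"
            )


def write_fixture(fixture: StudyFixture, out_dir: str) -> Dict:
    """Write the complete plain-text fixture; returns the manifest dict.

    Emits genome.fa, targets.bed, genes.bed, one VCF per sample (conditions
    plus control), coverage.tsv, samples.tsv, truth.json and manifest.json.
    """
    os.makedirs(out_dir, exist_ok=True)
    config = fixture.config
    paths = save_assets(fixture.assets, out_dir)
    vcf_dir = "vcf"
    os.makedirs(os.path.join(out_dir, vcf_dir), exist_ok=True)

    # per-sample depth draws for shared/background sites
    rng = np.random.default_rng(
        int(np.random.SeedSequence(config.seed).generate_state(1, dtype=np.uint32)[0])
        ^ 0x5EED
    )
    depth_model = DepthModel()
    policy = FilterPolicy()

    truth: Dict = {
        "seed": config.seed,
        "shared_sites": [list(s) for s in fixture.shared_sites],
        "control_sites": [list(s) for s in fixture.control_sites],
        "samples": {},
    }
    vcf_paths: Dict[str, str] = {}
    sheet_rows = []
    donor_by_label = {c.label: c.donor for c in config.conditions}

    for spec in config.conditions:
        label = spec.label
        svs = fixture.condition_variants[label]
        records = [
            (sv.call.contig, sv.call.pos, sv.call.ref, sv.call.alt,
             sv.call.depth, sv.call.alt_count)
            for sv in svs
        ]
        private_pos = {(sv.call.contig, sv.call.pos) for sv in svs}
        for contig, pos, ref, alt in fixture.shared_sites:
            if (contig, pos) in private_pos:
                continue
            depth, alt_count = depth_model.draw_passing(rng, policy)
            records.append((contig, pos, ref, alt, depth, alt_count))
        rel = os.path.join(vcf_dir, f"{label}.vcf")
        _write_vcf(os.path.join(out_dir, rel), label, records, fixture.assets.contigs)
        vcf_paths[label] = rel
        truth["samples"][label] = {
            "condition": label,
            "donor": spec.donor,
            "role": "treated",
            "params": {
                "n_variants": spec.n_variants,
                "class_probs": list(spec.class_probs),
                "region_bias": list(spec.region_bias),
                "context_bias": {
                    f"{cls}|{ctx}": w for (cls, ctx), w in spec.context_bias.items()
                },
                "depth_scale": fixture.depth_scales[label],
            },
            "variants": [
                {
                    "contig": sv.call.contig,
                    "pos": sv.call.pos,
                    "ref": sv.call.ref,
                    "alt": sv.call.alt,
                    "depth": sv.call.depth,
                    "alt_count": sv.call.alt_count,
                    "class": sv.substitution_class,
                    "context": sv.context,
                    "region": sv.region,
                    "gene_id": sv.gene_id,
                    "origin": sv.origin,
                }
                for sv in svs
            ],
        }
        sheet_rows.append(
            {
                "sample_id": label,
                "condition_label": label,
                "donor": spec.donor,
                "role": "treated",
            }
        )

    control_records = []
    for contig, pos, ref, alt in fixture.control_sites:
        depth, alt_count = depth_model.draw_passing(rng, policy)
        control_records.append((contig, pos, ref, alt, depth, alt_count))
    control_rel = os.path.join(vcf_dir, f"{config.control_label}.vcf")
    _write_vcf(
        os.path.join(out_dir, control_rel),
        config.control_label,
        control_records,
        fixture.assets.contigs,
    )
    vcf_paths[config.control_label] = control_rel
    sheet_rows.append(
        {
            "sample_id": config.control_label,
            "condition_label": config.control_label,
            "donor": "NA",
            "role": "control",
        }
    )

    pd.DataFrame(sheet_rows).to_csv(
        os.path.join(out_dir, "samples.tsv"), sep="\t", index=False
    )
    fixture.coverage.to_tsv(os.path.join(out_dir, "coverage.tsv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)

    manifest = {
        "seed": config.seed,
        "read_length": config.read_length,
        "control_sample": config.control_label,
        "paths": {
            **paths,
            "sample_sheet": "samples.tsv",
            "coverage_tsv": "coverage.tsv",
            "truth": "truth.json",
            "vcf_dir": vcf_dir,
            "vcfs": vcf_paths,
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
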