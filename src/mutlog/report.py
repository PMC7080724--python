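"""End-to-end analysis run: subtraction -> filters -> spectra -> regions ->
recurrence -> normalization, with TSV outputs and a JSON run report."""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .errors import ConfigurationError
from .genome import load_assets
from .normalization import CoverageMatrix, normalize_counts, size_factors
from .recurrence import build_panel, protected_loci, recurrent_genes
from .regions import assign_regions, region_calls_to_frame, tabulate_distribution
from .spectrum import (
    SUBSTITUTION_CLASSES,
    build_spectrum,
    cpg_fraction,
    rank_contexts,
    write_spectrum_tsv,
)
from .variants import (
    FilterPolicy,
    apply_filters,
    read_known_sites,
    read_sample_vcf,
    subtract_control,
    write_rejections_tsv,
    write_variants_tsv,
)


@dataclass
class RunConfig:
    """Paths and parameters for one analysis run."""

    reference_fasta: str
    targets_bed: str
    genes_bed: str
    vcf_dir: str
    sample_sheet: str
    coverage_tsv: Optional[str] = None
    known_sites: Optional[str] = None
    filters: FilterPolicy = field(default_factory=FilterPolicy)
    min_conditions: int = 3
    exonic_only: bool = False
    protection_pairs: List[Tuple[str, str]] = field(default_factory=list)
    out_dir: str = "mutlog_out"

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        d = dict(d)
        filt = d.pop("filters", {}) or {}
        pairs = [tuple(p) for p in d.pop("protection_pairs", [])]
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(filters=FilterPolicy(**filt), protection_pairs=pairs, **d)

    def to_dict(self) -> Dict:
        return {
            "reference_fasta": self.reference_fasta,
            "targets_bed": self.targets_bed,
            "genes_bed": self.genes_bed,
            "vcf_dir": self.vcf_dir,
            "sample_sheet": self.sample_sheet,
            "coverage_tsv": self.coverage_tsv,
            "known_sites": self.known_sites,
            "filters": {
                "min_depth": self.filters.min_depth,
                "min_alt": self.filters.min_alt,
                "min_vaf_exclusive": self.filters.min_vaf_exclusive,
            },
            "min_conditions": self.min_conditions,
            "exonic_only": self.exonic_only,
            "protection_pairs": [list(p) for p in self.protection_pairs],
            "out_dir": self.out_dir,
        }

    def validate_paths(self) -> None:
        for label, p in (
            ("reference_fasta", self.reference_fasta),
            ("targets_bed", self.targets_bed),
            ("genes_bed", self.genes_bed),
            ("vcf_dir", self.vcf_dir),
            ("sample_sheet", self.sample_sheet),
        ):
            if not os.path.exists(p):
                raise ConfigurationError(f"{label} path does not exist: {p}")


def run_analyze(config: RunConfig) -> Dict:
    """Execute every stage and write TSVs plus report.json to out_dir.

    Returns the report dict. Deterministic given identical inputs.
    """
    config.validate_paths()
    os.makedirs(config.out_dir, exist_ok=True)
    assets = load_assets(config.reference_fasta, config.targets_bed, config.genes_bed)
    sheet = pd.read_csv(config.sample_sheet, sep="\t", dtype=str)
    required = {"sample_id", "condition_label", "role"}
    if not required.issubset(sheet.columns):
        raise ConfigurationError(f"sample sheet must have columns {sorted(required)}")

    treated = sheet[sheet["role"] == "treated"]
    controls = sheet[sheet["role"] == "control"]
    sample_to_condition = dict(zip(treated["sample_id"], treated["condition_label"]))

    def vcf_path(sample_id: str) -> str:
        p = os.path.join(config.vcf_dir, f"{sample_id}.vcf")
        if not os.path.exists(p):
            raise ConfigurationError(f"missing VCF for sample {sample_id!r}: {p}")
        return p

    control_calls = []
    for sid in controls["sample_id"]:
        control_calls.extend(read_sample_vcf(vcf_path(sid), sample_id=sid))
    known = read_known_sites(config.known_sites) if config.known_sites else None

    per_sample: Dict[str, Dict] = {}
    kept_all = []
    rejected_all = []
    spectra = []
    for sid in treated["sample_id"]:
        parsed = read_sample_vcf(vcf_path(sid), sample_id=sid)
        somatic = subtract_control(parsed, control_calls, known)
        kept, rejected = apply_filters(somatic, config.filters)
        stage_counts = {
            "parsed": len(parsed),
            "after_subtraction": len(somatic),
            "after_filters": len(kept),
        }
        if not (
            stage_counts["parsed"]
            >= stage_counts["after_subtraction"]
            >= stage_counts["after_filters"]
        ):
            raise AssertionError(f"stage counts not monotone for {sid}: {stage_counts}")
        spec = build_spectrum(kept, assets, sample_id=sid)
        cpg = cpg_fraction(spec)
        per_sample[sid] = {
            "condition": sample_to_condition[sid],
            "stage_counts": stage_counts,
            "rejections": {
                r: sum(1 for _, reason in rejected if reason == r)
                for r in ("depth", "alt", "vaf")
            },
            "class_fractions": {
                k: (None if pd.isna(v) else round(float(v), 6))
                for k, v in spec.class_fractions().items()
            },
            "cpg_fraction_c_to_t": None if not cpg.defined else round(cpg.value, 6),
            "top_c_to_t_contexts": [c for c, _, _ in rank_contexts(spec, "C>T", 2)],
            "top_t_to_c_contexts": [c for c, _, _ in rank_contexts(spec, "T>C", 2)],
        }
        kept_all.extend(kept)
        rejected_all.extend(rejected)
        spectra.append(spec)

    write_variants_tsv(kept_all, os.path.join(config.out_dir, "filtered_variants.tsv"))
    write_rejections_tsv(rejected_all, os.path.join(config.out_dir, "rejections.tsv"))
    write_spectrum_tsv(spectra, os.path.join(config.out_dir, "spectrum.tsv"))

    region_calls = assign_regions(kept_all, assets)
    region_calls_to_frame(region_calls).to_csv(
        os.path.join(config.out_dir, "annotated_variants.tsv"), sep="\t", index=False
    )
    dist = tabulate_distribution(
        region_calls,
        groups=sample_to_condition,
        expected_groups=list(dict.fromkeys(treated["condition_label"])),
    )
    dist.to_csv(os.path.join(config.out_dir, "region_distribution.tsv"),
                sep="\t", index=False)

    panel = build_panel(
        region_calls,
        sample_to_condition,
        conditions=list(dict.fromkeys(treated["condition_label"])),
    )
    table = recurrent_genes(panel, config.min_conditions, config.exonic_only)
    table.indicators.to_csv(
        os.path.join(config.out_dir, "recurrence_matrix.tsv"), sep="\t"
    )
    protection = {
        f"{uv} vs {tsa}": protected_loci(panel, uv, tsa)
        for uv, tsa in config.protection_pairs
    }

    normalization = None
    if config.coverage_tsv:
        cov = CoverageMatrix.read_tsv(config.coverage_tsv)
        sf = size_factors(cov)
        sf.to_tsv(os.path.join(config.out_dir, "size_factors.tsv"))
        counts = pd.Series(
            {sid: per_sample[sid]["stage_counts"]["after_filters"]
             for sid in per_sample},
            dtype=float,
        )
        norm = normalize_counts(counts, sf)
        norm.to_csv(os.path.join(config.out_dir, "normalized_counts.tsv"), sep="\t")
        normalization = {
            "n_intervals_used": sf.n_intervals_used,
            "size_factors": {s: round(float(v), 6) for s, v in sf.factors.items()},
            "normalized_counts": {
                s: round(float(v), 6) for s, v in norm["normalized_count"].items()
            },
        }

    cfg_dict = config.to_dict()
    report = {
        "tool": "mutlog",
        "version": __version__,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "samples": per_sample,
        "region_distribution": dist.to_dict(orient="records"),
        "recurrent_genes": {
            g: int(table.selected.loc[g, "n_conditions"]) for g in table.genes
        },
        "protected_loci": protection,
        "normalization": normalization,
    }
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
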