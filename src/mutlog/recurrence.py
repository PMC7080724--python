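"""Cross-condition recurrence and HDAC-inhibitor protection analysis.

A gene is "mutated in condition c" when at least one filtered SNV from any
sample of c is assigned to it. Genes hit in at least ``min_conditions``
conditions are the recurrent (hotspot) set. A gene is "protected" when it
carries exonic mutations after UVB alone but none after TSA pretreatment
followed by UVB — the chromatin-decondensation protection readout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set

import pandas as pd

from .errors import ConfigurationError
from .regions import RegionCall


@dataclass
class ConditionPanel:
    """Per-condition mutated-gene sets (any-genic and exonic-only views)."""

    conditions: List[str]
    genic: Dict[str, Set[str]] = field(default_factory=dict)
    exonic: Dict[str, Set[str]] = field(default_factory=dict)

    def gene_universe(self) -> List[str]:
        out: Set[str] = set()
        for s in self.genic.values():
            out |= s
        return sorted(out)


@dataclass
class RecurrenceTable:
    """Boolean gene x condition indicator matrix plus the selected rows."""

    indicators: pd.DataFrame  # full matrix, for heat-map export
    selected: pd.DataFrame    # genes meeting the threshold, with counts

    @property
    def genes(self) -> List[str]:
        return list(self.selected.index)


def build_panel(
    region_calls: Sequence[RegionCall],
    sample_to_condition: Mapping[str, str],
    conditions: Sequence[str] | None = None,
) -> ConditionPanel:
    """Fold annotated calls into per-condition gene sets.

    A variant overlapping two genes counts toward both. A sample missing
    from the mapping is a configuration error (fail fast).
    """
    labels = (
        list(dict.fromkeys(conditions))
        if conditions is not None
        else list(dict.fromkeys(sample_to_condition.values()))
    )
    panel = ConditionPanel(
        conditions=labels,
        genic={c: set() for c in labels},
        exonic={c: set() for c in labels},
    )
    for rc in region_calls:
        sid = rc.variant.sample_id
        if sid not in sample_to_condition:
            raise ConfigurationError(f"sample {sid!r} has no condition mapping")
        cond = sample_to_condition[sid]
        if cond not in panel.genic:
            raise ConfigurationError(f"condition {cond!r} not in panel")
        if rc.region == "intergenic":
            continue
        genes = rc.overlapping_gene_ids or ((rc.gene_id,) if rc.gene_id else ())
        panel.genic[cond].update(genes)
        if rc.region == "exonic":
            panel.exonic[cond].update(genes)
    return panel


def recurrent_genes(
    panel: ConditionPanel, min_conditions: int = 3, exonic_only: bool = False
) -> RecurrenceTable:
    """Genes mutated in at least ``min_conditions`` conditions.

    Sorted by recurrence count descending, then gene_id. Raising the
    threshold above the number of conditions yields an empty table with a
    warning, not an error.
    """
    sets = panel.exonic if exonic_only else panel.genic
    genes = sorted({g for s in sets.values() for g in s})
    indicators = pd.DataFrame(
        [[g in sets[c] for c in panel.conditions] for g in genes],
        index=pd.Index(genes, name="gene_id"),
        columns=panel.conditions,
        dtype=bool,
    )
    if min_conditions > len(panel.conditions):
        warnings.warn(
            f"min_conditions={min_conditions} exceeds the {len(panel.conditions)} "
            "available conditions; no gene can qualify",
            stacklevel=2,
        )
    counts = indicators.sum(axis=1)
    sel = indicators[counts >= min_conditions].copy()
    sel["n_conditions"] = counts[sel.index]
    sel = sel.sort_values(
        ["n_conditions", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return RecurrenceTable(indicators=indicators, selected=sel)


def protected_loci(
    panel: ConditionPanel, uv_condition: str, tsa_uv_condition: str
) -> List[str]:
    """Genes with exonic hits under UVB alone and no hits under TSA+UVB.

    Swap the arguments for the symmetric (TSA-only) gene list.
    """
    for label in (uv_condition, tsa_uv_condition):
        if label not in panel.genic:
            raise KeyError(f"condition {label!r} not in panel")
    return sorted(panel.exonic[uv_condition] - panel.genic[tsa_uv_condition])
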