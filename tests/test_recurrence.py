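"""Cross-condition recurrence counting and TSA-protection detection."""
import pytest

from mutlog import (
    GeneModel,
    GenomeAssets,
    VariantCall,
    assign_regions,
    build_panel,
    protected_loci,
    recurrent_genes,
)
from mutlog.errors import ConfigurationError
from mutlog.recurrence import ConditionPanel


def _panel(genic, exonic=None, conditions=None):
    conditions = conditions or sorted(genic)
    return ConditionPanel(
        conditions=list(conditions),
        genic={c: set(genic.get(c, set())) for c in conditions},
        exonic={c: set((exonic or genic).get(c, set())) for c in conditions},
    )


@pytest.fixture
def linear_assets():
    """Three single-exon genes on one contig for panel-building tests."""
    seq = "ACGT" * 100
    genes = [
        GeneModel(f"g{i}", "chr1", 50 * i, 50 * i + 40,
                  exons=((50 * i, 50 * i + 20),))
        for i in range(1, 4)
    ]
    return GenomeAssets({"chr1": seq}, [], genes)


def _call(pos, sample):
    return VariantCall("chr1", pos, "C", "T", 30, 10, sample)


class TestBuildPanel:
    def test_indicators_follow_gene_hits(self, linear_assets):
        # g1 exon [50,70): exonic at pos0 55; g2 intron [120,140): pos0 125
        calls = assign_regions(
            [_call(56, "s1"), _call(126, "s3")], linear_assets
        )
        panel = build_panel(calls, {"s1": "c1", "s2": "c2", "s3": "c3"})
        assert panel.genic["c1"] == {"g1"}
        assert panel.exonic["c1"] == {"g1"}
        assert panel.genic["c3"] == {"g2"}
        assert panel.exonic["c3"] == set()  # intronic hit only
        assert panel.genic["c2"] == set()

    def test_intergenic_variants_never_enter_the_panel(self, linear_assets):
        calls = assign_regions([_call(10, "s1")], linear_assets)
        panel = build_panel(calls, {"s1": "c1"})
        assert panel.gene_universe() == []

    def test_unmapped_sample_is_a_configuration_error(self, linear_assets):
        calls = assign_regions([_call(56, "ghost")], linear_assets)
        with pytest.raises(ConfigurationError, match="ghost"):
            build_panel(calls, {"s1": "c1"})


class TestRecurrentGenes:
    def test_threshold_inclusion_and_exclusion(self):
        panel = _panel(
            {f"c{i}": set() for i in range(1, 15)}
            | {"c1": {"gA", "gB"}, "c2": {"gA", "gB"}, "c3": {"gA"}},
            conditions=[f"c{i}" for i in range(1, 15)],
        )
        table = recurrent_genes(panel, min_conditions=3)
        assert table.genes == ["gA"]  # mutated in 3 of 14
        assert "gB" not in table.genes  # only 2 of 14
        assert table.indicators.loc["gB"].sum() == 2

    def test_threshold_one_returns_every_mutated_gene(self):
        panel = _panel({"c1": {"gA"}, "c2": {"gB"}})
        assert recurrent_genes(panel, 1).genes == ["gA", "gB"]

    def test_sorting_by_count_then_gene_id(self):
        panel = _panel({"c1": {"gB", "gC"}, "c2": {"gB", "gA"}, "c3": {"gA"}})
        assert recurrent_genes(panel, 1).genes == ["gA", "gB", "gC"]

    def test_monotone_in_threshold(self):
        panel = _panel(
            {f"c{i}": ({"gA"} if i <= 9 else set()) | ({"gB"} if i % 2 else set())
             for i in range(1, 15)}
        )
        previous = None
        for k in range(1, 15):
            genes = set(recurrent_genes(panel, k).genes)
            if previous is not None:
                assert genes <= previous
            previous = genes

    def test_threshold_above_panel_size_warns_and_returns_empty(self):
        panel = _panel({"c1": {"gA"}})
        with pytest.warns(UserWarning):
            table = recurrent_genes(panel, min_conditions=5)
        assert table.genes == []

    def test_exonic_only_mode_drops_intronic_only_genes(self):
        panel = _panel(
            genic={"c1": {"gA", "gB"}, "c2": {"gA", "gB"}},
            exonic={"c1": {"gA"}, "c2": {"gA"}},
        )
        assert recurrent_genes(panel, 2, exonic_only=True).genes == ["gA"]
        assert recurrent_genes(panel, 2).genes == ["gA", "gB"]


class TestProtectedLoci:
    def test_uv_only_gene_listed_shared_gene_not(self):
        panel = _panel(
            genic={"U": {"gX", "gY"}, "TU": {"gY"}},
            exonic={"U": {"gX", "gY"}, "TU": {"gY"}},
        )
        assert protected_loci(panel, "U", "TU") == ["gX"]

    def test_intronic_hit_under_tsa_still_counts_as_mutated(self):
        panel = _panel(
            genic={"U": {"gX"}, "TU": {"gX"}},
            exonic={"U": {"gX"}, "TU": set()},
        )
        assert protected_loci(panel, "U", "TU") == []

    def test_disjoint_from_tsa_mutated_genes(self):
        panel = _panel(
            genic={"U": {"gA", "gB", "gC"}, "TU": {"gB"}},
            exonic={"U": {"gA", "gB"}, "TU": {"gB"}},
        )
        prot = set(protected_loci(panel, "U", "TU"))
        assert prot == {"gA"}
        assert prot.isdisjoint(panel.genic["TU"])

    def test_unknown_condition_label(self):
        panel = _panel({"U": {"gA"}})
        with pytest.raises(KeyError):
            protected_loci(panel, "U", "nope")


class TestPlantedRecovery:
    def test_planted_recurrent_and_protected_sets_recovered_exactly(self):
        """Fixture with controlled exonic hits: recurrence and protection
        recover the planted gene sets exactly."""
        from mutlog import SimulationConfig, ConditionSpec, simulate_study
        from mutlog.simulate import UV_CLASS_PROBS

        # background conditions place nothing in exons
        specs = [
            ConditionSpec(f"c{i}", n_variants=30, class_probs=UV_CLASS_PROBS,
                          region_bias=(0.0, 0.3, 0.7))
            for i in range(1, 15)
        ]
        planted = {
            "c1": ["gene001", "gene002", "gene003"],
            "c2": ["gene001", "gene002", "gene003"],
            "c3": ["gene001", "gene002", "gene003"],
            "c4": ["gene004"],
        }
        cfg = SimulationConfig(seed=23, conditions=specs, n_genes=20,
                               polymorphism_count=0, background_mutation_count=0)
        study = simulate_study(cfg, planted_hits=planted)
        calls = [sv.call for lst in study.condition_variants.values() for sv in lst]
        rcs = assign_regions(calls, study.assets)
        panel = build_panel(rcs, {f"c{i}": f"c{i}" for i in range(1, 15)})
        table = recurrent_genes(panel, min_conditions=3, exonic_only=True)
        assert table.genes == ["gene001", "gene002", "gene003"]
        # protection: genes hit in c1's exons but untouched (genic) in c4
        prot = protected_loci(panel, "c1", "c4")
        expected = {"gene001", "gene002", "gene003"} - panel.genic["c4"]
        assert set(prot) == expected
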