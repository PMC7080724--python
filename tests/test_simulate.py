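"""The synthetic study generator: construction guarantees, determinism and
convergence of empirical frequencies to the generating distributions."""
import filecmp
import json

import numpy as np
import pytest

from mutlog import (
    ConditionSpec,
    SimulationConfig,
    build_spectrum,
    classify_substitution,
    generate_genome,
    simulate_condition_variants,
    simulate_interval_coverage,
    simulate_polymorphisms_and_control,
    simulate_study,
    write_fixture,
)
from mutlog.errors import ConfigurationError, MissingContextError
from mutlog.simulate import UV_CLASS_PROBS


def _small_config(**kw):
    defaults = dict(
        seed=3,
        contig_lengths=(12_000,),
        n_genes=5,
        conditions=[ConditionSpec("condA", n_variants=40)],
        polymorphism_count=10,
        background_mutation_count=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateGenome:
    def test_construction_guarantees(self):
        assets = generate_genome(_small_config(seed=1, contig_lengths=(10_000,)))
        assert list(assets.contigs) == ["chr1"]
        assert len(assets.genes) == 5
        spans = sorted((g.start, g.end) for g in assets.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping
        # every exon lies inside some target interval
        for g in assets.genes:
            for s, e in g.exons:
                assert any(
                    t.contig == g.contig and t.start <= s and e <= t.end
                    for t in assets.target_intervals
                )

    def test_impossible_gene_load_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            _small_config(contig_lengths=(4_000,), n_genes=5)

    def test_crowded_placement_fails_with_named_constraint(self):
        cfg = _small_config(contig_lengths=(5_500,), n_genes=5)
        with pytest.raises(ConfigurationError, match="place gene"):
            generate_genome(cfg)

    def test_cpg_boost_raises_cpg_dinucleotide_density(self):
        plain = generate_genome(_small_config(seed=9))
        boosted = generate_genome(_small_config(seed=9, cpg_boost=0.05))
        assert boosted.contigs["chr1"].count("CG") > plain.contigs["chr1"].count("CG")


class TestDeterminism:
    def test_same_seed_gives_byte_identical_fixture(self, tmp_path):
        cfg = _small_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = write_fixture(simulate_study(cfg), str(d1))
        m2 = write_fixture(simulate_study(_small_config()), str(d2))
        assert m1 == m2
        for rel in ["genome.fa", "targets.bed", "genes.bed", "coverage.tsv",
                    "samples.tsv", "truth.json", "vcf/condA.vcf", "vcf/Control.vcf"]:
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel

    def test_different_seeds_differ(self):
        g1 = generate_genome(_small_config(seed=1))
        g2 = generate_genome(_small_config(seed=2))
        assert g1.contigs["chr1"] != g2.contigs["chr1"]


class TestConditionVariants:
    def test_degenerate_class_distribution(self, assets):
        spec = ConditionSpec("x", n_variants=60,
                             class_probs=(1.0, 0, 0, 0, 0, 0), context_bias={})
        svs = simulate_condition_variants(assets, spec, seed=4)
        assert all(
            classify_substitution(sv.call.ref, sv.call.alt) == "C>A" for sv in svs
        )

    def test_degenerate_context_distribution(self, assets):
        bias = {("C>T", "ACG"): 1.0} | {
            ("C>T", c): 0.0
            for c in [f + "C" + t for f in "ACGT" for t in "ACGT"] if c != "ACG"
        }
        spec = ConditionSpec("x", n_variants=50,
                             class_probs=(0, 0, 1.0, 0, 0, 0), context_bias=bias)
        svs = simulate_condition_variants(assets, spec, seed=4)
        assert {sv.context for sv in svs} == {"ACG"}

    def test_no_duplicate_positions_within_sample(self, study):
        for label, svs in study.condition_variants.items():
            pos = [(sv.call.contig, sv.call.pos) for sv in svs]
            assert len(pos) == len(set(pos)), label

    def test_empirical_class_frequencies_within_binomial_bounds(self, assets):
        probs = (0.10, 0.15, 0.30, 0.10, 0.25, 0.10)
        n = 2000
        spec = ConditionSpec("big", n_variants=n, class_probs=probs)
        svs = simulate_condition_variants(assets, spec, seed=12)
        from mutlog import SUBSTITUTION_CLASSES

        for cls, p in zip(SUBSTITUTION_CLASSES, probs):
            freq = sum(sv.substitution_class == cls for sv in svs) / n
            bound = 3 * np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < bound, (cls, freq, p)

    def test_missing_context_is_reported_by_name(self):
        # a genome without any G cannot host an ACG context
        cfg = _small_config(seed=6)
        assets = generate_genome(cfg)
        assets.contigs["chr1"] = assets.contigs["chr1"].replace("G", "A")
        assets._site_index = None
        spec = ConditionSpec(
            "x", n_variants=5, class_probs=(0, 0, 1.0, 0, 0, 0),
            context_bias={("C>T", c): (1.0 if c == "ACG" else 0.0)
                          for c in [f + "C" + t for f in "ACGT" for t in "ACGT"]},
        )
        with pytest.raises(MissingContextError, match="ACG"):
            simulate_condition_variants(assets, spec, seed=1)


class TestPolymorphismsAndCoverage:
    def test_shared_site_counts(self, assets):
        cfg = _small_config(polymorphism_count=50, background_mutation_count=7)
        shared, control = simulate_polymorphisms_and_control(assets, cfg, seed=8)
        assert len(shared) == 50
        assert len(control) == 57
        assert set(shared) <= set(control)

    def test_zero_counts_give_empty_control(self, assets):
        cfg = _small_config(polymorphism_count=0, background_mutation_count=0)
        shared, control = simulate_polymorphisms_and_control(assets, cfg, seed=8)
        assert shared == [] and control == []

    def test_shared_sites_present_in_every_sample_vcf(self, fixture_dir):
        out, manifest = fixture_dir
        truth = json.loads((out / "truth.json").read_text())
        shared = {tuple(s) for s in truth["shared_sites"]}
        assert len(shared) > 0
        for label, rel in manifest["paths"]["vcfs"].items():
            body = (out / rel).read_text()
            sites = set()
            for line in body.splitlines():
                if line.startswith("#"):
                    continue
                f = line.split("\t")
                sites.add((f[0], int(f[1]), f[3], f[4]))
            assert shared <= sites, label

    def test_zero_noise_coverage_rows_exactly_proportional(self, assets, study_config):
        cov = simulate_interval_coverage(
            assets, study_config, {"A": 1.0, "B": 4.0}, seed=1, noise=False
        )
        assert np.allclose(cov.values.loc["B"], 4.0 * cov.values.loc["A"])
        cov_same = simulate_interval_coverage(
            assets, study_config, {"A": 1.0, "B": 1.0}, seed=1, noise=False
        )
        assert np.allclose(cov_same.values.loc["A"], cov_same.values.loc["B"])

    def test_noisy_coverage_ratio_near_scale(self, assets, study_config):
        cov = simulate_interval_coverage(
            assets, study_config, {"A": 1.0, "B": 4.0}, seed=2, noise=True
        )
        ratios = (cov.values.loc["B"] / cov.values.loc["A"]).to_numpy()
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 4.0) < 3 * se + 0.2


class TestFixtureRoundTrip:
    def test_vcf_counts_match_truth_plus_shared(self, fixture_dir):
        from mutlog import read_sample_vcf

        out, manifest = fixture_dir
        truth = json.loads((out / "truth.json").read_text())
        label = "TSA_D2"
        calls = read_sample_vcf(str(out / manifest["paths"]["vcfs"][label]))
        n_truth = len(truth["samples"][label]["variants"])
        assert len(calls) == n_truth + len(truth["shared_sites"])

    def test_truth_classification_matches_spectrum_module(self, fixture_dir):
        """Cross-module oracle: the truth file's class/context for every
        variant equals what the spectrum classifier derives from the
        emitted FASTA."""
        from mutlog import VariantCall, extract_context
        from mutlog.genome import load_assets

        out, manifest = fixture_dir
        p = manifest["paths"]
        assets = load_assets(
            str(out / p["reference_fasta"]),
            str(out / p["targets_bed"]),
            str(out / p["genes_bed"]),
        )
        truth = json.loads((out / "truth.json").read_text())
        for sample in truth["samples"].values():
            for t in sample["variants"]:
                assert classify_substitution(t["ref"], t["alt"]) == t["class"]
                ctx = extract_context(assets, t["contig"], t["pos"], t["ref"], t["alt"])
                assert ctx.trinuc == t["context"]

    def test_manifest_records_config_seed(self, fixture_dir, study_config):
        _, manifest = fixture_dir
        assert manifest["seed"] == study_config.seed
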