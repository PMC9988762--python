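"""Synthetic-data generator: determinism, planted-signal soundness,
count-model behaviour, BH properties, fixture bundle round-trips."""

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from peakrank.errors import ConfigError, DataError, PlacementError
from peakrank.genemodel import GeneModel
from peakrank.intervals import GenomicInterval, consensus_sites, read_bed, site_name
from peakrank.simulate import (
    SimulationConfig,
    benjamini_hochberg,
    generate_de_table,
    generate_gene_model,
    generate_peak_replicates,
    plant_ground_truth,
    simulate_site_counts,
    simulate_study,
    write_fixture_bundle,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": -1},
            {"replicate_dropout_rate": 1.5},
            {"nb_dispersion": 0.0},
            {"nb_dispersion": -1.0},
            {"chrom_sizes": {}},
            {"chrom_sizes": {"c": 0}},
            {"n_planted_targets": 900, "n_planted_decoys": 200},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs).validate()


class TestGeneModel:
    def test_zero_genes_gives_empty_model(self):
        cfg = SimulationConfig(n_genes=0, n_planted_targets=0, n_planted_decoys=0)
        assert len(generate_gene_model(cfg)) == 0

    def test_containment_and_nonoverlap(self):
        cfg = SimulationConfig(
            n_genes=100, chrom_sizes={"chr1": 10_000_000},
            n_planted_targets=0, n_planted_decoys=0, seed=1,
        )
        model = generate_gene_model(cfg)
        assert len(model) == 100
        genes = sorted(model, key=lambda g: g.tx_start)
        for g in genes:
            assert 0 <= g.tx_start < g.tx_end <= 10_000_000
            assert g.tx_start <= g.tss < g.tx_end
        for a, b in zip(genes, genes[1:]):  # non-overlap on any strand
            assert a.tx_end <= b.tx_start

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=50, n_planted_targets=0, n_planted_decoys=0, seed=3)
        a = generate_gene_model(cfg).to_frame()
        b = generate_gene_model(cfg).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_placement_failure_on_tiny_genome(self):
        cfg = SimulationConfig(
            n_genes=100, chrom_sizes={"c": 100_000},
            n_planted_targets=0, n_planted_decoys=0,
        )
        with pytest.raises(PlacementError):
            generate_gene_model(cfg)


class TestPeaks:
    def test_noise_free_limit_identical_replicates(self, small_config):
        cfg = replace(small_config, peak_jitter_sd=0.0, replicate_dropout_rate=0.0)
        model = generate_gene_model(cfg)
        truth = plant_ground_truth(model, cfg)
        sets = generate_peak_replicates(model, truth, cfg)
        for group in cfg.groups:
            members = [ps for ps in sets if ps.group == group]
            keys = [[iv.key() for iv in ps.intervals] for ps in members]
            assert all(k == keys[0] for k in keys)

    def test_planted_sites_group_exclusive(self, small_config):
        cfg = replace(small_config, peak_jitter_sd=0.0, replicate_dropout_rate=0.0)
        model = generate_gene_model(cfg)
        truth = plant_ground_truth(model, cfg)
        sets = generate_peak_replicates(model, truth, cfg)
        til = [ps for ps in sets if ps.group == "TIL"]
        tnil = [ps for ps in sets if ps.group == "TNIL"]
        for iv in truth.planted_gained_sites:
            assert all(any(iv.key() == p.key() for p in ps.intervals) for ps in til)
            assert not any(any(iv.key() == p.key() for p in ps.intervals) for ps in tnil)
        for iv in truth.planted_lost_sites:
            assert all(any(iv.key() == p.key() for p in ps.intervals) for ps in tnil)
            assert not any(any(iv.key() == p.key() for p in ps.intervals) for ps in til)

    def test_full_dropout_leaves_only_planted(self, small_config):
        cfg = replace(small_config, replicate_dropout_rate=1.0, peak_jitter_sd=0.0)
        model = generate_gene_model(cfg)
        truth = plant_ground_truth(model, cfg)
        sets = generate_peak_replicates(model, truth, cfg)
        planted_keys = {
            iv.key() for iv in truth.planted_gained_sites + truth.planted_lost_sites
        }
        for ps in sets:
            assert {iv.key() for iv in ps.intervals} <= planted_keys

    def test_consensus_recovers_planted_site_in_one_group_only(self, small_config):
        """A planted gained site survives the TIL consensus and is absent
        from the TNIL consensus (the downstream oracle for planting)."""
        model = generate_gene_model(small_config)
        truth = plant_ground_truth(model, small_config)
        sets = generate_peak_replicates(model, truth, small_config)
        cons = {
            g: consensus_sites([ps for ps in sets if ps.group == g])
            for g in small_config.groups
        }
        for iv in truth.planted_gained_sites:
            assert any(iv.overlaps(s) for s in cons["TIL"].sites)
            assert not any(iv.overlaps(s) for s in cons["TNIL"].sites)


class TestCounts:
    def test_determinism(self, small_config):
        model = generate_gene_model(small_config)
        truth = plant_ground_truth(model, small_config)
        sites = [GenomicInterval("chrA", i * 2000, i * 2000 + 400) for i in range(1, 50)]
        a = simulate_site_counts(sites, truth, small_config)
        b = simulate_site_counts(sites, truth, small_config)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_planted_group_mean_ratio(self, small_config):
        """Monte-Carlo: 10000 replicates of a planted gained site have
        empirical TIL/TNIL mean ratio 2^log2fc within 5%."""
        cfg = replace(small_config, site_log2fc_planted=2.0)
        planted = GenomicInterval("chrA", 1_000_000, 1_000_400)
        truth = plant_ground_truth(generate_gene_model(replace(cfg, n_planted_targets=0, n_planted_decoys=0)), cfg)
        truth.planted_gained_sites.append(planted)
        sites = [
            GenomicInterval(planted.chrom, planted.start, planted.end, name=f"rep{i}")
            for i in range(10_000)
        ]
        cm = simulate_site_counts(sites, truth, cfg)
        til = cm.counts[[s for s in cm.counts if s.startswith("TIL")]].values.mean()
        tnil = cm.counts[[s for s in cm.counts if s.startswith("TNIL")]].values.mean()
        assert til / tnil == pytest.approx(4.0, rel=0.05)

    def test_small_dispersion_approaches_poisson(self, small_config):
        cfg = replace(small_config, nb_dispersion=1e-8, n_planted_targets=0,
                      n_planted_decoys=0, background_log_sd=0.0)
        truth = plant_ground_truth(generate_gene_model(cfg), cfg)
        sites = [GenomicInterval("chrA", i * 1000, i * 1000 + 400, name=f"s{i}")
                 for i in range(1, 3000)]
        cm = simulate_site_counts(sites, truth, cfg)
        values = cm.counts.values.ravel()
        # Poisson(100): mean 100, variance 100
        assert values.mean() == pytest.approx(100.0, rel=0.02)
        assert values.var() == pytest.approx(100.0, rel=0.1)

    def test_empty_sites_rejected(self, small_config):
        truth = plant_ground_truth(generate_gene_model(small_config), small_config)
        with pytest.raises(DataError):
            simulate_site_counts([], truth, small_config)


class TestDETable:
    def test_bh_hand_computed_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.8])
        assert list(adj) == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_bh_monotone_in_raw_p_rank(self, rng):
        p = rng.random(200)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_planted_targets_signed_and_significant(self, small_config):
        model = generate_gene_model(small_config)
        truth = plant_ground_truth(model, small_config)
        de = generate_de_table(model, truth, small_config).set_index("gene_id")
        for g in truth.planted_target_genes | truth.planted_decoy_genes:
            sign = 1 if truth.gene_expression_direction[g] == "Up" else -1
            assert de.loc[g, "log2FoldChange"] == sign * small_config.gene_log2fc_planted
            assert de.loc[g, "padj"] < 0.05

    def test_null_fdr_controlled(self):
        """With no planted genes, the BH-significant fraction stays at or
        below the nominal level (simulation over 50 replicates)."""
        fracs = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_genes=1000, n_planted_targets=0, n_planted_decoys=0, seed=seed
            )
            model = generate_gene_model(cfg)
            truth = plant_ground_truth(model, cfg)
            de = generate_de_table(model, truth, cfg)
            fracs.append(float((de["padj"] < 0.05).mean()))
        assert np.mean(fracs) <= 0.05


class TestBundle:
    def test_roundtrip_and_manifest(self, tmp_path, small_config):
        study = simulate_study(small_config)
        manifest = write_fixture_bundle(tmp_path, study)
        # every written file appears in the manifest exactly once
        files = sorted(p.name for p in tmp_path.iterdir())
        assert sorted(manifest) == files
        # BED round trip through the interval reader
        for ps in study.peak_sets:
            back = read_bed(tmp_path / f"peaks_{ps.sample_id}.bed", group=ps.group)
            assert [iv.key() for iv in back.intervals] == [iv.key() for iv in ps.intervals]
        # gene model and tables round trip
        model_back = GeneModel.from_tsv(tmp_path / "gene_model.tsv")
        assert model_back.to_frame().equals(study.model.to_frame())
        de_back = pd.read_csv(tmp_path / "de_table.tsv", sep="\t")
        assert list(de_back["gene_id"]) == list(study.de_table["gene_id"])

    def test_empty_peak_set_writes_valid_empty_bed(self, tmp_path, small_config):
        cfg = replace(
            small_config, n_background_peaks=0, n_planted_targets=0, n_planted_decoys=0,
        )
        model = generate_gene_model(cfg)
        truth = plant_ground_truth(model, cfg)
        sets = generate_peak_replicates(model, truth, cfg)
        assert all(len(ps) == 0 for ps in sets)
        from peakrank.intervals import write_bed

        write_bed(sets[0].intervals, tmp_path / "empty.bed")
        assert (tmp_path / "empty.bed").read_text() == ""
        assert len(read_bed(tmp_path / "empty.bed")) == 0

    def test_bundle_byte_identical_across_runs(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture_bundle(d1, simulate_study(small_config))
        write_fixture_bundle(d2, simulate_study(small_config))
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p1.read_bytes() == p2.read_bytes()

    def test_ground_truth_json_roundtrip(self, tmp_path, small_config):
        from peakrank.simulate import GroundTruth

        truth = plant_ground_truth(generate_gene_model(small_config), small_config)
        truth.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.planted_target_genes == truth.planted_target_genes
        assert back.planted_decoy_genes == truth.planted_decoy_genes
        assert [iv.key() for iv in back.planted_gained_sites] == [
            iv.key() for iv in truth.planted_gained_sites
        ]
        assert back.planted_histone_directions == truth.planted_histone_directions
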