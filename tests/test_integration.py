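"""RP scoring, rank aggregation, site-to-gene assignment, and the two- and
three-way integrations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import rp_direct

from peakrank.errors import DataError, ValidationError
from peakrank.genemodel import GeneModel, GeneRecord
from peakrank.integration import (
    aggregate_ranks,
    assign_sites_to_genes,
    de_score_table,
    gene_directions,
    integrate_de_with_pgr,
    rank_genes,
    regulatory_potential,
    rp_table,
    stratified_de_ranks,
    three_way_integration,
)
from peakrank.intervals import GenomicInterval


def _gene(gene_id="g1", chrom="c", tss=100_000, strand="+", span=10_000):
    start = tss if strand == "+" else tss - span + 1
    end = start + span
    return GeneRecord(
        gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
        tx_start=start, tx_end=end, exon_starts=(start,), exon_ends=(end,),
    )


def _peak(chrom, center, width=200, name=None):
    return GenomicInterval(chrom, center - width // 2, center + width // 2, name=name)


class TestRegulatoryPotential:
    def test_peak_at_tss_scores_one(self):
        g = _gene()
        rp = regulatory_potential(g, [_peak("c", g.tss)])
        assert rp.score == 1.0 and rp.k == 1

    def test_two_peaks_at_half_decay_score_one(self):
        g = _gene()
        peaks = [_peak("c", g.tss - 1000), _peak("c", g.tss + 1000)]
        rp = regulatory_potential(g, peaks, d0=1000)
        assert rp.score == pytest.approx(1.0, rel=1e-12)

    def test_additivity_over_concatenated_peak_lists(self, rng):
        g = _gene()
        peaks1 = [_peak("c", g.tss + int(d)) for d in rng.integers(-8000, 8000, size=5)]
        peaks2 = [_peak("c", g.tss + int(d)) for d in rng.integers(-8000, 8000, size=7)]
        s1 = regulatory_potential(g, peaks1).score
        s2 = regulatory_potential(g, peaks2).score
        s12 = regulatory_potential(g, peaks1 + peaks2).score
        assert s12 == pytest.approx(s1 + s2, rel=1e-12)

    def test_moving_a_peak_by_d0_halves_its_term(self):
        g = _gene(tss=500_000)
        near = regulatory_potential(g, [_peak("c", g.tss + 2000)], d0=1000).score
        far = regulatory_potential(g, [_peak("c", g.tss + 3000)], d0=1000).score
        assert far == pytest.approx(near / 2, rel=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        g = _gene(tss=500_000)
        for _ in range(20):
            peaks = [
                _peak("c", int(rng.integers(300_000, 700_000))) for _ in range(10)
            ]
            got = regulatory_potential(g, peaks, d0=1000, window=100_000).score
            exp = rp_direct(g.tss, peaks, d0=1000, window=100_000)
            assert got == pytest.approx(exp, rel=1e-12)

    def test_out_of_window_and_other_chrom_ignored(self):
        g = _gene()
        rp = regulatory_potential(
            g, [_peak("c", g.tss + 50_000), _peak("other", g.tss)], d0=1000
        )
        assert rp.score == 0.0 and rp.k == 0

    def test_invalid_d0(self):
        with pytest.raises(ValidationError):
            regulatory_potential(_gene(), [], d0=0)

    def test_rp_table_matches_scalar_path(self, rng):
        genes = [_gene(f"g{i}", tss=100_000 + 40_000 * i) for i in range(8)]
        model = GeneModel(genes)
        peaks = [_peak("c", int(rng.integers(50_000, 500_000))) for _ in range(60)]
        table = rp_table(model, peaks, d0=1000)
        for g in genes:
            scalar = regulatory_potential(g, peaks, d0=1000)
            assert table.loc[g.gene_id, "rp_score"] == pytest.approx(scalar.score, rel=1e-12)
            assert table.loc[g.gene_id, "k"] == scalar.k


class TestRanking:
    def test_basic_and_ties(self):
        assert list(rank_genes([3, 1, 2])) == [1, 3, 2]
        assert list(rank_genes([2, 2, 1])) == [1.5, 1.5, 3]
        assert list(rank_genes([1, 3, 2], higher_is_better=False)) == [1, 3, 2]

    def test_nan_ranked_last(self):
        ranks = rank_genes([3.0, np.nan, 2.0])
        assert ranks[1] == 3.0
        assert list(ranks[[0, 2]]) == [1, 2]

    @given(
        st.lists(st.integers(-1000, 1000), min_size=1, max_size=40),
        st.sampled_from(["exp", "affine", "cube"]),
    )
    @settings(deadline=None, derandomize=True)
    def test_invariant_under_monotone_transforms(self, scores, kind):
        s = np.array(scores, dtype=float)
        if kind == "exp":
            t = np.exp(s / 1000.0)
        elif kind == "affine":
            t = 3.0 * s + 7.0
        else:
            t = s ** 3
        assert list(rank_genes(s)) == list(rank_genes(t))

    def test_aggregate_single_gene(self):
        agg = aggregate_ranks(pd.Series({"g": 1.0}), pd.Series({"g": 1.0}))
        assert agg.loc["g", "rank_product"] == 1.0
        assert agg.loc["g", "aggregated_rank"] == 1

    def test_aggregate_product_ordering(self):
        agg = aggregate_ranks(pd.Series({"A": 1.0, "B": 2.0}), pd.Series({"A": 3.0, "B": 1.0}))
        assert list(agg.index) == ["B", "A"]
        assert list(agg["rank_product"]) == [2.0, 3.0]

    def test_aggregate_matches_brute_force_sort(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rde = pd.Series(rng.permutation(30) + 1.0, index=genes)
        rrp = pd.Series(rng.permutation(30) + 1.0, index=genes)
        agg = aggregate_ranks(rde, rrp)
        products = {g: rde[g] * rrp[g] for g in genes}
        expected = sorted(genes, key=lambda g: (products[g], g))
        assert list(agg.index) == expected

    def test_aggregate_empty_intersection_is_error(self):
        with pytest.raises(DataError):
            aggregate_ranks(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))

    def test_de_score_monotonicity(self):
        de = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2FoldChange": [1.0, 2.0, 1.0],
                "pvalue": [0.01, 0.01, 0.001],
                "padj": [0.04, 0.04, 0.004],
            }
        )
        scored = de_score_table(de)
        assert scored.loc["b", "de_score"] > scored.loc["a", "de_score"]
        assert scored.loc["c", "de_score"] > scored.loc["a", "de_score"]

    def test_stratified_ranks_keep_directions_separate(self):
        de = pd.DataFrame(
            {
                "gene_id": ["up1", "up2", "dn1", "dn2"],
                "log2FoldChange": [2.0, 1.0, -3.0, -0.5],
                "pvalue": [1e-4] * 4,
                "padj": [1e-3] * 4,
            }
        )
        r = stratified_de_ranks(de_score_table(de))
        assert r["up1"] == 1 and r["up2"] == 2
        assert r["dn1"] == 1 and r["dn2"] == 2


class TestAssignment:
    @pytest.fixture
    def two_gene_model(self):
        return GeneModel([_gene("gA", tss=100_000), _gene("gB", tss=150_000)])

    @staticmethod
    def _sites(rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "log2_fold_change", "significant"],
            index=pd.Index([f"s{i}" for i in range(len(rows))], name="site_id"),
        )

    def test_site_in_gene_body_window_zero(self, two_gene_model):
        sites = self._sites([("c", 104_000, 104_400, 1.0, True)])
        asg = assign_sites_to_genes(sites, two_gene_model, window=0)
        assert list(asg["gene_id"]) == ["gA"]

    def test_multi_assignment_with_wide_window(self, two_gene_model):
        # midpoint 130200: 20200 past gA's end (110000), 19800 before gB's start
        sites = self._sites([("c", 130_000, 130_400, 1.0, True)])
        asg = assign_sites_to_genes(sites, two_gene_model, window=25_000)
        assert sorted(asg["gene_id"]) == ["gA", "gB"]

    def test_matches_containment_scan(self, rng):
        genes = [
            _gene(f"g{i}", tss=int(rng.integers(50_000, 900_000)) , span=8_000)
            for i in range(12)
        ]
        # keep spans disjoint for model validity is not required; model allows overlap
        model = GeneModel(genes)
        rows = []
        for _ in range(80):
            start = int(rng.integers(0, 990_000))
            rows.append(("c", start, start + 400, float(rng.normal()), bool(rng.random() < 0.7)))
        sites = self._sites(rows)
        window = 3000
        asg = assign_sites_to_genes(sites, model, window=window)
        got = set(zip(asg["gene_id"], asg["site_id"]))
        exp = set()
        for sid, r in sites.iterrows():
            m = (r["start"] + r["end"]) // 2
            for g in genes:
                if g.tx_start - window <= m <= g.tx_end + window:
                    exp.add((g.gene_id, sid))
        assert got == exp

    def test_gene_direction_mean_sign_and_tie(self):
        asg = pd.DataFrame(
            {
                "gene_id": ["g", "g", "h", "h", "k"],
                "site_id": ["s1", "s2", "s3", "s4", "s5"],
                "log2_fold_change": [2.0, -1.0, 1.0, -1.0, -0.5],
                "significant": [True, True, True, True, False],
            }
        )
        d = gene_directions(asg)
        assert d["g"] == "Up"
        assert "h" not in d.index  # exact tie -> ambiguous, excluded
        assert "k" not in d.index  # no significant site


class TestIntegrate:
    @pytest.fixture
    def model(self):
        return GeneModel([_gene("gA", tss=100_000), _gene("gB", tss=200_000)])

    @staticmethod
    def _pgr(rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "log2_fold_change", "direction"],
            index=pd.Index([f"p{i}" for i in range(len(rows))], name="site_id"),
        )

    def test_fdr_criterion_excludes_regardless_of_rp(self, model):
        de = pd.DataFrame(
            {"gene_id": ["gA"], "log2FoldChange": [2.0], "pvalue": [0.1], "padj": [0.2]}
        )
        pgr = self._pgr([("c", 99_800, 100_200, 1.0, "gained")])
        res = integrate_de_with_pgr(de, pgr, model)
        assert res.gained.empty and res.lost.empty

    def test_gained_site_at_tss_with_significant_de_included(self, model):
        de = pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "log2FoldChange": [2.0, 0.1],
                "pvalue": [1e-6, 0.8],
                "padj": [1e-4, 0.9],
            }
        )
        pgr = self._pgr([("c", 99_800, 100_200, 1.0, "gained")])
        res = integrate_de_with_pgr(de, pgr, model)
        assert list(res.gained.index) == ["gA"]
        assert res.gained.loc["gA", "rp_score"] == pytest.approx(1.0)
        assert res.lost.empty
        assert res.pgr_direction("gA") == "Up"

    def test_three_way_requires_histone_data(self, model):
        de = pd.DataFrame(
            {"gene_id": ["gA"], "log2FoldChange": [2.0], "pvalue": [1e-6], "padj": [1e-4]}
        )
        pgr = integrate_de_with_pgr(de, self._pgr([("c", 99_900, 100_100, 1.0, "gained")]), model)
        with pytest.raises(DataError, match="histone"):
            three_way_integration(pgr, {}, de, model)

    def test_discordant_histone_site_excluded(self, model):
        de = pd.DataFrame(
            {"gene_id": ["gA"], "log2FoldChange": [2.0], "pvalue": [1e-6], "padj": [1e-4]}
        )
        pgr = integrate_de_with_pgr(de, self._pgr([("c", 99_900, 100_100, 1.0, "gained")]), model)
        down_site = pd.DataFrame(
            {
                "chrom": ["c"], "start": [104_000], "end": [104_400],
                "log2_fold_change": [-1.5], "significant": [True],
            },
            index=pd.Index(["h1"], name="site_id"),
        )
        res = three_way_integration(pgr, {"H3K27ac": down_site}, de, model)
        assert res.n_candidates == 0
        up_site = down_site.assign(log2_fold_change=1.5)
        res2 = three_way_integration(pgr, {"H3K27ac": up_site}, de, model)
        assert list(res2.union["gene_id"]) == ["gA"]
        row = res2.per_mark["H3K27ac"].iloc[0]
        assert (row["histone_direction"], row["pgr_direction"], row["expression_direction"]) \
            == ("Up", "Up", "Up")

    def test_candidates_subset_of_criteria12_genes(self, small_config):
        """Criterion-3 filtering never adds genes beyond criteria (1)+(2)."""
        from peakrank.simulate import simulate_study

        study = simulate_study(small_config)
        diff = study.counts.site_table.copy()
        rows = []
        for sid, r in diff.iterrows():
            iv = GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
            direction = "ns"
            lfc = 0.0
            for p in study.truth.planted_gained_sites:
                if iv.overlaps(p):
                    direction, lfc = "gained", 2.0
            for p in study.truth.planted_lost_sites:
                if iv.overlaps(p):
                    direction, lfc = "lost", -2.0
            rows.append((r["chrom"], r["start"], r["end"], lfc, direction))
        pgr_diff = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "log2_fold_change", "direction"],
            index=diff.index,
        )
        pgr = integrate_de_with_pgr(study.de_table, pgr_diff, study.model)
        res = three_way_integration(pgr, study.histone, study.de_table, study.model)
        assert set(res.union["gene_id"]) <= pgr.gene_ids()

    def test_planted_truth_recovery_at_module_level(self, small_config):
        """With exact planted differential sites, the integration recovers
        the concordant targets and rejects the discordant decoys."""
        from peakrank.simulate import simulate_study

        study = simulate_study(small_config)
        rows = []
        names = []
        for iv in study.truth.planted_gained_sites:
            rows.append((iv.chrom, iv.start, iv.end, 2.0, "gained"))
            names.append(iv.name)
        for iv in study.truth.planted_lost_sites:
            rows.append((iv.chrom, iv.start, iv.end, -2.0, "lost"))
            names.append(iv.name)
        pgr_diff = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "log2_fold_change", "direction"],
            index=pd.Index(names, name="site_id"),
        )
        pgr = integrate_de_with_pgr(study.de_table, pgr_diff, study.model)
        res = three_way_integration(pgr, study.histone, study.de_table, study.model)
        called = set(res.union["gene_id"])
        targets = set(study.truth.planted_target_genes)
        decoys = set(study.truth.planted_decoy_genes)
        assert targets <= called
        assert not (called & decoys)
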