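"""Tiling, CV, global methylation, metagene profile, region comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from methylhet import synthetic_data as sd
from methylhet.epiread_core import BetaTrack, CpGReference, EpiRead, compute_beta_track
from methylhet.methylome_summaries import (
    global_methylation,
    metagene_profile,
    region_group_comparison,
    sample_cv,
    tile_methylation,
)


def track_from_values(positions, betas, depth, length=None):
    """BetaTrack with given betas at given positions, constant depth."""
    positions = np.asarray(positions)
    betas = np.asarray(betas, dtype=float)
    meth = np.round(betas * depth).astype(np.int64)
    ref = CpGReference(
        positions={"c1": positions},
        contig_lengths={"c1": int(length or positions.max() + 10)},
    )
    track = BetaTrack(
        meth={"c1": meth}, total={"c1": np.full(len(positions), depth, dtype=np.int64)}
    )
    return track, ref


class TestTiling:
    def test_tile_mean_and_eligibility(self):
        track, ref = track_from_values([10, 20, 30], [0.2, 0.4, 0.6], depth=20, length=100)
        tiles = tile_methylation(track, ref, tile_width=100, depth_threshold=10)
        assert len(tiles) == 1
        assert tiles.loc[0, "methylation"] == pytest.approx(0.4)
        assert bool(tiles.loc[0, "eligible"])

    def test_depth_exactly_ten_is_ineligible(self):
        track, ref = track_from_values([10, 20], [0.5, 0.5], depth=10, length=100)
        tiles = tile_methylation(track, ref, tile_width=100, depth_threshold=10)
        assert not bool(tiles.loc[0, "eligible"])

    def test_cpg_free_tile_flagged(self):
        track, ref = track_from_values([10], [0.5], depth=20, length=200)
        tiles = tile_methylation(track, ref, tile_width=100, depth_threshold=10)
        assert len(tiles) == 2
        assert tiles.loc[1, "n_cpgs"] == 0
        assert not bool(tiles.loc[1, "eligible"])
        assert math.isnan(tiles.loc[1, "methylation"])

    def test_each_cpg_rule_uses_minimum_depth(self):
        track, ref = track_from_values([10, 20], [0.5, 0.5], depth=20, length=100)
        track.total["c1"][1] = 5  # one thin CpG
        mean_rule = tile_methylation(track, ref, 100, 10, depth_rule="mean")
        each_rule = tile_methylation(track, ref, 100, 10, depth_rule="each")
        assert bool(mean_rule.loc[0, "eligible"])  # mean 12.5 > 10
        assert not bool(each_rule.loc[0, "eligible"])  # min 5 <= 10

    def test_tiling_partitions_contig(self):
        config = sd.SimulationConfig(n_loci=40, seed=3)
        ref, _ = sd.simulate_reference(config)
        reads = sd.simulate_epireads(config, sd.clonal_distributions(config))
        track = compute_beta_track(reads, ref)
        tiles = tile_methylation(track, ref, tile_width=777)
        assert tiles["start"].iloc[0] == 0
        assert tiles["end"].iloc[-1] == ref.contig_lengths["chrS"]
        # contiguous, non-overlapping
        assert (tiles["start"].iloc[1:].to_numpy() == tiles["end"].iloc[:-1].to_numpy()).all()
        assert int(tiles["n_cpgs"].sum()) == ref.total_cpgs


class TestCV:
    def test_constant_tiles_zero_cv(self):
        tiles = pd.DataFrame(
            {"methylation": [0.5, 0.5, 0.5], "eligible": [True] * 3}
        )
        assert sample_cv(tiles).cv == 0.0

    def test_direct_arithmetic(self):
        tiles = pd.DataFrame(
            {"methylation": [0.2, 0.4, 0.6], "eligible": [True] * 3}
        )
        res = sample_cv(tiles, "s")
        assert res.cv == pytest.approx(0.2 / 0.4)
        assert res.n_eligible_tiles == 3

    def test_all_ineligible_undefined(self):
        tiles = pd.DataFrame({"methylation": [0.2, 0.4], "eligible": [False, False]})
        assert math.isnan(sample_cv(tiles).cv)

    def test_cv_orders_with_across_tile_dispersion(self):
        # cohorts generated with wider across-locus methylation dispersion
        # (more clones, more even mixing) must show a larger tile CV
        rng = np.random.default_rng(4)
        cvs = []
        for founder_prob in (0.95, 0.5):
            config = sd.SimulationConfig(
                n_loci=120, clonality=1, founder_meth_prob=founder_prob, seed=6
            )
            ref, _ = sd.simulate_reference(config)
            dists = sd.clonal_distributions(config, rng)
            reads = sd.simulate_epireads(config, dists, rng=rng)
            track = compute_beta_track(reads, ref)
            tiles = tile_methylation(track, ref, tile_width=2000)
            cvs.append(sample_cv(tiles).cv)
        # founder_meth_prob near 1: almost all tiles methylated, low CV;
        # 50/50 founders: bimodal tiles, high CV
        assert cvs[1] > cvs[0]


class TestGlobalMethylation:
    def test_unweighted_mean(self):
        track, _ = track_from_values([0, 10, 20, 30], [1, 1, 0, 0], depth=10)
        assert global_methylation(track) == pytest.approx(0.5)

    def test_fully_methylated_simulation(self):
        config = sd.SimulationConfig(n_loci=5, error_rate=0.0, seed=2)
        ref, _ = sd.simulate_reference(config)
        dists = [
            sd.EpialleleDistribution.from_sparse(f"L{i}", {"MMMM": 1.0})
            for i in range(5)
        ]
        track = compute_beta_track(sd.simulate_epireads(config, dists), ref)
        assert global_methylation(track) == 1.0

    def test_error_rate_lowers_level_by_expectation(self):
        e = 0.1
        config = sd.SimulationConfig(n_loci=50, error_rate=e, seed=12)
        ref, _ = sd.simulate_reference(config)
        dists = [
            sd.EpialleleDistribution.from_sparse(f"L{i}", {"MMMM": 1.0})
            for i in range(50)
        ]
        track = compute_beta_track(
            sd.simulate_epireads(config, dists, coverage=50), ref
        )
        assert global_methylation(track) == pytest.approx(1 - e, abs=0.01)

    def test_no_coverage_undefined(self):
        ref = CpGReference(positions={"c1": np.array([5])}, contig_lengths={"c1": 10})
        track = compute_beta_track([], ref)
        assert math.isnan(global_methylation(track))


class TestMetagene:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])

    def test_flat_track_flat_profile(self):
        positions = np.arange(50, 4950, 25)
        track, ref = track_from_values(positions, np.full(len(positions), 0.7), 20, length=5000)
        genes = self._genes([("c1", 1500, 3500, "g1", 0, "+")])
        prof = metagene_profile(track, ref, genes, flank_bp=1000, n_body_bins=20, n_flank_bins=5)
        defined = prof.values[~np.isnan(prof.values)]
        assert np.allclose(defined, 0.7)

    def test_minus_strand_flips_orientation(self):
        positions = np.arange(0, 3000, 10)
        betas = np.linspace(0, 1, len(positions))  # rising along the genome
        track, ref = track_from_values(positions, betas, 20, length=3000)
        plus = self._genes([("c1", 500, 2500, "g", 0, "+")])
        minus = self._genes([("c1", 500, 2500, "g", 0, "-")])
        p_plus = metagene_profile(track, ref, plus, 400, 20, 5).values
        p_minus = metagene_profile(track, ref, minus, 400, 20, 5).values
        np.testing.assert_allclose(p_plus, p_minus[::-1], atol=1e-12)

    def test_two_genes_average(self):
        positions = np.arange(0, 2000, 10)
        betas = np.where(positions < 1000, 0.2, 0.6)
        track, ref = track_from_values(positions, betas, 20, length=2000)
        genes = self._genes(
            [("c1", 200, 800, "a", 0, "+"), ("c1", 1200, 1800, "b", 0, "+")]
        )
        prof = metagene_profile(track, ref, genes, 100, 10, 2)
        body = prof.values[2:12]
        assert np.allclose(body, 0.4)

    def test_short_genes_skipped_and_counted(self):
        positions = np.arange(0, 500, 10)
        track, ref = track_from_values(positions, np.full(len(positions), 0.5), 20, length=500)
        genes = self._genes([("c1", 100, 150, "tiny", 0, "+")])
        prof = metagene_profile(track, ref, genes, 100, n_body_bins=100, n_flank_bins=2)
        assert prof.n_genes_used == 0
        assert prof.n_genes_skipped == 1

    def test_empty_gene_set_rejected(self):
        track, ref = track_from_values([10], [0.5], 20)
        with pytest.raises(ValueError):
            metagene_profile(track, ref, pd.DataFrame())


class TestRegionComparison:
    def test_identical_groups_zero_differences(self):
        means = pd.DataFrame(
            {"s1": [0.3, 0.5], "s2": [0.4, 0.6], "s3": [0.3, 0.5], "s4": [0.4, 0.6]},
            index=["r1", "r2"],
        )
        groups = {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}
        res = region_group_comparison(means, groups)
        assert np.allclose(res["mean_diff"], 0.0)

    def test_exact_small_sample_p(self):
        # [1,2,3] vs [4,5,6]: U = 0; all 20 label permutations -> p = 2/20
        means = pd.DataFrame(
            [[1, 2, 3, 4, 5, 6]],
            index=["r"],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
        res = region_group_comparison(means, groups)
        assert res.loc["r", "U"] == 0.0
        assert res.loc["r", "p"] == pytest.approx(0.1)

    def test_null_simulation_type_I_error(self, rng):
        # 300 exchangeable regions: ~5% raw rejections expected at alpha=0.05
        n_regions, n = 300, 10
        means = pd.DataFrame(
            rng.normal(size=(n_regions, 2 * n)),
            columns=[f"s{i}" for i in range(2 * n)],
        )
        groups = {f"s{i}": ("a" if i < n else "b") for i in range(2 * n)}
        res = region_group_comparison(means, groups)
        rate = (res["p"] < 0.05).mean()
        assert 0.01 <= rate <= 0.10

    def test_group_size_validation(self):
        means = pd.DataFrame([[1, 2, 3]], columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            region_group_comparison(means, {"s1": "a", "s2": "a", "s3": "b"})

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_bh_matches_brute_force(self, pvals):
        # oracle: step-up definition computed literally
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        q = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q, brute, atol=1e-12)
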