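import numpy as np
import pandas as pd
import pytest

from admixscan.calls import AncestryMatrix
from admixscan.genome import AnnotationTrack, GeneticMap, MarkerSet, make_windows
from admixscan.regions import (
    DetectionConfig,
    audit_regions,
    bootstrap_observed_counts,
    classify_shared,
    detect_regions,
    find_outlier_regions,
    matched_window_null,
    permutation_null_blocks,
    permutation_null_shuffle,
    refine_regions,
    site_quantiles,
)
from admixscan.winstats import window_mean_ancestry
from conftest import make_markers, make_uniform_map


def markers_at(positions, chrom="chr1"):
    return MarkerSet(pd.DataFrame({"chrom": chrom, "pos": positions}))


class TestSiteQuantiles:
    def test_uniform_grid(self):
        vals = np.linspace(0, 1, 101)
        assert site_quantiles(vals, 0.025) == pytest.approx(0.025)

    def test_constant_vector(self):
        assert site_quantiles(np.full(50, 0.3), 0.8) == pytest.approx(0.3)

    def test_sort_and_index_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.random(37)
        for q in (0.025, 0.05, 0.1, 0.9):
            # type-7: linear interpolation of order statistics at (n-1) q
            srt = np.sort(vals)
            hpos = (len(vals) - 1) * q
            lo, hi = int(np.floor(hpos)), int(np.ceil(hpos))
            oracle = srt[lo] + (hpos - lo) * (srt[hi] - srt[lo])
            assert site_quantiles(vals, q) == pytest.approx(oracle)


class TestFindOutlierRegions:
    def cfg(self):
        return DetectionConfig()

    def test_no_focal_sites_empty(self):
        anc = np.full(100, 0.5)
        out = find_outlier_regions(anc, markers_at(np.arange(100) * 10), self.cfg(), "desert")
        assert len(out) == 0

    def test_single_dip_direct_scan(self):
        """One dip at sites 30-40, bounded by the edge-site rule."""
        anc = np.array([0.2, 0.2, 0.01, 0.02, 0.2, 0.2])
        mk = markers_at([10, 20, 30, 40, 50, 60])
        # quantile thresholds land at ~0.015 (focal) and ~0.05 (edge) by
        # construction of this vector
        cfg = DetectionConfig(q_focal=0.2, q_edge=0.3, q_window=0.4)
        thr_focal = site_quantiles(anc, 0.2)   # type-7: exactly 0.02
        thr_edge = site_quantiles(anc, 0.3)    # 0.11
        assert thr_focal == pytest.approx(0.02) and thr_edge < 0.2
        out = find_outlier_regions(anc, mk, cfg, "desert")
        assert len(out) == 1
        r = out.iloc[0]
        # contains exactly sites 30 and 40 (both at/below the focal threshold)
        assert r["start"] == 30 and r["end"] == 41
        assert r["n_sites"] == 2
        assert r["n_focal"] == 2
        assert r["focal_bp"] == 30

    def test_two_focal_sites_one_region(self):
        anc = np.array([0.5, 0.5, 0.0, 0.01, 0.0, 0.5, 0.5, 0.5, 0.5, 0.5])
        mk = markers_at(np.arange(10) * 100)
        cfg = DetectionConfig(q_focal=0.2, q_edge=0.3, q_window=0.4)
        out = find_outlier_regions(anc, mk, cfg, "desert")
        # the two zero sites are focal (0.01 exceeds the 0.008 threshold)
        assert len(out) == 1
        assert out.iloc[0]["n_focal"] == 2
        assert out.iloc[0]["n_sites"] == 3

    def test_invalid_kind(self):
        with pytest.raises(ValueError):
            find_outlier_regions(np.zeros(5), markers_at([1, 2, 3, 4, 5]), self.cfg(), "lake")


def random_fixture(seed, n_sites=400):
    rng = np.random.default_rng(seed)
    anc = np.clip(rng.beta(5, 5, n_sites) * 0.4 + rng.random(n_sites) * 0.1, 0, 1)
    # carve a few dips and peaks
    for _ in range(rng.integers(1, 4)):
        c = rng.integers(20, n_sites - 20)
        w = rng.integers(3, 15)
        anc[c : c + w] *= 0.05
    for _ in range(rng.integers(1, 4)):
        c = rng.integers(20, n_sites - 20)
        w = rng.integers(3, 15)
        anc[c : c + w] = 1 - (1 - anc[c : c + w]) * 0.05
    pos = np.sort(rng.choice(n_sites * 50, size=n_sites, replace=False))
    return anc, markers_at(pos)


class TestMirrorSymmetry:
    def test_desert_island_mirror_100_fixtures(self):
        """Desert detection on 1-ancestry equals island detection on ancestry."""
        cfg = DetectionConfig()
        for seed in range(100):
            anc, mk = random_fixture(seed)
            deserts = find_outlier_regions(1.0 - anc, mk, cfg, "desert")
            islands = find_outlier_regions(anc, mk, cfg, "island")
            pd.testing.assert_frame_equal(
                deserts.drop(columns="kind"), islands.drop(columns="kind")
            )


class TestRefineRegions:
    def setup_pipeline(self, seed=0):
        gmap = make_uniform_map(1, 2_000_000, 2.0)
        markers = make_markers(gmap, 2_000)  # 1000 markers, 0.002 cM spacing
        rng = np.random.default_rng(seed)
        n_ind = 40
        base = rng.choice([0, 1, 2], p=[0.49, 0.42, 0.09], size=(n_ind, len(markers))).astype(np.int8)
        return gmap, markers, base

    def test_merge_and_length_filters(self):
        gmap, markers, dosage = self.setup_pipeline()
        # two deep deserts 40 kb apart (gap < 50 kb merge distance), each 30 kb
        for lo, hi in ((500_000, 530_000), (570_000, 600_000)):
            sel = (markers.pos >= lo) & (markers.pos < hi)
            dosage[:, sel] = 0
        m = AncestryMatrix(dosage=dosage, markers=markers)
        grid = make_windows(gmap, "cM", 0.05)
        cfg = DetectionConfig(min_aims=5)
        regs = detect_regions(m, grid, cfg, "desert")
        assert len(regs) == 1
        r = regs.iloc[0]
        assert r["start"] <= 510_000 and r["end"] >= 590_000
        assert audit_regions(regs, m, grid, cfg, "desert")

    def test_short_region_dropped(self):
        """An 8 kb raw region is dropped by the length filter while an 80 kb
        one with the same midpoint window survives (deterministic refine)."""
        gmap, markers, dosage = self.setup_pipeline(1)
        sel = (markers.pos >= 500_000) & (markers.pos < 600_000)
        dosage[:, sel] = 0
        m = AncestryMatrix(dosage=dosage, markers=markers)
        grid = make_windows(gmap, "cM", 0.05)
        cfg = DetectionConfig(min_aims=5)
        raw_short = pd.DataFrame(
            [("desert", "chr1", 520_000, 528_000, 524_000, 4, 1)],
            columns=["kind", "chrom", "start", "end", "focal_bp", "n_sites", "n_focal"],
        )
        raw_long = pd.DataFrame(
            [("desert", "chr1", 500_000, 580_000, 524_000, 40, 10)],
            columns=["kind", "chrom", "start", "end", "focal_bp", "n_sites", "n_focal"],
        )
        assert len(refine_regions(raw_short, m, grid, cfg, "desert")) == 0
        assert len(refine_regions(raw_long, m, grid, cfg, "desert")) == 1

    def test_island_thinned_filter(self):
        gmap, markers, dosage = self.setup_pipeline(2)
        sel = (markers.pos >= 500_000) & (markers.pos < 560_000)
        dosage[:, sel] = 2
        m = AncestryMatrix(dosage=dosage, markers=markers)
        grid = make_windows(gmap, "cM", 0.05)
        cfg = DetectionConfig(min_aims=5)
        with_self = detect_regions(m, grid, cfg, "island", thinned_matrix=m)
        assert len(with_self) >= 1
        # a discordant "thinned" matrix (ancestry differs by ~0.5) kills islands
        thinned = AncestryMatrix(
            dosage=np.where(dosage >= 0, 0, -1).astype(np.int8), markers=markers
        )
        without = detect_regions(m, grid, cfg, "island", thinned_matrix=thinned)
        assert len(without) == 0

    def test_refine_keeps_config_predicates(self):
        gmap, markers, dosage = self.setup_pipeline(3)
        sel = (markers.pos >= 800_000) & (markers.pos < 900_000)
        dosage[:, sel] = 0
        m = AncestryMatrix(dosage=dosage, markers=markers)
        grid = make_windows(gmap, "cM", 0.05)
        cfg = DetectionConfig(min_aims=5)
        regs = detect_regions(m, grid, cfg, "desert")
        assert audit_regions(regs, m, grid, cfg, "desert")


class TestClassifyShared:
    def build(self, seed=0):
        gmap = make_uniform_map(1, 2_000_000, 2.0)
        markers = make_markers(gmap, 2_000)
        rng = np.random.default_rng(seed)
        dosage = rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1], size=(30, len(markers))).astype(np.int8)
        sel = (markers.pos >= 1_000_000) & (markers.pos < 1_100_000)
        dosage[:, sel] = 0
        m = AncestryMatrix(dosage=dosage, markers=markers)
        grid = make_windows(gmap, "cM", 0.05)
        cfg = DetectionConfig(min_aims=5)
        regs = detect_regions(m, grid, cfg, "desert")
        assert len(regs) >= 1
        return gmap, markers, grid, cfg, m, regs

    def test_identical_population_all_shared(self):
        gmap, markers, grid, cfg, m, regs = self.build()
        anc, _ = window_mean_ancestry(m, grid)
        flags = classify_shared(regs, anc, grid, cfg, "desert")
        assert flags.all()

    def test_constant_other_none_shared(self):
        gmap, markers, grid, cfg, m, regs = self.build()
        anc = np.full(len(grid), 0.2)
        flags = classify_shared(regs, anc, grid, cfg, "desert")
        assert not flags.any()

    def test_constructed_common_dip_shared(self):
        gmap, markers, grid, cfg, m, regs = self.build()
        rng = np.random.default_rng(42)
        other = rng.uniform(0.2, 0.4, size=len(grid))
        widx = grid.window_index(
            np.full(len(regs), "chr1"),
            ((regs["start"] + regs["end"]) // 2).to_numpy(),
        )
        other[widx] = 0.001  # a dip exactly at the region midpoints
        flags = classify_shared(regs, other, grid, cfg, "desert")
        assert flags.all()


class TestPermutationNulls:
    def setup(self):
        gmap = make_uniform_map(2, 2_000_000, 2.0)
        grid = make_windows(gmap, "cM", 0.05)
        rng = np.random.default_rng(3)
        other = rng.random(len(grid))
        return gmap, grid, other

    def test_empty_regions_all_zero(self):
        gmap, grid, other = self.setup()
        regs = pd.DataFrame(columns=["kind", "chrom", "start", "end"])
        out = permutation_null_shuffle(regs, other, grid, DetectionConfig(), "desert", n_perm=50, seed=0)
        assert out["observed"] == 0
        assert np.all(out["null"] == 0)

    def test_binomial_expectation_oracle(self):
        """R regions over iid-uniform windows: E[null count] = R * q."""
        gmap, grid, other = self.setup()
        starts = np.arange(10) * 150_000 + 10_000
        regs = pd.DataFrame(
            {
                "kind": "desert",
                "chrom": "chr1",
                "start": starts,
                "end": starts + 20_000,
            }
        )
        cfg = DetectionConfig()
        out = permutation_null_shuffle(regs, other, grid, cfg, "desert", n_perm=10_000, seed=1)
        expected = len(regs) * cfg.share_quantile
        assert out["null"].mean() == pytest.approx(expected, rel=0.05)

    def test_block_offset_zero_reproduces_observed(self):
        gmap, grid, other = self.setup()
        starts = np.arange(5) * 300_000 + 50_000
        regs = pd.DataFrame(
            {"kind": "desert", "chrom": "chr1", "start": starts, "end": starts + 30_000}
        )
        cfg = DetectionConfig()
        out = permutation_null_blocks(regs, other, grid, cfg, "desert", offsets=np.array([0]))
        assert out["null"][0] == out["observed"]

    def test_block_constant_ancestry_zero_everywhere(self):
        gmap, grid, _ = self.setup()
        starts = np.arange(5) * 300_000 + 50_000
        regs = pd.DataFrame(
            {"kind": "desert", "chrom": "chr1", "start": starts, "end": starts + 30_000}
        )
        out = permutation_null_blocks(
            regs, np.full(len(grid), 0.25), grid, DetectionConfig(), "desert"
        )
        assert out["observed"] == 0 and np.all(out["null"] == 0)

    def test_block_rotation_moves_single_dip(self):
        gmap, grid, _ = self.setup()
        rng = np.random.default_rng(11)
        other = rng.uniform(0.3, 0.6, size=len(grid))  # continuous background
        regs = pd.DataFrame(
            {"kind": "desert", "chrom": "chr1", "start": [500_000], "end": [530_000]}
        )
        cfg = DetectionConfig()
        widx = int(
            grid.window_index(np.array(["chr1"]), np.array([515_000]))[0]
        )
        other[widx] = 0.0  # shared dip exactly at the region
        obs = permutation_null_blocks(regs, other, grid, cfg, "desert", offsets=np.array([0]))
        half = len(grid) // 2
        rolled = permutation_null_blocks(regs, other, grid, cfg, "desert", offsets=np.array([half]))
        assert obs["observed"] == 1
        assert rolled["null"][0] == 0

    def test_default_offsets_tile_genome(self):
        gmap, grid, other = self.setup()
        regs = pd.DataFrame(
            {"kind": "desert", "chrom": "chr1", "start": [100_000], "end": [130_000]}
        )
        out = permutation_null_blocks(regs, other, grid, DetectionConfig(), "desert")
        # fewer windows than the requested 130 tilings: every rotation distinct
        assert len(out["offsets"]) == min(130, len(grid) - 1)
        assert (out["offsets"] > 0).all()


class TestMatchedWindowNull:
    def build(self):
        gmap = make_uniform_map(1, 4_000_000, 4.0)
        markers = make_markers(gmap, 2_000)
        rng = np.random.default_rng(5)
        # coding-correlated ancestry: more coding -> lower minor ancestry
        coding_rows = []
        dosage = rng.choice([0, 1, 2], p=[0.5, 0.4, 0.1], size=(30, len(markers))).astype(np.int8)
        for block in range(40):
            s = block * 100_000
            dens = rng.integers(0, 50_000)
            coding_rows.append(("chr1", s, s + dens, "coding"))
            if dens > 30_000:
                sel = (markers.pos >= s) & (markers.pos < s + 100_000)
                dosage[:, sel] = np.where(
                    rng.random((30, sel.sum())) < 0.7, 0, dosage[:, sel]
                ).astype(np.int8)
        track = AnnotationTrack(
            pd.DataFrame(coding_rows, columns=["chrom", "start", "end", "cls"])
        )
        m = AncestryMatrix(dosage=dosage, markers=markers)
        region = pd.Series({"chrom": "chr1", "start": 1_000_000, "end": 1_050_000})
        return gmap, track, m, region

    def test_infinite_tolerance_marginal(self):
        gmap, track, m, region = self.build()
        cfg = DetectionConfig()
        p = matched_window_null(region, m, gmap, track, cfg, np.inf, "desert")
        assert p == pytest.approx(cfg.share_quantile, abs=0.03)

    def test_probability_bounded(self):
        gmap, track, m, region = self.build()
        cfg = DetectionConfig()
        p = matched_window_null(region, m, gmap, track, cfg, 20_000, "desert")
        assert np.isnan(p) or 0.0 <= p <= 1.0


class TestBootstrapObservedCounts:
    def test_all_shared(self):
        out = bootstrap_observed_counts(np.ones(7, dtype=bool), n_boot=200, seed=0)
        assert np.all(out == 7)

    def test_none_shared(self):
        out = bootstrap_observed_counts(np.zeros(7, dtype=bool), n_boot=200, seed=0)
        assert np.all(out == 0)

    def test_binomial_mean_oracle(self):
        flags = np.array([True] * 5 + [False] * 5)
        out = bootstrap_observed_counts(flags, n_boot=20_000, seed=1)
        assert out.mean() == pytest.approx(5.0, rel=0.02)


class TestDetectionConfig:
    def test_quantile_ordering_enforced(self):
        with pytest.raises(ValueError):
            DetectionConfig(q_focal=0.2, q_edge=0.1)
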