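"""Gi* statistic, BH-FDR correction, confidence tiers and blackspots."""

import warnings

import numpy as np
import pytest

from ohsa import (
    classify,
    distance_band_weights,
    extract_blackspots,
    fdr_correct,
    gi_star,
    plant_truth_cells,
)
from ohsa import ClusterSpec, SimulationConfig, assign_counts, generate_events, generate_regions, make_fishnet

from _oracles import bh_adjust_brute, gi_star_brute
from conftest import grid_points


class TestGiStar:
    def test_requires_include_self(self):
        w = distance_band_weights(grid_points(3, 3), 200.0, include_self=False)
        with pytest.raises(ValueError, match="include_self"):
            gi_star(np.arange(9.0), w)

    def test_identity_weights_reduce_to_standardized_deviation(self):
        """With d=0 (self only) the statistic collapses to (x_i - xbar)/S
        and matches the literal transcription."""
        w = distance_band_weights(grid_points(3, 3), 0.0, include_self=True)
        vals = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 1.0, 9.0, 2.0, 4.0])
        gi, s = gi_star(vals, w)
        np.testing.assert_allclose(gi, (vals - vals.mean()) / s, atol=1e-12)
        np.testing.assert_allclose(gi, gi_star_brute(vals, w.matrix.toarray()), atol=1e-12)

    def test_single_spike_caps_its_own_zscore(self):
        """5x5 lattice, one cell at 50 among 1s: the lone spike inflates the
        global S, so its Gi* is exactly 2.0 — high, but not a blackspot."""
        pts = grid_points(5, 5)
        vals = np.ones(25)
        vals[12] = 50.0
        w = distance_band_weights(pts, 200.0, include_self=True)
        gi, _ = gi_star(vals, w)
        assert gi[12] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(gi, gi_star_brute(vals, w.matrix.toarray()), atol=1e-12)

    def test_elevated_center_cross_is_a_blackspot(self):
        """5x5 lattice with the center cell and its rook cross raised to 10:
        the center exceeds 2.58 and is extracted as a blackspot."""
        pts = grid_points(5, 5)
        vals = np.ones(25)
        vals[[7, 11, 12, 13, 17]] = 10.0
        w = distance_band_weights(pts, 200.0, include_self=True)
        gi, _ = gi_star(vals, w)
        assert gi[12] > 2.58
        np.testing.assert_allclose(gi, gi_star_brute(vals, w.matrix.toarray()), atol=1e-12)
        cls = classify(vals, w)
        assert 12 in extract_blackspots(cls)

    def test_constant_values_error(self):
        w = distance_band_weights(grid_points(3, 3), 200.0, include_self=True)
        with pytest.raises(ValueError, match="S = 0"):
            gi_star(np.ones(9), w)

    def test_saturated_neighborhood_is_degenerate_not_significant(self):
        """A band covering the whole lattice makes the statistic 0/0."""
        pts = grid_points(2, 2)
        w = distance_band_weights(pts, 10_000.0, include_self=True)
        with pytest.warns(UserWarning, match="saturated"):
            gi, _ = gi_star(np.array([1.0, 2.0, 3.0, 4.0]), w)
        assert np.isnan(gi).all()
        with pytest.warns(UserWarning, match="saturated"):
            cls = classify(np.array([1.0, 2.0, 3.0, 4.0]), w)
        assert (cls.table["bin"] == 0).all() and cls.table["degenerate"].all()

    @pytest.mark.parametrize("trial", range(5))
    def test_oracle_equivalence_on_random_lattices(self, trial):
        rng = np.random.default_rng(100 + trial)
        nr, nc = rng.integers(3, 16, 2)
        pts = grid_points(int(nr), int(nc))
        vals = rng.poisson(2.0, len(pts)).astype(float)
        if vals.std() == 0:
            vals[0] += 1
        d = float(rng.choice([200.0, 300.0, 450.0]))
        w = distance_band_weights(pts, d, include_self=True)
        gi, _ = gi_star(vals, w)
        np.testing.assert_allclose(gi, gi_star_brute(vals, w.matrix.toarray()), atol=1e-12)


class TestFdrCorrect:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_correct([0.001, 0.02, 0.03, 0.9]), [0.004, 0.04, 0.04, 0.9]
        )

    def test_equal_p_values_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_and_empty(self):
        np.testing.assert_allclose(fdr_correct([0.07]), [0.07])
        assert fdr_correct([]).size == 0

    def test_nan_passthrough_excluded_from_family(self):
        out = fdr_correct([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], bh_adjust_brute([0.01, 0.04]))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_step_up(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 40)
        np.testing.assert_allclose(fdr_correct(p), bh_adjust_brute(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])


class TestClassifyBins:
    @pytest.mark.parametrize(
        "z,p_adj,expected",
        [
            (3.0, 0.001, 3),
            (3.0, 0.02, 0),  # 99% z without the adjusted-p condition
            (2.2, 0.02, 2),
            (1.8, 0.08, 1),
            (0.0, 1.0, 0),
            (2.58, 0.001, 2),  # boundary value falls to the lower tier
            (-2.2, 0.02, -2),
            (-3.0, 0.005, -3),
            (-1.8, 0.09, -1),
        ],
    )
    def test_threshold_gating(self, z, p_adj, expected):
        from ohsa.hotspot import _bin_one

        assert _bin_one(z, p_adj) == expected

    def test_fdr_never_adds_extreme_bins(self):
        """Cells at the +/-99% tier after correction are a subset of those
        that would qualify on raw p."""
        rng = np.random.default_rng(5)
        pts = grid_points(10, 10)
        vals = rng.poisson(2.0, 100).astype(float)
        vals[[33, 34, 43, 44]] += 15
        w = distance_band_weights(pts, 300.0, include_self=True)
        cls = classify(vals, w)
        t = cls.table
        raw_extreme = (np.abs(t["gi_z"]) > 2.58) & (t["p"] < 0.01)
        assert ((np.abs(t["bin"]) == 3) <= raw_extreme).all()
        assert (t["p_adjusted"].dropna() >= t["p"].dropna() - 1e-15).all()


class TestRecovery:
    def test_type_one_rate_under_csr(self):
        """Raw (pre-FDR) upper-tail rate at z > 2.58 under multinomial CSR
        counts on 400 cells stays within [0.001, 0.015] (200 replicates)."""
        pts = grid_points(20, 20)
        w = distance_band_weights(pts, 400.0, include_self=True)
        rng = np.random.default_rng(17)
        fracs = []
        for _ in range(200):
            counts = np.bincount(rng.integers(0, 400, 800), minlength=400).astype(float)
            gi, _ = gi_star(counts, w)
            fracs.append((gi > 2.58).mean())
        assert 0.001 <= np.mean(fracs) <= 0.015

    def test_planted_cluster_cells_recovered_as_blackspots(self):
        """>= 80% of planted-truth cells (>= 10 clustered events) classified
        as blackspots, across 20 seeded replicates."""
        regions = generate_regions(1, 4000.0)
        lat = make_fishnet(regions, 200.0)
        w = distance_band_weights(lat, 400.0, include_self=True)
        hits = total = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_events=600,
                background_fraction=400 / 600,
                clusters=[ClusterSpec((2000.0, 2000.0), 200.0, 1.0)],
                seed=seed,
            )
            ev, truth = generate_events(regions, cfg)
            assign_counts(lat, ev, "ALL")
            truth_cells = plant_truth_cells(truth, lat, 10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cls = classify(lat.values("ALL"), w, index=lat.cells.index)
            spots = extract_blackspots(cls)
            assert spots <= set(lat.cells.index)
            hits += len(truth_cells & spots)
            total += len(truth_cells)
        assert total > 0
        assert hits / total >= 0.8
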