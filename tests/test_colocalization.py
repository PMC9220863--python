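"""Nearest-neighbor distances and the KS comparison against the null."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from neurofish import GridGeometry, nn_compare, nn_distances, simulate_random_placement
from neurofish.nulls import NullEnsemble

from conftest import spot_frame


class TestNNDistances:
    def test_two_spots_give_symmetric_sample(self):
        spots = spot_frame([(0.0, 0.0), (300.0, 0.0)])
        assert nn_distances(spots, mode="self").tolist() == [300.0, 300.0]
        # counted once in the unique-pair sample
        assert nn_distances(spots, mode="self", unique_pairs=True).tolist() == [300.0]

    def test_single_spot_yields_empty_sample_with_warning(self):
        with pytest.warns(UserWarning, match=">= 2"):
            sample = nn_distances(spot_frame([(1.0, 1.0)]), mode="self")
        assert sample.size == 0

    @pytest.mark.parametrize("n", [5, 50, 200])
    def test_matches_brute_force_all_pairs_oracle(self, n):
        rng = np.random.default_rng(n)
        spots = spot_frame(list(zip(rng.uniform(0, 5e4, n), rng.uniform(0, 5e4, n))))
        xy = spots[["x_nm", "y_nm"]].to_numpy()
        d = cdist(xy, xy)
        np.fill_diagonal(d, np.inf)
        oracle = d.min(axis=1)
        assert nn_distances(spots, mode="self").tolist() == oracle.tolist()

    def test_cross_mode_nearest_in_other_table(self):
        a = spot_frame([(0.0, 0.0), (1000.0, 0.0)])
        b = spot_frame([(100.0, 0.0)])
        assert nn_distances(a, b, mode="cross").tolist() == [100.0, 900.0]

    def test_self_sample_invariant_under_spot_permutation(self):
        rng = np.random.default_rng(8)
        spots = spot_frame(list(zip(rng.uniform(0, 1e4, 40), rng.uniform(0, 1e4, 40))))
        shuffled = spots.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert sorted(nn_distances(spots, mode="self")) == pytest.approx(
            sorted(nn_distances(shuffled, mode="self"))
        )


class TestNNCompare:
    def _null(self, g, mask, n, seed, n_sims=5):
        return simulate_random_placement(n, mask, g, n_sims=n_sims, seed=seed)

    def test_grid_spaced_600nm_fills_second_bin(self):
        g = GridGeometry(256, 256)
        pts = [(1000.0 + 600.0 * i, 1000.0 + 600.0 * j) for i in range(5) for j in range(5)]
        null = self._null(g, np.ones((256, 256), bool), 25, seed=3)
        hist = nn_compare(spot_frame(pts), null)
        row = hist.table[(hist.table.bin_lo_nm == 500.0)].iloc[0]
        assert row.observed_fraction == 1.0

    def test_disjoint_supports_give_ks_statistic_one(self):
        g = GridGeometry(64, 64)
        pts = [(1000.0, 1000.0), (1100.0, 1000.0), (2000.0, 2000.0), (2150.0, 2000.0)]
        # null domain far away so all null NN distances are tiny but the
        # observed/null *samples* are made disjoint via a narrow strip
        tables = [spot_frame([(0.0, 0.0), (5000.0, 0.0), (850.0, 3000.0), (5850.0, 3000.0)])]
        null = NullEnsemble(n_sims=1, seed=0, tables=tables)
        hist = nn_compare(spot_frame(pts), null)
        assert hist.ks_statistic == 1.0

    def test_observed_from_same_engine_is_not_rejected(self):
        """Structureless spots vs the null: KS p > 0.05 in >= 90% of seeds."""
        g = GridGeometry(128, 128)
        rng = np.random.default_rng(0)
        mask = np.zeros((128, 128), bool)
        mask[40:46, 10:120] = True
        mask[70:76, 10:120] = True
        ok = 0
        for seed in range(10):
            obs = simulate_random_placement(120, mask, g, 1, seed=1000 + seed).tables[0]
            null = simulate_random_placement(120, mask, g, 25, seed=2000 + seed)
            hist = nn_compare(obs, null)
            ok += hist.ks_p > 0.05
        assert ok >= 9

    def test_clustered_pairs_rejected(self):
        """Spots laid out as 200 nm pairs concentrate the first bin and
        drive the KS p-value far below 0.01."""
        g = GridGeometry(256, 256)
        mask = np.zeros((256, 256), bool)
        mask[100:110, 5:250] = True
        base = simulate_random_placement(100, mask, g, 1, seed=5).tables[0]
        paired = spot_frame(
            [(x, y) for x, y in zip(base.x_nm, base.y_nm)]
            + [(x + 200.0, y) for x, y in zip(base.x_nm, base.y_nm)]
        )
        null = simulate_random_placement(200, mask, g, 25, seed=6)
        hist = nn_compare(paired, null)
        assert hist.ks_p < 0.01
        first = hist.table.iloc[0]
        assert first.observed_fraction > first.null_fraction

    def test_counts_and_bin_layout(self):
        g = GridGeometry(64, 64)
        mask = np.ones((64, 64), bool)
        obs = simulate_random_placement(30, mask, g, 1, seed=1).tables[0]
        null = simulate_random_placement(30, mask, g, 4, seed=2)
        hist = nn_compare(obs, null)
        assert hist.n_observed_distances == 30
        assert hist.n_null_distances == 120
        assert len(hist.table) == 10  # nine 500-nm bins plus overflow
        assert hist.table.bin_lo_nm.iloc[-1] == 4500.0 and np.isinf(hist.table.bin_hi_nm.iloc[-1])
        assert hist.table.observed_fraction.sum() == pytest.approx(1.0)
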