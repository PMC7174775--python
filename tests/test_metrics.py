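"""Repeatability, similarity, PCA dimensionality and activation summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from scipy.linalg import hadamard

from hdemg.errors import ParameterError, ZeroVarianceError
from hdemg.heatmap import Heatmap
from hdemg.metrics import (
    activation_summary,
    average_similarity,
    gesture_similarity,
    pca_dimensionality,
    repeatability,
)
from hdemg.synth import make_spatial_template


def _hm(values, kind="normalized", gesture="g", rep=0):
    return Heatmap(np.asarray(values, dtype=float), kind, gesture, rep)


def _random_maps(rng, n, gesture="g"):
    return [_hm(np.abs(rng.normal(size=(8, 8))), gesture=gesture, rep=i) for i in range(n)]


class TestRepeatability:
    def test_ten_identical_maps_give_45_unit_pairs(self, rng):
        base = np.abs(rng.normal(size=(8, 8)))
        sim = repeatability([_hm(base, rep=i) for i in range(10)])
        assert sim.n_unique_pairs == 45
        assert sim.pair_values().shape == (45,)
        assert np.allclose(sim.pair_values(), 1.0)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_constant_offset_gives_r2_of_one(self, rng):
        base = np.abs(rng.normal(size=(8, 8)))
        sim = repeatability([_hm(base), _hm(base + 3.0)])
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_zero_variance_map_names_the_repetition(self, rng):
        maps = _random_maps(rng, 3)
        maps[1] = _hm(np.full((8, 8), 0.7), rep=1)
        with pytest.raises(ZeroVarianceError, match="1"):
            repeatability(maps)

    def test_values_are_bounded_and_symmetric(self, rng):
        sim = repeatability(_random_maps(rng, 6))
        assert np.all(sim.values >= 0) and np.all(sim.values <= 1)
        assert np.allclose(sim.values, sim.values.T)

    @settings(deadline=None, max_examples=11, suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(n=st.integers(2, 12))
    def test_pair_count_is_n_choose_2(self, rng, n):
        sim = repeatability(_random_maps(rng, n))
        assert sim.n_unique_pairs == n * (n - 1) // 2
        assert sim.pair_values().shape == (n * (n - 1) // 2,)


class TestGestureSimilarity:
    def test_seven_gestures_give_21_pairs(self, rng):
        maps = [_hm(np.abs(rng.normal(size=(8, 8))), gesture=f"g{i}") for i in range(7)]
        sim = gesture_similarity(maps)
        assert sim.n_unique_pairs == 21
        assert sim.labels == [f"g{i}" for i in range(7)]

    def test_duplicated_gesture_pair_has_unit_entry(self, rng):
        base = np.abs(rng.normal(size=(8, 8)))
        maps = [_hm(base, gesture="a"), _hm(base, gesture="b"),
                _hm(np.abs(rng.normal(size=(8, 8))), gesture="c")]
        sim = gesture_similarity(maps)
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_narrow_templates_are_nearly_uncorrelated(self, grid):
        centers = [(0, 1.5), (2.7, 5), (5.3, 1.5), (1.3, 5), (4, 2.5), (6.6, 5), (2, 3.5)]
        maps = [
            _hm(make_spatial_template(grid, c, 0.5, 1.0).amplitudes, gesture=f"g{i}")
            for i, c in enumerate(centers)
        ]
        sim = gesture_similarity(maps)
        off = sim.pair_values()
        assert np.all(off < 0.05)

    def test_group_average_matrix(self, rng):
        mats = []
        for _ in range(3):
            maps = [_hm(np.abs(rng.normal(size=(8, 8))), gesture=f"g{i}") for i in range(4)]
            mats.append(gesture_similarity(maps))
        avg = average_similarity(mats)
        assert np.allclose(avg.values, np.mean([m.values for m in mats], axis=0))
        assert np.allclose(np.diag(avg.values), 1.0)


class TestPCADimensionality:
    def test_rank_one_collection(self, rng):
        base = np.abs(rng.normal(size=(8, 8)))
        maps = [_hm(base + 1e-12 * rng.normal(size=(8, 8)), rep=i) for i in range(70)]
        res = pca_dimensionality(maps)
        assert res.n_pcs_90 == 1
        assert res.ve[0] == pytest.approx(1.0, abs=1e-6)

    def test_five_orthogonal_equal_power_patterns(self):
        """Orthogonal equal-power design: maps 1 + 0.5*h_i with Hadamard rows.

        After centering, the 5 pattern directions are exactly orthogonal with
        equal power, so each of the five components explains 20%.
        """
        h = hadamard(64).astype(float)
        maps = []
        for i in range(5):
            pattern = 1.0 + 0.5 * h[i + 1]  # row 0 is constant; skip it
            maps.extend([_hm(pattern.reshape(8, 8), rep=r) for r in range(14)])
        res = pca_dimensionality(maps)
        assert res.n_pcs_90 == 5
        assert np.allclose(res.ve[:5], 0.2, atol=1e-9)
        assert np.all(res.ve[5:] < 1e-12)

    def test_planted_rank_equals_nonzero_components(self, rng):
        h = hadamard(64).astype(float)
        for k in (2, 4, 6):
            maps = []
            for i in range(k):
                maps.extend(
                    [_hm((1 + 0.3 * h[i + 1]).reshape(8, 8)) for _ in range(3)]
                )
            res = pca_dimensionality(maps)
            assert int(np.sum(res.ve > 1e-12)) == k

    def test_cumulative_ve_properties(self, rng):
        maps = _random_maps(rng, 30)
        res = pca_dimensionality(maps)
        assert np.all(np.diff(res.cumulative_ve) >= -1e-12)
        assert res.cumulative_ve[-1] == pytest.approx(1.0, abs=1e-9)
        assert res.ve.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.ve >= 0)

    def test_matches_sklearn_pca(self, rng):
        from sklearn.decomposition import PCA

        maps = _random_maps(rng, 20)
        res = pca_dimensionality(maps)
        x = np.stack([m.vector() for m in maps], axis=1)
        ref = PCA().fit(x - x.mean(axis=0))  # same column-centred orientation
        assert np.allclose(res.ve[: len(ref.explained_variance_ratio_)],
                           ref.explained_variance_ratio_, atol=1e-9)

    def test_transposed_orientation_flag(self, rng):
        maps = _random_maps(rng, 20)
        res_t = pca_dimensionality(maps, electrodes_as_observations=False)
        assert res_t.cumulative_ve[-1] == pytest.approx(1.0)

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ParameterError):
            pca_dimensionality(_random_maps(rng, 1))
        maps = [_hm(np.full((8, 8), 0.5)) for _ in range(5)]
        with pytest.raises(ZeroVarianceError):
            pca_dimensionality(maps)


class TestActivationSummary:
    def test_single_value_has_zero_sd(self):
        df = pd.DataFrame(
            [{"group": "dmd", "max_normalized": 0.5, "max_absolute": 30.0}]
        )
        out = activation_summary(df)
        assert out.loc[0, "mean_max_normalized"] == 0.5
        assert out.loc[0, "sd_max_normalized"] == 0.0
        assert out.loc[0, "n"] == 1

    def test_cohort_counts_210_and_560(self, rng):
        rows = []
        for group, n_part in (("dmd", 3), ("healthy", 8)):
            for p in range(n_part):
                for g in range(7):
                    for r in range(10):
                        rows.append({"group": group,
                                     "max_normalized": rng.uniform(),
                                     "max_absolute": rng.uniform() * 100})
        out = activation_summary(pd.DataFrame(rows)).set_index("group")
        assert out.loc["dmd", "n"] == 210
        assert out.loc["healthy", "n"] == 560

    def test_missing_columns_rejected(self):
        with pytest.raises(ParameterError):
            activation_summary(pd.DataFrame([{"group": "x", "max_normalized": 1.0}]))
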