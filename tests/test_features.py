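import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tensorspec.exceptions import (
    BandError,
    ConfigError,
    DegenerateInputError,
    SelectionError,
)
from tensorspec.features import (
    aggregate_profiles,
    class_difference_profile,
    extract_feature_matrix,
    profiles_from_sparse,
    restrict_band,
    select_characteristic,
)
from tensorspec.io import SpectrumSet, WavenumberGrid, make_grid
from tensorspec.trpca import SpectralTensor


def _sset(n_samples, grid):
    rng = np.random.default_rng(0)
    return SpectrumSet(grid=grid, absorbance=rng.normal(size=(n_samples, grid.n_points)),
                       labels=np.array(["I"] * n_samples, dtype=object))


class TestRestrictBand:
    def test_inclusive_lattice_count(self):
        s = _sset(2, make_grid(12500, 4000, 4))
        out = restrict_band(s, 8000, 4500)
        assert out.n_points == (8000 - 4500) // 4 + 1 == 876
        assert out.grid.values[0] == 8000.0 and out.grid.values[-1] == 4500.0

    def test_full_band_is_identity(self):
        s = _sset(2, make_grid(6000, 5000, 10))
        out = restrict_band(s, 6000, 5000)
        assert out.isclose(s, atol=0.0)

    def test_disjoint_band_errors(self):
        s = _sset(1, make_grid(12500, 4000, 4))
        with pytest.raises(BandError):
            restrict_band(s, 100, 50)

    def test_tensor_band_restriction(self):
        grid = make_grid(6000, 5000, 10)
        T = SpectralTensor(np.random.default_rng(1).normal(size=(100, 4, 2)),
                           grid, ["I", "II"])
        out = restrict_band(T, 5800, 5300)
        assert out.shape == (51, 4, 2)
        assert out.grid.values[0] == 5800.0


class TestProfiles:
    def test_zero_matrix(self):
        assert np.array_equal(class_difference_profile(np.zeros((4, 3))), np.zeros(4))

    def test_single_column_abs(self):
        assert class_difference_profile(np.array([[-2.0], [3.0]])).tolist() == [2.0, 3.0]

    def test_two_by_two_oracle(self):
        assert class_difference_profile(np.array([[1.0, -2.0], [0.0, 3.0]])).tolist() == [3.0, 3.0]

    def test_aggregate_examples(self):
        assert aggregate_profiles(np.array([[3.0, 3.0]])).tolist() == [3.0, 3.0]
        assert aggregate_profiles(np.array([[3.0, 3.0], [1.0, 0.0]])).tolist() == [4.0, 3.0]
        assert aggregate_profiles(np.zeros((3, 4))).tolist() == [0.0] * 4

    def test_profiles_from_sparse_column_sum_identity(self):
        grid = make_grid(6000, 5960, 10)
        E = SpectralTensor(np.random.default_rng(2).normal(size=(4, 5, 3)), grid,
                           ["a", "b", "c"])
        prof = profiles_from_sparse(E)
        assert np.array_equal(prof.Q, prof.P.sum(axis=0))
        order = prof.descending_order()
        assert np.all(np.diff(prof.Q[order]) <= 0)

    @given(st.integers(0, 20))
    def test_sample_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.normal(size=(6, 8))
        perm = rng.permutation(8)
        assert np.allclose(class_difference_profile(E), class_difference_profile(E[:, perm]))

    @given(st.floats(0.1, 50.0))
    def test_scale_linearity(self, alpha):
        E = np.random.default_rng(1).normal(size=(3, 5, 2))
        P = np.stack([class_difference_profile(E[:, :, h]) for h in range(2)])
        Pa = np.stack([class_difference_profile(alpha * E[:, :, h]) for h in range(2)])
        assert np.allclose(aggregate_profiles(Pa), alpha * aggregate_profiles(P), rtol=1e-9)


class TestSelection:
    grid4 = WavenumberGrid(nu_max=5000, resolution=10, n_points=2)

    def test_normalized_keeps_both(self):
        cs = select_characteristic(np.array([4.0, 3.0]), self.grid4, threshold=0.2)
        assert cs.indices.tolist() == [0, 1]
        assert np.allclose(cs.scores, [1.0, 0.75])

    def test_normalized_drops_small(self):
        cs = select_characteristic(np.array([1.0, 0.1]), self.grid4, threshold=0.2)
        assert cs.indices.tolist() == [0]

    def test_exact_threshold_excluded(self):
        cs = select_characteristic(np.array([1.0, 0.2]), self.grid4, threshold=0.2)
        assert cs.indices.tolist() == [0]

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            select_characteristic(np.zeros(2), self.grid4, threshold=0.2)

    def test_empty_selection_advises(self):
        with pytest.raises(SelectionError, match="lower the threshold"):
            select_characteristic(np.array([1.0, 0.5]), self.grid4, threshold=1.0)

    def test_raw_thresholding_flag(self):
        cs = select_characteristic(np.array([0.5, 0.1]), self.grid4, threshold=0.2,
                                   normalize=False)
        assert cs.indices.tolist() == [0] and not cs.normalized

    @given(st.integers(0, 10), st.floats(0.05, 0.5), st.floats(0.5, 0.95))
    def test_threshold_monotonicity(self, seed, lo, hi):
        Q = np.random.default_rng(seed).random(30)
        grid = WavenumberGrid(nu_max=6000, resolution=10, n_points=30)
        low = set(select_characteristic(Q, grid, threshold=lo).indices)
        try:
            high = set(select_characteristic(Q, grid, threshold=hi).indices)
        except SelectionError:
            high = set()
        assert high <= low


class TestExtract:
    def test_named_columns(self):
        grid = WavenumberGrid(nu_max=5000, resolution=10, n_points=4)
        s = SpectrumSet(grid=grid, absorbance=np.array([[0., 1., 2., 3.], [4., 5., 6., 7.]]),
                        labels=np.array(["I", "II"], dtype=object))
        cs = select_characteristic(np.array([0.0, 1.0, 0.0, 0.9]), grid, threshold=0.2)
        X = extract_feature_matrix(s, cs)
        assert X.tolist() == [[1.0, 3.0], [5.0, 7.0]]

    def test_all_indices_is_identity(self):
        grid = WavenumberGrid(nu_max=5000, resolution=10, n_points=3)
        s = _sset(2, grid)
        cs = select_characteristic(np.array([1.0, 0.9, 0.8]), grid, threshold=0.2)
        assert np.array_equal(extract_feature_matrix(s, cs), s.absorbance)

    def test_out_of_range_index(self):
        grid = WavenumberGrid(nu_max=5000, resolution=10, n_points=8)
        s = _sset(1, WavenumberGrid(nu_max=5000, resolution=10, n_points=3))
        cs = select_characteristic(np.array([0.0] * 7 + [1.0]), grid, threshold=0.2)
        with pytest.raises(ConfigError):
            extract_feature_matrix(s, cs)
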