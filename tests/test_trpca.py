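import numpy as np
import pytest

from oracles import bcirc_tensor_svt, matrix_rpca_ialm, planted_tensor
from tensorspec.exceptions import ConfigError, DataError
from tensorspec.io import WavenumberGrid
from tensorspec.trpca import (
    SpectralTensor,
    TRPCAConfig,
    default_eta,
    load_tensor,
    matrix_svt,
    save_tensor,
    soft_threshold,
    tensor_svt,
    trpca_decompose,
)


def _tensor(data):
    data = np.asarray(data, dtype=float)
    grid = WavenumberGrid(nu_max=6000.0, resolution=10.0, n_points=data.shape[0])
    return SpectralTensor(data=data, grid=grid,
                          class_order=[f"c{i}" for i in range(data.shape[2])])


class TestDefaultEta:
    def test_unit_tensor(self):
        assert default_eta(1, 1, 1, "sqrt") == 1.0
        assert default_eta(1, 1, 1, "literal") == 1.0

    def test_paper_scale_tensor(self):
        assert default_eta(2125, 150, 5, "sqrt") == pytest.approx(9.7014e-3, rel=1e-4)
        assert default_eta(2125, 150, 5, "literal") == pytest.approx(9.4118e-5, rel=1e-4)

    def test_invalid(self):
        with pytest.raises(ConfigError):
            default_eta(0, 1, 1)


class TestProxOperators:
    def test_soft_threshold_examples(self):
        assert np.allclose(soft_threshold(np.array([-3.0, 0.5, 2.0]), 1.0), [-2.0, 0.0, 1.0])
        x = np.array([0.3, -1.2, 4.0])
        assert np.array_equal(soft_threshold(x, 0.0), x)
        assert np.allclose(soft_threshold(np.array([1.0, -1.0]), 5.0), 0.0)
        with pytest.raises(ConfigError):
            soft_threshold(x, -0.1)

    def test_matrix_svt_diagonal(self):
        out = matrix_svt(np.diag([3.0, 1.0]), 2.0)
        assert np.allclose(out, np.diag([1.0, 0.0]), atol=1e-12)

    def test_matrix_svt_identity_and_annihilation(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(5, 4))
        assert np.allclose(matrix_svt(M, 0.0), M, atol=1e-10)
        smax = np.linalg.norm(M, 2)
        assert np.allclose(matrix_svt(M, smax + 1e-9), 0.0, atol=1e-10)

    def test_matrix_svt_rejects_nonfinite(self):
        with pytest.raises(DataError):
            matrix_svt(np.array([[np.nan, 1.0]]), 0.5)


class TestTensorSvt:
    def test_single_class_reduces_to_matrix_svt(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(6, 5))
        out = tensor_svt(_tensor(M[:, :, None]), 0.7)
        assert np.allclose(out.data[:, :, 0], matrix_svt(M, 0.7), atol=1e-10)

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        T = _tensor(rng.normal(size=(5, 4, 3)))
        assert np.allclose(tensor_svt(T, 0.0).data, T.data, atol=1e-10)

    @pytest.mark.parametrize("shape", [(6, 5, 2), (8, 6, 5), (4, 7, 3)])
    @pytest.mark.parametrize("tau", [0.3, 1.5])
    def test_matches_block_circulant_oracle(self, shape, tau):
        rng = np.random.default_rng(hash(shape) % 2**31)
        data = rng.normal(size=shape)
        ours = tensor_svt(_tensor(data), tau).data
        assert np.allclose(ours, bcirc_tensor_svt(data, tau), atol=1e-9)

    def test_repeated_slices(self):
        # identical frontal slices concentrate in the zero-frequency band;
        # the oracle is the ground truth for the resulting prox
        M = np.random.default_rng(2).normal(size=(6, 5))
        data = np.repeat(M[:, :, None], 4, axis=2)
        ours = tensor_svt(_tensor(data), 0.5).data
        ref = bcirc_tensor_svt(data, 0.5)
        assert np.allclose(ours, ref, atol=1e-9)
        # output slices stay identical by symmetry
        assert np.allclose(ours[:, :, 0], ours[:, :, 3], atol=1e-9)


class TestDecomposition:
    def test_zero_tensor(self):
        res = trpca_decompose(_tensor(np.zeros((4, 3, 2))))
        assert res.converged and res.iterations == 1
        assert np.all(res.A.data == 0) and np.all(res.E.data == 0)

    def test_planted_low_rank_plus_sparse(self):
        D, A0, E0 = planted_tensor(60, 40, 3, 0.02, np.random.default_rng(7))
        res = trpca_decompose(_tensor(D))
        assert res.converged
        assert np.linalg.norm(res.A.data - A0) / np.linalg.norm(A0) < 1e-3
        assert np.linalg.norm(res.E.data - E0) / np.linalg.norm(E0) < 1e-3

    def test_single_slice_matches_matrix_rpca(self):
        rng = np.random.default_rng(11)
        L = rng.normal(size=(60, 3)) @ rng.normal(size=(3, 40))
        S = (rng.random((60, 40)) < 0.05) * rng.choice([-2.0, 2.0], size=(60, 40))
        D = L + S
        lam = default_eta(60, 40, 1)
        A_ref, _ = matrix_rpca_ialm(D, lam)
        res = trpca_decompose(_tensor(D[:, :, None]))
        rel = np.linalg.norm(res.A.data[:, :, 0] - A_ref) / np.linalg.norm(A_ref)
        assert rel < 1e-4

    def test_exact_split_at_convergence(self):
        D, _, _ = planted_tensor(30, 20, 3, 0.05, np.random.default_rng(5))
        cfg = TRPCAConfig()
        res = trpca_decompose(_tensor(D), cfg)
        gap = np.linalg.norm(D - res.A.data - res.E.data) / np.linalg.norm(D)
        assert res.converged and gap <= cfg.tol

    def test_residual_monotone_after_warmup(self):
        D, _, _ = planted_tensor(40, 30, 3, 0.03, np.random.default_rng(8))
        res = trpca_decompose(_tensor(D))
        h = res.residual_history
        assert all(h[i + 1] <= h[i] * (1 + 1e-9) for i in range(5, len(h) - 1))

    def test_scaling_equivariance(self):
        D, _, _ = planted_tensor(30, 20, 3, 0.05, np.random.default_rng(9))
        cfg = TRPCAConfig(tol=1e-9)
        base = trpca_decompose(_tensor(D), cfg)
        scaled = trpca_decompose(_tensor(7.0 * D), cfg)
        relA = np.linalg.norm(scaled.A.data - 7.0 * base.A.data) / np.linalg.norm(7.0 * base.A.data)
        relE = np.linalg.norm(scaled.E.data - 7.0 * base.E.data) / max(np.linalg.norm(7.0 * base.E.data), 1e-30)
        assert relA < 1e-8 and relE < 1e-8

    def test_sparsity_weight_monotonically_shrinks_E(self):
        D, _, _ = planted_tensor(30, 20, 3, 0.05, np.random.default_rng(10))
        l1 = [
            np.abs(trpca_decompose(_tensor(D), TRPCAConfig(eta=e)).E.data).sum()
            for e in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(l1, l1[1:]))

    def test_nonconvergence_warns_not_raises(self):
        D, _, _ = planted_tensor(20, 15, 2, 0.05, np.random.default_rng(12))
        with pytest.warns(UserWarning, match="did not reach"):
            res = trpca_decompose(_tensor(D), TRPCAConfig(max_iter=3))
        assert not res.converged and res.iterations == 3


def test_tensor_container_round_trip(tmp_path):
    T = _tensor(np.random.default_rng(1).normal(size=(6, 4, 3)))
    path = save_tensor(T, tmp_path / "t.npz")
    back = load_tensor(path)
    assert np.array_equal(back.data, T.data)
    assert back.grid.isclose(T.grid) and back.class_order == T.class_order
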