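import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls as scipy_nnls

from hsmcr.decompose import (
    Constraints,
    estimate_presence,
    lack_of_fit,
    match_components,
    mcr_als_fit,
    nnls_multi,
    select_rank,
    simplisma_init,
    svd_scree,
)
from hsmcr.multiset import augment, refold


def brute_force_nnls(A, b):
    """Active-set enumeration oracle: try every passive subset."""
    k = A.shape[1]
    best_x, best_r = np.zeros(k), np.linalg.norm(b)
    for mask in itertools.product([False, True], repeat=k):
        passive = np.flatnonzero(mask)
        if passive.size == 0:
            continue
        x_p, *_ = np.linalg.lstsq(A[:, passive], b, rcond=None)
        if np.any(x_p < -1e-12):
            continue
        x = np.zeros(k)
        x[passive] = np.clip(x_p, 0, None)
        r = np.linalg.norm(A @ x - b)
        if r < best_r - 1e-12:
            best_x, best_r = x, r
    return best_x, best_r


class TestNNLS:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m, k = 12, rng.integers(2, 7)
        A = rng.normal(size=(m, k))
        B = rng.normal(size=(m, 4))
        X = nnls_multi(A, B)
        for j in range(4):
            x_bf, r_bf = brute_force_nnls(A, B[:, j])
            r = np.linalg.norm(A @ X[:, j] - B[:, j])
            assert r == pytest.approx(r_bf, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        A = rng.normal(size=(20, 6))
        B = rng.normal(size=(20, 8))
        X = nnls_multi(A, B)
        for j in range(8):
            x_sp, r_sp = scipy_nnls(A, B[:, j])
            assert np.linalg.norm(A @ X[:, j] - B[:, j]) == pytest.approx(r_sp, abs=1e-8)

    def test_nonnegative_and_1d(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(10, 4))
        b = rng.normal(size=10)
        x = nnls_multi(A, b)
        assert x.shape == (4,)
        assert np.all(x >= 0)


class TestSVDRank:
    def test_noiseless_rank_equals_components(self, small_scene):
        _, images, _ = small_scene
        sv = svd_scree(augment(images))
        assert np.sum(sv > 1e-8 * sv[0]) == 3

    def test_zero_matrix(self):
        sv = svd_scree(np.zeros((5, 4)))
        np.testing.assert_array_equal(sv, 0.0)

    def test_duplicate_image_keeps_rank(self, small_scene):
        _, images, _ = small_scene
        sv1 = svd_scree(augment(images))
        sv2 = svd_scree(augment(images + [images[0].copy()]))
        rank1 = np.sum(sv1 > 1e-8 * sv1[0])
        rank2 = np.sum(sv2 > 1e-8 * sv2[0])
        assert rank1 == rank2

    def test_gap_worked_example(self):
        assert select_rank(np.array([100.0, 50.0, 40.0, 0.1, 0.08]), method="gap") == 3

    def test_manual(self):
        assert select_rank(np.array([3.0, 2.0, 1.0]), method="manual", k=5) == 5

    def test_noise_floor(self, small_scene):
        params, images, truth = small_scene
        mset = augment(images)
        rng = np.random.default_rng(0)
        sd = 1e-3 * mset.data.max()
        noisy = mset.data + rng.normal(0, sd, size=mset.data.shape)
        sv = svd_scree(noisy)
        k = select_rank(sv, noise_sd=sd, method="noise_floor", matrix_shape=noisy.shape)
        assert k == 3

    def test_gap_needs_two(self):
        with pytest.raises(ValueError):
            select_rank(np.array([1.0]), method="gap")

    def test_descending_required(self):
        with pytest.raises(ValueError):
            select_rank(np.array([1.0, 2.0]), method="gap")


def brute_force_purity1(data, alpha_pct):
    mu = data.mean(axis=1)
    sigma = data.std(axis=1)
    alpha = alpha_pct / 100.0 * mu.max()
    return sigma / (mu + alpha)


class TestSimplisma:
    def make_planted(self):
        """Mixtures of 2 components with one pure pixel of each planted."""
        rng = np.random.default_rng(0)
        s1 = np.abs(np.sin(np.linspace(0, 3, 40))) + 0.05
        s2 = np.abs(np.cos(np.linspace(0, 5, 40))) + 0.05
        rows = []
        for _ in range(30):
            a = rng.uniform(0.3, 0.7)
            rows.append(a * s1 + (1 - a) * s2)
        rows[7] = s1.copy()
        rows[19] = s2.copy()
        return np.array(rows), {7, 19}

    def test_pure_pixels_selected_first(self):
        data, pure = self.make_planted()
        _, idx = simplisma_init(data, 2)
        assert set(idx) == pure

    def test_k1_matches_exhaustive(self):
        data, _ = self.make_planted()
        _, idx = simplisma_init(data, 1, alpha_pct=1.0)
        assert idx[0] == int(np.argmax(brute_force_purity1(data, 1.0)))

    def test_constant_row_not_selected(self):
        rng = np.random.default_rng(1)
        data = rng.random((10, 20))
        data[4] = 0.5  # zero variance row
        _, idx = simplisma_init(data, 3, alpha_pct=1.0)
        assert 4 not in idx
        p = brute_force_purity1(data, 1.0)
        assert np.isfinite(p[4]) and p[4] == 0.0

    def test_k_exceeding_rank_warns(self):
        rng = np.random.default_rng(2)
        u = rng.random((20, 2))
        v = rng.random((2, 15))
        with pytest.warns(UserWarning, match="rank"):
            simplisma_init(u @ v, 5)

    def test_output_normalized_nonnegative(self):
        data, _ = self.make_planted()
        S0, _ = simplisma_init(data, 2)
        assert np.all(S0 >= 0)
        np.testing.assert_allclose(np.linalg.norm(S0, axis=1), 1.0, atol=1e-12)

    def test_k_bounds(self):
        with pytest.raises(ValueError):
            simplisma_init(np.ones((3, 4)), 0)


class TestLackOfFit:
    def test_zero_residual(self):
        D = np.array([[1.0, 2.0], [3.0, 4.0]])
        C = np.eye(2)
        assert lack_of_fit(D, C, D) == 0.0

    def test_zero_model(self):
        D = np.array([[1.0, 1.0]])
        assert lack_of_fit(D, np.zeros((1, 1)), np.zeros((1, 2))) == 100.0

    def test_worked_example(self):
        D = np.array([[2.0, 0.0], [0.0, 2.0]])
        C = np.eye(2)
        S = np.eye(2)
        assert lack_of_fit(D, C, S) == pytest.approx(50.0, abs=1e-12)

    def test_all_zero_D_errors(self):
        with pytest.raises(ValueError):
            lack_of_fit(np.zeros((2, 2)), np.eye(2), np.eye(2))


class TestMCRALS:
    def test_true_spectra_init_immediate_fit(self, small_scene):
        _, images, truth = small_scene
        mset = augment(images)
        model = mcr_als_fit(mset, truth.pure_spectra, max_iter=1)
        assert model.lof_trace[0] < 1e-6

    def test_simplisma_init_recovery(self, small_scene):
        _, images, truth = small_scene
        mset = augment(images)
        S0, _ = simplisma_init(mset, 3)
        model = mcr_als_fit(mset, S0)
        assert model.lof < 0.1
        _, corrs = match_components(model, truth.pure_spectra)
        assert np.all(corrs > 0.999)

    def test_correspondence_zero_maps(self, small_scene):
        _, images, truth = small_scene
        mset = augment(images)
        presence = np.ones((4, 3), dtype=bool)
        presence[0, 1] = False  # declare component 1 absent in image 1
        model = mcr_als_fit(
            mset, truth.pure_spectra, Constraints(correspondence=presence)
        )
        m = refold(mset, model.C[:, 1], "X1")
        assert np.all(m[np.isfinite(m)] == 0)
        start, end = mset.blocks["X1"]
        assert np.all(model.C[start:end, 1] == 0)

    def test_zero_row_S0_errors(self, small_scene):
        _, images, _ = small_scene
        mset = augment(images)
        S0 = np.ones((2, mset.n_channels))
        S0[1] = 0
        with pytest.raises(ValueError, match="zero row"):
            mcr_als_fit(mset, S0)

    def test_k_exceeds_channels_errors(self, small_scene):
        _, images, _ = small_scene
        mset = augment(images)
        with pytest.raises(ValueError):
            mcr_als_fit(mset, np.ones((mset.n_channels + 1, mset.n_channels)))

    def test_constraint_invariants(self, small_scene):
        _, images, _ = small_scene
        mset = augment(images)
        S0, _ = simplisma_init(mset, 3)
        model = mcr_als_fit(mset, S0, max_iter=8)
        assert np.all(model.C >= 0)
        assert np.all(model.S_t >= 0)
        np.testing.assert_allclose(np.linalg.norm(model.S_t, axis=1), 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_lof_monotone_random_instances(self, seed):
        from hsmcr.io_cube import SpectralImage

        rng = np.random.default_rng(seed)
        axis = np.linspace(1200, 1300, 12)
        images = [
            SpectralImage(
                cube=np.abs(rng.normal(0.5, 0.2, size=(5, 5, 12))),
                axis=axis,
                meta={"section_id": f"X{i}"},
            )
            for i in range(2)
        ]
        mset = augment(images)
        S0, _ = simplisma_init(mset, 3)
        model = mcr_als_fit(mset, S0, tol=0.0, max_iter=15)
        trace = np.asarray(model.lof_trace)
        assert np.all(np.diff(trace) <= 1e-8 * np.maximum(trace[:-1], 1e-30))


class TestEstimatePresence:
    def make_model_multiset(self, C_blocks, k):
        """Assemble a synthetic fitted model from per-image C blocks."""
        from hsmcr.decompose import MCRModel
        from hsmcr.io_cube import SpectralImage

        n = C_blocks[0].shape[0]
        side = int(np.sqrt(n))
        axis = np.linspace(1200, 1250, k + 2)
        images = [
            SpectralImage(
                cube=np.ones((side, side, k + 2)), axis=axis, meta={"section_id": f"X{i + 1}"}
            )
            for i in range(len(C_blocks))
        ]
        mset = augment(images)
        C = np.vstack(C_blocks)
        model = MCRModel(
            C=C, S_t=np.ones((k, k + 2)), presence=None, lof_trace=[1.0], n_iter=1,
            converged=True,
        )
        return model, mset

    def test_truly_absent_flagged_at_default_threshold(self):
        rng = np.random.default_rng(0)
        present = rng.uniform(0.5, 1.0, size=(16, 2))
        blocks = []
        for i in range(3):
            b = rng.uniform(0.5, 1.0, size=(16, 2))
            if i == 0:
                b[:, 1] = rng.uniform(0, 1e-4, size=16)  # ground-truth zeros + tiny noise
            blocks.append(b)
        model, mset = self.make_model_multiset(blocks, 2)
        presence = estimate_presence(model, mset)
        assert not presence[0, 1]
        assert presence[1:, :].all() and presence[0, 0]

    def test_uniform_component_present_everywhere(self):
        blocks = [np.full((9, 1), 0.7) for _ in range(4)]
        model, mset = self.make_model_multiset(blocks, 1)
        assert estimate_presence(model, mset).all()

    def test_zero_threshold_all_present(self):
        rng = np.random.default_rng(1)
        blocks = [rng.random((9, 3)) for _ in range(2)]
        model, mset = self.make_model_multiset(blocks, 3)
        assert estimate_presence(model, mset, rel_threshold=0.0).all()

    def test_at_least_one_per_image(self):
        blocks = [np.full((4, 2), 1.0), np.full((4, 2), 1e-9)]
        model, mset = self.make_model_multiset(blocks, 2)
        presence = estimate_presence(model, mset, rel_threshold=0.5)
        assert presence[1].any()


class TestMatchComponents:
    def test_identity(self, small_scene):
        _, _, truth = small_scene
        perm, corrs = match_components(truth.pure_spectra, truth.pure_spectra)
        np.testing.assert_array_equal(perm, np.arange(3))
        np.testing.assert_allclose(corrs, 1.0, atol=1e-12)

    def test_swap(self, small_scene):
        _, _, truth = small_scene
        swapped = truth.pure_spectra[[1, 0, 2]]
        perm, corrs = match_components(swapped, truth.pure_spectra)
        np.testing.assert_array_equal(perm, [1, 0, 2])
        np.testing.assert_allclose(corrs, 1.0, atol=1e-12)

    def test_matches_factorial_enumeration(self, small_scene):
        _, images, truth = small_scene
        mset = augment(images)
        rng = np.random.default_rng(0)
        noisy = np.clip(
            truth.pure_spectra[[2, 0, 1]] + rng.normal(0, 0.01, truth.pure_spectra.shape),
            0,
            None,
        )
        perm, _ = match_components(noisy, truth.pure_spectra)

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        best, best_total = None, -np.inf
        for p in itertools.permutations(range(3)):
            total = sum(corr(truth.pure_spectra[j], noisy[p[j]]) for j in range(3))
            if total > best_total:
                best, best_total = p, total
        np.testing.assert_array_equal(perm, best)

    def test_k_mismatch_errors(self, small_scene):
        _, _, truth = small_scene
        with pytest.raises(ValueError):
            match_components(truth.pure_spectra[:2], truth.pure_spectra)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_nnls_property(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(3, 15))
    k = int(rng.integers(1, 6))
    A = rng.normal(size=(m, k))
    b = rng.normal(size=m)
    x = nnls_multi(A, b)
    _, r_sp = scipy_nnls(A, b)
    assert np.all(x >= 0)
    assert np.linalg.norm(A @ x - b) <= r_sp + 1e-8
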