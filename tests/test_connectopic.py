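import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.linalg import eigh
from scipy.stats import spearmanr

from connectopath.connectopic import (
    ConnectopicMap,
    ConnectopicMapping,
    Fingerprints,
    GradientTemplate,
    ProcrustesAlignment,
    align_to_template,
    build_group_template,
    connectivity_fingerprints,
    eta2_similarity,
    laplacian_eigenmaps,
    svd_reduce_reference,
)


def eta2_double_loop(a: np.ndarray) -> np.ndarray:
    """Unvectorized oracle for the paired-profile eta-squared formula."""
    v = a.shape[0]
    out = np.empty((v, v))
    for i in range(v):
        for j in range(v):
            m = (a[i] + a[j]) / 2.0
            mbar = m.mean()
            num = np.sum((a[i] - m) ** 2 + (a[j] - m) ** 2)
            den = np.sum((a[i] - mbar) ** 2 + (a[j] - mbar) ** 2)
            out[i, j] = 1.0 if den == 0 else 1.0 - num / den
    np.fill_diagonal(out, 1.0)
    return out


class TestSvdReduce:
    def test_rank_bounded_by_time_points(self, rng):
        red = svd_reduce_reference(rng.standard_normal((100, 500)))
        assert red.rank <= 100

    def test_reconstruction_is_lossless(self, rng):
        x = rng.standard_normal((60, 40))
        red = svd_reduce_reference(x)
        centered = x - x.mean(axis=0)
        assert np.linalg.norm(red.reconstruct() - centered) < 1e-8

    def test_duplicated_column_does_not_raise_rank(self, rng):
        x = rng.standard_normal((50, 20))
        dup = np.column_stack([x, x[:, 3]])
        assert svd_reduce_reference(dup).rank == svd_reduce_reference(x).rank

    def test_constant_columns_dropped_with_warning(self, rng):
        x = rng.standard_normal((30, 5))
        x[:, 2] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            red = svd_reduce_reference(x)
        assert red.kept_columns.tolist() == [0, 1, 3, 4]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            svd_reduce_reference(np.ones((20, 4)))


class TestFingerprints:
    def test_vertex_equal_to_component_correlates_perfectly(self, rng):
        ref = rng.standard_normal((50, 6))
        red = svd_reduce_reference(ref)
        roi = np.column_stack([red.component_ts[:, 0], rng.standard_normal(50)])
        fp = connectivity_fingerprints(roi, red)
        assert fp.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_vertices_share_fingerprint(self, rng):
        ref = rng.standard_normal((40, 5))
        red = svd_reduce_reference(ref)
        v = rng.standard_normal(40)
        fp = connectivity_fingerprints(np.column_stack([v, v]), red)
        np.testing.assert_array_equal(fp.values[0], fp.values[1])

    def test_matches_per_pair_correlation_oracle(self, rng):
        ref = rng.standard_normal((10, 3))
        roi = rng.standard_normal((10, 4))
        red = svd_reduce_reference(ref)
        fp = connectivity_fingerprints(roi, red)
        for v in range(4):
            for j in range(red.rank):
                expected = np.corrcoef(roi[:, v], red.component_ts[:, j])[0, 1]
                assert fp.values[v, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_vertex_named_in_error(self, rng):
        ref = rng.standard_normal((30, 4))
        roi = rng.standard_normal((30, 3))
        roi[:, 1] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            connectivity_fingerprints(roi, svd_reduce_reference(ref))


class TestEta2:
    def test_identical_rows_give_one(self, rng):
        row = rng.standard_normal(8)
        sim = eta2_similarity(np.vstack([row, row, rng.standard_normal(8)]))
        assert sim.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_orthogonal_pair(self):
        # a=(1,0), b=(0,1): numerator 1, denominator 1 -> eta2 = 0
        sim = eta2_similarity(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert sim.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        a = rng.standard_normal((20, 7))
        sim = eta2_similarity(a)
        assert np.abs(sim.values - eta2_double_loop(a)).max() < 1e-10

    def test_bounds_symmetry_and_unit_diagonal(self, rng):
        a = rng.uniform(-1, 1, size=(15, 6))
        s = eta2_similarity(a).values
        assert np.all((s >= 0) & (s <= 1))
        np.testing.assert_array_equal(s, s.T)
        np.testing.assert_array_equal(np.diag(s), np.ones(15))

    def test_one_only_for_equal_rows(self, rng):
        a = rng.standard_normal((12, 5))
        a[3] = a[7]
        s = eta2_similarity(a).values
        iu = np.triu_indices(12, k=1)
        equal_pairs = {(3, 7)}
        for i, j in zip(*iu):
            if (i, j) in equal_pairs:
                assert s[i, j] == pytest.approx(1.0, abs=1e-12)
            else:
                assert s[i, j] < 1.0

    def test_nan_input_rejected(self):
        bad = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="finite"):
            eta2_similarity(bad)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 12), st.integers(2, 8)),
            elements=st.floats(-5, 5, allow_nan=False, width=64),
        )
    )
    def test_similarity_properties_hold_for_arbitrary_fingerprints(self, a):
        """Symmetry, unit diagonal and the [0, 1] range hold for any finite
        fingerprint matrix, and agree with the double-loop oracle."""
        s = eta2_similarity(a).values
        assert np.all((s >= 0) & (s <= 1))
        np.testing.assert_array_equal(s, s.T)
        np.testing.assert_array_equal(np.diag(s), np.ones(a.shape[0]))
        assert np.abs(s - np.clip(eta2_double_loop(a), 0, 1)).max() < 1e-9


def path_graph_weights(n: int) -> np.ndarray:
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    np.fill_diagonal(w, 1.0)  # diagonal is ignored by the eigenmap
    return w


class TestLaplacianEigenmaps:
    def test_path_graph_first_gradient_monotone(self):
        cmap = laplacian_eigenmaps(path_graph_weights(5), k=2)
        g = cmap.gradients[:, 0]
        diffs = np.diff(g)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_eigen_residual_against_dense_solver(self, rng):
        a = rng.uniform(0.1, 1.0, size=(12, 12))
        w = 0.5 * (a + a.T)
        cmap = laplacian_eigenmaps(w, k=4)
        wz = w.copy()
        np.fill_diagonal(wz, 0.0)
        d = np.diag(wz.sum(axis=1))
        lap = d - wz
        for j in range(4):
            v = cmap.gradients[:, j]
            lam = cmap.eigenvalues[j]
            assert np.linalg.norm(lap @ v - lam * (d @ v)) < 1e-8

    def test_matches_dense_generalized_eigensolver(self, rng):
        a = rng.uniform(0.0, 1.0, size=(10, 10))
        w = 0.5 * (a + a.T)
        np.fill_diagonal(w, 0.0)
        d = np.diag(w.sum(axis=1))
        evals = eigh(np.diag(w.sum(axis=1)) - w, d, eigvals_only=True)
        cmap = laplacian_eigenmaps(w, k=3)
        np.testing.assert_allclose(cmap.eigenvalues, evals[1:4], atol=1e-10)

    def test_complete_graph_degenerate_spectrum(self):
        n = 6
        w = np.ones((n, n))
        cmap = laplacian_eigenmaps(w, k=n - 2)
        assert np.ptp(cmap.eigenvalues) < 1e-10
        # every gradient orthogonal (in the degree inner product) to the constant vector
        d = np.full(n, n - 1.0)
        for j in range(cmap.gradients.shape[1]):
            assert abs(np.sum(d * cmap.gradients[:, j])) < 1e-8

    def test_disconnected_graph_lists_component_sizes(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = w[3, 4] = w[4, 3] = 1.0
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            laplacian_eigenmaps(w, k=1)

    def test_asymmetric_matrix_rejected(self, rng):
        w = rng.uniform(0.1, 1.0, size=(6, 6))
        with pytest.raises(ValueError, match="asymmetric"):
            laplacian_eigenmaps(w, k=1)

    def test_epsilon_threshold_must_preserve_connectivity(self):
        w = path_graph_weights(6)
        with pytest.raises(ValueError, match="disconnected"):
            laplacian_eigenmaps(w, k=1, epsilon=2.0)

    def test_gradients_orthogonal_in_degree_inner_product(self, rng):
        a = rng.uniform(0.2, 1.0, size=(15, 15))
        w = 0.5 * (a + a.T)
        cmap = laplacian_eigenmaps(w, k=4)
        wz = w.copy()
        np.fill_diagonal(wz, 0.0)
        d = wz.sum(axis=1)
        g = cmap.gradients
        gram = g.T @ (d[:, None] * g)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestGroupTemplate:
    def test_single_subject_template_matches_subject_map(self, rng):
        a = rng.uniform(0.1, 1.0, size=(10, 10))
        w = 0.5 * (a + a.T)
        tpl = build_group_template([w], k=2)
        single = laplacian_eigenmaps(w, k=2)
        for j in range(2):
            dot = abs(np.dot(tpl.gradients[:, j], single.gradients[:, j]))
            norm = np.linalg.norm(tpl.gradients[:, j]) * np.linalg.norm(single.gradients[:, j])
            assert dot / norm == pytest.approx(1.0, abs=1e-8)

    def test_subject_order_is_irrelevant_bitwise(self, rng):
        mats = [0.5 * (m + m.T) for m in rng.uniform(0.1, 1.0, size=(5, 8, 8))]
        t1 = build_group_template(mats, k=2)
        t2 = build_group_template(mats[::-1], k=2)
        assert t1.gradients.tobytes() == t2.gradients.tobytes()

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            build_group_template([np.eye(4), np.eye(5)], k=1)


class TestProcrustes:
    def test_identity_when_already_aligned(self, rng):
        g = rng.standard_normal((20, 3))
        tpl = GradientTemplate(gradients=g)
        out = align_to_template(ConnectopicMap(g, np.arange(3.0)), tpl)
        assert out.residual == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(out.gradients, g, atol=1e-10)

    def test_sign_flips_recovered(self, rng):
        g = rng.standard_normal((20, 3))
        flipped = g * np.array([-1.0, 1.0, -1.0])
        out = align_to_template(ConnectopicMap(flipped, np.arange(3.0)), GradientTemplate(g))
        assert out.residual == pytest.approx(0.0, abs=1e-10)

    def test_random_rotation_recovered(self, rng):
        g = rng.standard_normal((30, 4))
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        out = align_to_template(ConnectopicMap(g @ q, np.arange(4.0)), GradientTemplate(g))
        assert out.residual < 1e-8
        np.testing.assert_allclose(out.gradients, g, atol=1e-8)

    def test_k_mismatch_rejected(self, rng):
        g = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="gradient count"):
            align_to_template(ConnectopicMap(g, np.arange(3.0)), GradientTemplate(g[:, :2]))

    def test_transformer_api_roundtrip(self, rng):
        g = rng.standard_normal((15, 3))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        aligner = ProcrustesAlignment().fit(g)
        out = aligner.transform(g @ q)
        assert out.aligned and out.residual < 1e-8


class TestEndToEnd:
    def test_full_vs_reduced_reference_consistency(self, strip_mesh, rng):
        """Gradients from fingerprints against the SVD-reduced reference agree
        with gradients from fingerprints against the raw reference columns."""
        from connectopath import GradientSpec, simulate_subject_timeseries

        roi, ref = simulate_subject_timeseries(strip_mesh, GradientSpec(), "control", 200, 21)
        mp = ConnectopicMapping(3).fit(roi, ref, orient=strip_mesh.axis_coordinate)

        # full-reference fingerprints: correlate ROI vertices with every raw column
        rc = roi - roi.mean(axis=0)
        fc = ref - ref.mean(axis=0)
        num = rc.T @ fc
        den = np.outer(np.sqrt((rc**2).sum(0)), np.sqrt((fc**2).sum(0)))
        fp_full = Fingerprints(values=num / den)
        cmap_full = laplacian_eigenmaps(
            eta2_similarity(fp_full), 3, orient=strip_mesh.axis_coordinate
        )
        aligner = ProcrustesAlignment().fit(cmap_full.gradients)
        aligned = aligner.transform(mp.to_map())
        rho = abs(spearmanr(aligned.gradients[:, 0], cmap_full.gradients[:, 0]).statistic)
        assert rho >= 0.99

    def test_zero_variance_vertices_reinserted_as_nan(self, strip_mesh, rng):
        from connectopath import GradientSpec, simulate_subject_timeseries

        roi, ref = simulate_subject_timeseries(strip_mesh, GradientSpec(), "control", 100, 5)
        roi[:, 7] = 1.5
        with pytest.warns(UserWarning, match="zero-variance"):
            mp = ConnectopicMapping(2).fit(roi, ref)
        assert np.all(np.isnan(mp.gradients_[7]))
        assert np.all(np.isfinite(np.delete(mp.gradients_, 7, axis=0)))
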