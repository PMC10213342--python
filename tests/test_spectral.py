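import numpy as np
import pytest
from hypothesis import given, strategies as st

from foldnet import reference, simulate, spectral


class TestGramMatrix:
    def test_orthonormal_rows_give_identity(self):
        X = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        R = spectral.gram_matrix(X)
        np.testing.assert_allclose(R.matrix, np.eye(2), atol=1e-12)

    def test_direct_arithmetic_example(self):
        R = spectral.gram_matrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(R.matrix, [[5.0, 11.0], [11.0, 25.0]])

    def test_non_finite_entries_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            spectral.gram_matrix(np.array([[1.0, np.nan], [1.0, 2.0]]))

    def test_mean_profile_is_recorded(self):
        X = np.array([[1.0, 3.0], [2.0, 4.0]])
        np.testing.assert_allclose(spectral.gram_matrix(X).mean_profile, [2.0, 3.0])


class TestEigendecompose:
    def test_identity_gives_equal_fractions(self):
        sr = spectral.eigendecompose(
            spectral.GramMatrix("g", np.eye(4), n=4)
        )
        np.testing.assert_allclose(sr.fractions, [0.25] * 4, atol=1e-12)

    def test_two_by_two_fractions_match_characteristic_polynomial(self):
        # R = [[5,11],[11,25]]: eigenvalues 15 +/- sqrt(221), trace 30
        R = spectral.gram_matrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        sr = spectral.eigendecompose(R)
        lam = np.array([15.0 + np.sqrt(221.0), 15.0 - np.sqrt(221.0)])
        np.testing.assert_allclose(sr.fractions, lam / 30.0, atol=1e-12)
        np.testing.assert_allclose(sr.fractions, [0.995536, 0.004464], atol=1e-6)

    def test_rank_one_panel_concentrates_fully(self, rng):
        v = rng.uniform(0.5, 2.0, 4)
        X = np.outer(v, rng.uniform(0.5, 2.0, 6))
        sr = spectral.eigendecompose(spectral.gram_matrix(X))
        np.testing.assert_allclose(sr.fractions, [1.0, 0.0, 0.0, 0.0], atol=1e-10)
        assert spectral.leading_fraction(sr) == pytest.approx(1.0)

    def test_zero_panel_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            spectral.eigendecompose(spectral.GramMatrix("g", np.zeros((3, 3)), n=3))

    def test_reconstruction_orthonormality_and_ordering(self, rng):
        for _ in range(20):
            X = rng.uniform(0.0, 3.0, size=(4, rng.integers(4, 10)))
            R = spectral.gram_matrix(X)
            sr = spectral.eigendecompose(R)
            assert np.all(np.diff(sr.fractions) <= 1e-12)
            assert sr.fractions.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(
                sr.vectors_raw.T @ sr.vectors_raw, np.eye(4), atol=1e-8
            )
            recon = sr.vectors_raw @ np.diag(sr.raw_eigenvalues) @ sr.vectors_raw.T
            assert np.linalg.norm(recon - R.matrix) <= 1e-8 * np.linalg.norm(R.matrix)

    def test_report_sign_convention_largest_component_positive(self, rng):
        X = rng.uniform(0.0, 3.0, size=(4, 7))
        sr = spectral.eigendecompose(spectral.gram_matrix(X))
        for k in range(4):
            col = sr.vectors[:, k]
            assert col[np.argmax(np.abs(col))] > 0


class TestSpectralProperties:
    def test_fractions_equal_normalized_squared_singular_values(self, rng):
        for _ in range(30):
            X = rng.standard_normal((4, int(rng.integers(7, 10))))
            sr = spectral.eigendecompose(spectral.gram_matrix(X))
            sv2 = np.linalg.svd(X, compute_uv=False) ** 2
            np.testing.assert_allclose(sr.fractions, sv2 / sv2.sum(), atol=1e-8)

    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_equivariance_of_fractions(self, c, seed):
        X = np.random.default_rng(seed).uniform(0.1, 3.0, (4, 8))
        f1 = spectral.eigendecompose(spectral.gram_matrix(X)).fractions
        f2 = spectral.eigendecompose(spectral.gram_matrix(c * X)).fractions
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_permutation_equivariance(self, rng):
        X = rng.uniform(0.1, 3.0, (4, 8))
        perm = rng.permutation(4)
        a = spectral.eigendecompose(spectral.gram_matrix(X))
        b = spectral.eigendecompose(spectral.gram_matrix(X[perm]))
        np.testing.assert_allclose(a.fractions, b.fractions, atol=1e-9)
        np.testing.assert_allclose(
            np.abs(b.vectors_raw), np.abs(a.vectors_raw[perm]), atol=1e-8
        )

    def test_leading_fraction_bounds(self, rng):
        for _ in range(20):
            X = rng.standard_normal((4, 8))
            lf = spectral.leading_fraction(spectral.eigendecompose(spectral.gram_matrix(X)))
            assert 0.25 - 1e-12 <= lf <= 1.0 + 1e-12


class TestLeadingVectorComparison:
    def test_self_alignment_is_one(self, rng):
        X = rng.uniform(0.1, 3.0, (4, 7))
        sr = spectral.eigendecompose(spectral.gram_matrix(X))
        alignment, reversed_ = spectral.compare_leading_vectors(sr, sr)
        assert alignment == pytest.approx(1.0, abs=1e-12)
        assert not reversed_

    def test_negated_leading_vector_flags_reversal(self):
        V = np.linalg.qr(np.random.default_rng(1).standard_normal((4, 4)))[0]
        a = spectral.SpectralResult.from_table(V)
        b = spectral.SpectralResult.from_table(np.column_stack([-V[:, 0], V[:, 1:]]))
        alignment, reversed_ = spectral.compare_leading_vectors(a, b)
        assert alignment == pytest.approx(-1.0, abs=1e-12)
        assert reversed_

    def test_published_tables_align_negatively(self):
        """The reported control/severe leading eigenvectors point in opposite
        directions: their dot product is ~-0.944."""
        con, sev = reference.reference_spectral_results()
        alignment, reversed_ = spectral.compare_leading_vectors(con, sev)
        assert alignment == pytest.approx(-0.9442, abs=1e-3)
        assert reversed_

    def test_mismatched_panel_sizes_error(self, rng):
        a = spectral.SpectralResult.from_table(np.eye(4))
        b = spectral.SpectralResult.from_table(np.eye(3))
        with pytest.raises(ValueError, match="panel sizes"):
            spectral.compare_leading_vectors(a, b)


class TestTrajectory:
    def test_identical_groups_have_zero_deltas_and_no_reversals(self, rng):
        X = rng.uniform(0.1, 3.0, (4, 7))
        srs = [
            spectral.eigendecompose(spectral.gram_matrix(X, g))
            for g in ("control", "incipient", "moderate", "severe")
        ]
        traj = spectral.coordination_trajectory(srs)
        np.testing.assert_allclose(traj.deltas, 0.0, atol=1e-12)
        assert not traj.reversed_vs_first.any()
        np.testing.assert_allclose(np.diag(traj.alignment), 1.0, atol=1e-12)

    def test_planted_opposite_directions_are_detected(self):
        u = np.ones(4) / 2.0
        cfg = simulate.PanelSimConfig(
            spectra={"control": (0.56, 0.20, 0.14, 0.10), "severe": (0.79, 0.11, 0.06, 0.04)},
            group_sizes={"control": 9, "severe": 7},
            directions={"control": u, "severe": -u},
            noise_scale=0.02,
            seed=4,
        )
        sim = simulate.simulate_panel(cfg)
        srs = [
            spectral.eigendecompose(spectral.gram_matrix(sim.log_matrices[g], g))
            for g in ("control", "severe")
        ]
        alignment, reversed_ = spectral.compare_leading_vectors(*srs)
        assert reversed_ and alignment < -0.9

    def test_needs_two_groups(self):
        sr = spectral.SpectralResult.from_table(np.eye(4))
        with pytest.raises(ValueError):
            spectral.coordination_trajectory([sr])


def test_bootstrap_interval_brackets_point_estimate(rng):
    X = rng.uniform(0.5, 3.0, (4, 9))
    est, lo, hi = spectral.bootstrap_leading_fraction(X, n_boot=200, seed=1)
    assert 0.25 <= lo <= hi <= 1.0
    assert lo - 0.1 <= est <= hi + 0.1
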