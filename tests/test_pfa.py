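import numpy as np
import pytest

from hci.pfa import GlobalPattern, LocalPattern, align_patterns, choose_dim, local_decompose


def make_local(pattern, name="v"):
    d, n = pattern.shape
    return LocalPattern(
        view_name=name,
        center=np.zeros(d),
        loadings=np.eye(d),
        pattern=np.asarray(pattern, dtype=float),
        eigenvalues=np.ones(d),
        dim=d,
        variance_threshold=0.8,
    )


class TestChooseDim:
    @pytest.mark.parametrize(
        "ev, thr, expected",
        [
            ([5, 3, 2], 0.8, 2),     # 8/10 hits the boundary exactly
            ([8, 1, 1], 0.8, 1),     # 8/10 >= 0.8 at the first eigenvalue
            ([10], 0.5, 1),
            ([10], 1.0, 1),
            ([4, 3, 2, 1], 1.0, 4),
        ],
    )
    def test_boundaries(self, ev, thr, expected):
        assert choose_dim(np.array(ev, dtype=float), thr) == expected

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(50):
            ev = np.sort(rng.uniform(0.1, 5.0, size=rng.integers(1, 12)))[::-1]
            thr = rng.uniform(0.05, 1.0)
            total = ev.sum()
            d_oracle = next(
                r + 1 for r in range(len(ev))
                if ev[: r + 1].sum() / total >= thr - 1e-12
            )
            assert choose_dim(ev, thr) == d_oracle

    def test_empty_and_nonpositive_error(self):
        with pytest.raises(ValueError):
            choose_dim(np.array([]), 0.8)
        with pytest.raises(ValueError):
            choose_dim(np.array([1.0, 0.0]), 0.8)


class TestLocalDecompose:
    def test_exact_rank_one(self, rng):
        u = rng.normal(size=8)
        v = rng.normal(size=10)
        W = np.outer(u, v) + rng.normal(size=(8, 1))  # plus constant rows
        lp = local_decompose(W, 0.8)
        assert lp.dim == 1
        assert lp.reconstruction_error == pytest.approx(0.0, abs=1e-18)

    def test_contract_fields(self, rng):
        W = rng.normal(size=(20, 10))
        lp = local_decompose(W, 0.8)
        np.testing.assert_allclose(lp.center, W.mean(axis=1), atol=1e-12)
        # orthonormal loadings
        np.testing.assert_allclose(
            lp.loadings.T @ lp.loadings, np.eye(lp.dim), atol=1e-8
        )
        # pattern is exactly the projection of the centered matrix
        A = W - lp.center[:, None]
        np.testing.assert_allclose(lp.pattern, lp.loadings.T @ A, atol=1e-10)
        # minimal dimension under the cumulative-eigenvalue rule
        ratios = np.cumsum(lp.eigenvalues) / lp.eigenvalues.sum()
        assert ratios[lp.dim - 1] >= 0.8 - 1e-12
        assert lp.dim == 1 or ratios[lp.dim - 2] < 0.8

    def test_reconstruction_error_equals_discarded_spectrum(self, rng):
        """Best rank-d centered approximation: the Frobenius error must
        equal the discarded eigenvalue mass of an independent full
        eigendecomposition of the centered scatter."""
        W = rng.normal(size=(20, 10))
        lp = local_decompose(W, 0.8)
        A = W - W.mean(axis=1)[:, None]
        ev_oracle = np.sort(np.linalg.eigvalsh(A @ A.T))[::-1]
        ev_oracle = ev_oracle[ev_oracle > 1e-10 * ev_oracle[0]]
        recon = lp.center[:, None] + lp.loadings @ lp.pattern
        err = np.sum((W - recon) ** 2)
        expected = ev_oracle[lp.dim:].sum()
        assert err == pytest.approx(expected, rel=1e-6)
        np.testing.assert_allclose(lp.eigenvalues, ev_oracle, rtol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        W = rng.normal(size=(15, 8))
        a = local_decompose(W, 0.9)
        b = local_decompose(W.copy(), 0.9)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for col in a.loadings.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_degenerate_view_errors(self):
        with pytest.raises(ValueError, match="degenerate view"):
            local_decompose(np.ones((5, 4)), 0.8)


class TestAlignPatterns:
    def test_single_view_identity(self, rng):
        lp = make_local(rng.normal(size=(3, 12)))
        gp = align_patterns([lp])
        np.testing.assert_array_equal(gp.pattern, lp.pattern)
        assert gp.view_weights.tolist() == [1.0]
        assert gp.residuals.tolist() == [0.0]
        assert gp.converged

    def test_three_identical_views(self, rng):
        P = rng.normal(size=(4, 15))
        gp = align_patterns([make_local(P, f"v{i}") for i in range(3)])
        # identical views: equal thirds, zero residual, consensus equal to
        # the shared pattern up to the common normalization scale
        np.testing.assert_allclose(gp.view_weights, np.ones(3) / 3, atol=1e-10)
        np.testing.assert_allclose(gp.residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            gp.pattern / np.linalg.norm(gp.pattern),
            P / np.linalg.norm(P),
            atol=1e-8,
        )

    def test_recovers_planted_pattern_from_noisy_rotations(self, rng):
        """Three noisy rotations of a planted 2-D pattern: the consensus
        must reproduce the planted sample geometry (distance correlation
        ~1) despite each view being arbitrarily rotated."""
        base = rng.normal(size=(2, 40))
        views = []
        for i in range(3):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            views.append(make_local(R @ base + rng.normal(0, 0.05, (2, 40)), f"v{i}"))
        gp = align_patterns(views)
        from scipy.spatial.distance import pdist

        db, dy = pdist(base.T), pdist(gp.pattern.T)
        assert np.corrcoef(db, dy)[0, 1] > 0.99

    def test_objective_monotone_and_weights_normalized(self, rng):
        views = [make_local(rng.normal(size=(3, 20)), f"v{i}") for i in range(4)]
        gp = align_patterns(views)
        assert np.all(np.diff(gp.objective_history) <= 1e-9)
        assert gp.view_weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(gp.view_weights >= 0)
        assert gp.n_iter <= 100

    def test_mismatched_sample_counts_error(self, rng):
        a = make_local(rng.normal(size=(2, 10)), "a")
        b = make_local(rng.normal(size=(2, 11)), "b")
        with pytest.raises(ValueError, match="sample count"):
            align_patterns([a, b])

    def test_consensus_dimension_defaults_to_smallest_view(self, rng):
        views = [
            make_local(rng.normal(size=(5, 20)), "big"),
            make_local(rng.normal(size=(2, 20)), "small"),
        ]
        gp = align_patterns(views)
        assert gp.dim == 2
        gp2 = align_patterns(views, target_dim=4)
        assert gp2.dim == 4
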