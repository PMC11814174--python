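"""Fisher LDA: scatter matrices, closed form vs eigen solution, Mahalanobis."""

import numpy as np
import pytest
from scipy import linalg

from popsep import (
    PopulationVectorSet,
    SyntheticConfig,
    TimeWindow,
    fisher_separation,
    generate_dataset,
    lda_direction,
    mahalanobis_distance,
    project_1d,
    scatter_matrices,
    separation_timecourse,
    sliding_windows,
)
from popsep.separation import (
    DegenerateScatterError,
    SingularScatterError,
    fisher_criterion,
)


def _vectors(X1, X2):
    """PopulationVectorSet from explicit per-class row blocks (cat, dog)."""
    X = np.vstack([X1, X2])
    y = np.array([0] * len(X1) + [1] * len(X2))
    return PopulationVectorSet(
        matrix=X,
        labels=y,
        image_ids=[f"i{k}" for k in range(len(X))],
        neuron_ids=[f"n{k}" for k in range(X.shape[1])],
        window=TimeWindow(0.0, 100.0),
    )


def _random_instance(rng, n_dim=None, n_per_class=None):
    N = n_dim or rng.integers(2, 7)
    n = n_per_class or rng.integers(N + 3, 40)
    mu1 = rng.uniform(2, 10, N)
    mu2 = mu1 + rng.normal(0, 1.5, N)
    A = rng.normal(0, 1, (N, N))
    X1 = np.abs(mu1 + rng.normal(0, 1, (n, N)) @ A * 0.3)
    X2 = np.abs(mu2 + rng.normal(0, 1, (n, N)) @ A * 0.3)
    return _vectors(X1, X2)


class TestScatterMatrices:
    def test_hand_computed_2d_example(self):
        vs = _vectors(np.array([[0.0, 0.0], [0.0, 2.0]]),
                      np.array([[2.0, 0.0], [2.0, 2.0]]))
        m1, m2, S_W, S_B = scatter_matrices(vs)
        np.testing.assert_array_equal(m1, [0.0, 1.0])
        np.testing.assert_array_equal(m2, [2.0, 1.0])
        np.testing.assert_array_equal(S_B, [[4.0, 0.0], [0.0, 0.0]])
        np.testing.assert_array_equal(S_W, [[0.0, 0.0], [0.0, 4.0]])

    def test_identical_rows_give_zero_within_scatter(self):
        vs = _vectors(np.ones((3, 2)), np.full((3, 2), 4.0))
        m1, m2, S_W, S_B = scatter_matrices(vs)
        np.testing.assert_array_equal(S_W, np.zeros((2, 2)))

    def test_trace_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vs = _random_instance(rng)
            m1, m2, _, S_B = scatter_matrices(vs)
            assert np.trace(S_B) == pytest.approx(np.sum((m2 - m1) ** 2), rel=1e-12)

    def test_degenerate_class_rejected(self):
        vs = _vectors(np.ones((1, 2)), np.ones((3, 2)))
        with pytest.raises(DegenerateScatterError):
            scatter_matrices(vs)

    def test_scatter_psd_and_rank_one_between(self):
        rng = np.random.default_rng(2)
        vs = _random_instance(rng)
        _, _, S_W, S_B = scatter_matrices(vs)
        assert np.all(linalg.eigvalsh(S_W) > -1e-9)
        assert np.linalg.matrix_rank(S_B, tol=1e-9) <= 1
        np.testing.assert_allclose(S_W, S_W.T)


class TestLdaDirection:
    def test_whitened_case(self):
        w = lda_direction(np.array([0.0, 0.0]), np.array([2.0, 0.0]), np.eye(2), "strict")
        assert abs(w[1]) < 1e-12 and w[0] > 0

    def test_matches_generalised_eigensolver(self):
        """Closed form equals the top eigenvector of S_W^-1 S_B (100 cases)."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            vs = _random_instance(rng)
            m1, m2, S_W, S_B = scatter_matrices(vs)
            w = lda_direction(m1, m2, S_W, "strict")
            evals, evecs = linalg.eigh(S_B, S_W)   # independent eigen route
            v = evecs[:, -1]
            cos = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
            assert cos > 1 - 1e-8
            # J(w_hat) = lambda_max = D^2, all to 1e-8 relative
            D = mahalanobis_distance(m1, m2, S_W, "strict")
            J = fisher_criterion(w, S_W, S_B)
            assert J == pytest.approx(evals[-1], rel=1e-8)
            assert J == pytest.approx(D**2, rel=1e-8)

    def test_maximality_over_random_directions(self):
        rng = np.random.default_rng(4)
        vs = _random_instance(rng, n_dim=4)
        m1, m2, S_W, S_B = scatter_matrices(vs)
        w = lda_direction(m1, m2, S_W, "strict")
        J_opt = fisher_criterion(w, S_W, S_B)
        for _ in range(1000):
            u = rng.normal(size=4)
            assert fisher_criterion(u, S_W, S_B) <= J_opt * (1 + 1e-9)

    def test_normalisation_constraint(self):
        rng = np.random.default_rng(5)
        vs = _random_instance(rng)
        m1, m2, S_W, _ = scatter_matrices(vs)
        w = lda_direction(m1, m2, S_W, "strict")
        assert w @ S_W @ w == pytest.approx(1.0, rel=1e-9)

    def test_singular_scatter_strict_raises(self):
        S_W = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularScatterError, match="rank"):
            lda_direction(np.zeros(2), np.ones(2), S_W, "strict")


class TestMahalanobis:
    def test_identical_means_zero(self):
        assert mahalanobis_distance(np.ones(3), np.ones(3), np.eye(3), "strict") == 0.0

    def test_euclidean_reduction(self):
        D = mahalanobis_distance(np.zeros(2), np.array([2.0, 0.0]), np.eye(2), "strict")
        assert D == pytest.approx(2.0, rel=1e-12)

    def test_affine_invariance(self):
        """D unchanged under invertible linear maps of the feature space."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            vs = _random_instance(rng, n_dim=5)
            m1, m2, S_W, _ = scatter_matrices(vs)
            D = mahalanobis_distance(m1, m2, S_W, "strict")
            A = rng.normal(size=(5, 5)) + 3 * np.eye(5)
            # recompute through the full path on affinely mapped rows
            # (shift keeps rates non-negative; scatter and mean differences
            # are shift-invariant)
            vst = PopulationVectorSet(
                matrix=vs.matrix @ A.T - (vs.matrix @ A.T).min(),
                labels=vs.labels, image_ids=vs.image_ids,
                neuron_ids=vs.neuron_ids, window=vs.window,
            )
            n1, n2, SWt, _ = scatter_matrices(vst)
            Dt = mahalanobis_distance(n1, n2, SWt, "strict")
            assert Dt == pytest.approx(D, rel=1e-6)

    def test_ridge_and_strict_agree_when_well_conditioned(self):
        rng = np.random.default_rng(7)
        vs = _random_instance(rng, n_dim=4, n_per_class=30)
        m1, m2, S_W, _ = scatter_matrices(vs)
        a = mahalanobis_distance(m1, m2, S_W, "strict")
        b = mahalanobis_distance(m1, m2, S_W, "ridge")
        assert b == pytest.approx(a, rel=1e-4)


class TestSeparationResult:
    def test_identities_enforced(self):
        rng = np.random.default_rng(8)
        for inversion in ("strict", "ridge", "pinv"):
            vs = _random_instance(rng, n_dim=4)
            res = fisher_separation(vs, inversion=inversion)
            assert res.criterion == pytest.approx(res.distance**2, rel=1e-8)
            assert res.eigenvalue == pytest.approx(res.criterion, rel=1e-8)
            assert res.distance >= 0
            assert res.inversion == inversion


class TestProjection:
    def test_mean_gap_equals_criterion(self):
        """(projected mean difference)^2 = J(w_hat) under w^T S_W w = 1."""
        rng = np.random.default_rng(9)
        vs = _random_instance(rng)
        m1, m2, S_W, S_B = scatter_matrices(vs)
        w = lda_direction(m1, m2, S_W, "strict")
        proj = project_1d(vs, w)
        gap2 = (proj["dog"]["mean"] - proj["cat"]["mean"]) ** 2
        assert gap2 == pytest.approx(fisher_criterion(w, S_W, S_B), rel=1e-9)

    def test_zero_direction_rejected(self):
        rng = np.random.default_rng(10)
        vs = _random_instance(rng, n_dim=3)
        with pytest.raises(ValueError, match="zero"):
            project_1d(vs, np.zeros(3))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        vs = _random_instance(rng, n_dim=3)
        with pytest.raises(ValueError, match="shape"):
            project_1d(vs, np.ones(5))

    def test_high_contrast_classes_visibly_separated(self):
        cfg = SyntheticConfig(
            n_neurons=15, images_per_category=25, trials_per_image=8,
            category_contrast=6.0, selective_fraction=0.8,
            latency_mean=40.0, latency_sd=5.0, seed=51,
        )
        ds = generate_dataset(cfg)
        from popsep import population_vectors

        vs = population_vectors(ds, TimeWindow(150.0, 100.0))
        res = fisher_separation(vs, inversion="ridge")
        proj = project_1d(vs, res.direction)
        gap = proj["dog"]["mean"] - proj["cat"]["mean"]
        pooled_sd = np.sqrt(
            0.5 * (proj["dog"]["values"].var(ddof=1) + proj["cat"]["values"].var(ddof=1))
        )
        assert gap > pooled_sd


class TestTimecourse:
    def test_null_data_flat(self):
        """Zero-signal: no significant trend of D on window start."""
        cfg = SyntheticConfig(
            n_neurons=10, images_per_category=20, trials_per_image=6,
            category_contrast=0.0, seed=61,
        )
        ds = generate_dataset(cfg)
        ws = sliding_windows(-100, 300, width=100, step=25)
        tc = separation_timecourse(ds, ws)
        from scipy import stats

        slope = stats.linregress(tc.window_starts, tc.distance)
        assert slope.pvalue > 0.05
        assert np.all(tc.distance >= 0)

    def test_ramp_rises_step_does_not(self):
        """TE-like ramp grows late vs early; TEO-like step stays level.

        The ramp configuration shows a significant late-vs-early increase
        (Mann-Whitney, one-sided); the step configuration's late/early
        D ratio stays close to 1 and well below the ramp's on every
        matched seed.
        """
        from popsep import mannwhitney_windows

        ws = sliding_windows(0, 100, step=10) + sliding_windows(250, 350, step=10)
        base = dict(
            n_neurons=30, images_per_category=30, trials_per_image=8,
            latency_mean=40.0, latency_sd=10.0, selective_fraction=0.4,
        )
        ramp_hits = ratio_hits = 0
        seeds = range(5)
        for seed in seeds:
            ds_step = generate_dataset(
                SyntheticConfig(profile="step", category_contrast=2.5, seed=70 + seed, **base)
            )
            ds_ramp = generate_dataset(
                SyntheticConfig(profile="ramp", category_contrast=2.5,
                                training_gain=1.5, seed=70 + seed, **base)
            )
            tc_s = separation_timecourse(ds_step, ws)
            tc_r = separation_timecourse(ds_ramp, ws)
            early = slice(0, 11)
            late = slice(11, 22)
            ratio_s = tc_s.distance[late].mean() / tc_s.distance[early].mean()
            ratio_r = tc_r.distance[late].mean() / tc_r.distance[early].mean()
            p_r = mannwhitney_windows(tc_r, (0, 100), (250, 350), "greater").p_value
            ramp_hits += p_r < 0.05
            ratio_hits += ratio_r > ratio_s
        assert ramp_hits >= 4
        assert ratio_hits >= 4
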