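"""EM covariance estimation, MVN likelihoods and simulated assignment."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import isoassign as ia
from isoassign.assignment import (ConvergenceError, FeatherRecord,
                                  records_to_matrix, select_assignable)

RNG = np.random.default_rng(2024)
TRUE_SIGMA = np.array([[169.0, 5.0, 2.3],
                       [5.0, 1.69, 0.3],
                       [2.3, 0.3, 0.81]])
TRUE_MU = np.array([-60.0, -18.0, 9.0])


class TestFitMvnMissing:
    def test_complete_data_equals_closed_form(self):
        X = RNG.normal(size=(50, 3)) @ np.linalg.cholesky(TRUE_SIGMA).T + TRUE_MU
        fit = ia.fit_mvn_missing(X)
        assert fit.converged
        assert np.allclose(fit.mean, X.mean(axis=0), atol=1e-10)
        assert np.allclose(fit.cov, np.cov(X.T, ddof=0), atol=1e-10)

    def test_two_point_hand_example(self):
        # (0,0) and (2,2) padded with two more points to satisfy n >= 4;
        # use the 4-point set {(0,0),(2,2),(0,0),(2,2)}: mean (1,1),
        # n-divisor covariance [[1,1],[1,1]]
        X = np.array([[0.0, 0.0], [2.0, 2.0], [0.0, 0.0], [2.0, 2.0]])
        fit = ia.fit_mvn_missing(X)
        assert np.allclose(fit.mean, [1.0, 1.0], atol=1e-10)
        assert np.allclose(fit.cov, [[1.0, 1.0], [1.0, 1.0]], atol=1e-10)

    def test_recovery_under_mcar(self):
        n = 500
        rng = np.random.default_rng(77)
        X = rng.normal(size=(n, 3)) @ np.linalg.cholesky(TRUE_SIGMA).T + TRUE_MU
        mask = rng.random((n, 3)) < 0.2
        # keep the at-least-one-observed invariant
        mask[mask.all(axis=1)] = False
        Xm = np.where(mask, np.nan, X)
        fit = ia.fit_mvn_missing(Xm)
        assert fit.converged
        p = 1 - mask.mean(axis=0)
        for i in range(3):
            for j in range(3):
                n_eff = n * p[i] * p[j]
                se = np.sqrt((TRUE_SIGMA[i, i] * TRUE_SIGMA[j, j]
                              + TRUE_SIGMA[i, j] ** 2) / n_eff)
                assert abs(fit.cov[i, j] - TRUE_SIGMA[i, j]) < 3 * se, (i, j)

    def test_missing_improves_over_complete_case_only(self):
        """EM uses partial records; its estimate should not be degenerate."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3)) @ np.linalg.cholesky(TRUE_SIGMA).T + TRUE_MU
        Xm = X.copy()
        Xm[::3, 0] = np.nan  # drop a third of the d2h values
        fit = ia.fit_mvn_missing(Xm)
        assert fit.converged
        assert fit.n_complete == 40
        assert np.linalg.eigvalsh(fit.cov).min() > 0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ia.fit_mvn_missing(np.zeros((3, 3)))
        X = np.full((6, 3), np.nan)
        X[:, 0] = 1.0
        X[0, 1] = 2.0  # second isotope observed once only
        X[:, 2] = 3.0
        with pytest.raises(ValueError):
            ia.fit_mvn_missing(X)

    def test_accepts_feather_records(self):
        recs = [FeatherRecord(f"s{i}", d2h=float(v), d13c=float(v) / 10,
                              d15n=float(v) / 20)
                for i, v in enumerate(RNG.normal(-60, 13, 20))]
        fit = ia.fit_mvn_missing(recs)
        assert fit.n_records == 20 and fit.n_complete == 20


class TestLogMvnDensity:
    def test_standard_normal_at_mean(self):
        got = ia.log_mvn_density(np.zeros(3), np.zeros(3), np.eye(3))
        assert got == pytest.approx(-1.5 * np.log(2 * np.pi))

    def test_diagonal_factorizes(self):
        x, mu = np.array([1.0, -2.0, 0.5]), np.array([0.0, 1.0, -1.0])
        var = np.array([4.0, 0.25, 9.0])
        got = ia.log_mvn_density(x, mu, np.diag(var))
        want = sum(-0.5 * (np.log(2 * np.pi * v) + (xi - mi) ** 2 / v)
                   for xi, mi, v in zip(x, mu, var))
        assert got == pytest.approx(want, abs=1e-12)

    def test_against_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            cov = A @ A.T + 0.5 * np.eye(3)
            x, mu = rng.normal(size=3), rng.normal(size=3)
            assert ia.log_mvn_density(x, mu, cov) == pytest.approx(
                multivariate_normal.logpdf(x, mu, cov), abs=1e-9)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            ia.log_mvn_density(np.zeros(2), np.zeros(2),
                               np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestNormalizedClusterProbs:
    def test_dominance_at_far_separation(self, separated_summary):
        fit = ia.MvnFit(TRUE_MU, TRUE_SIGMA, 10, 10, 1, True)
        x = separated_summary.mean_vectors()[1]
        p = ia.normalized_cluster_probs(x, separated_summary, fit)
        assert p[1] > 0.999
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_equidistant_symmetry(self):
        means = np.array([[-10.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        summ = ia.ClusterSummary(np.array([1, 2]), ("d2h", "d13c", "d15n"),
                                 means, np.ones((2, 3)), np.array([5, 5]))
        fit = ia.MvnFit(np.zeros(3), np.eye(3), 10, 10, 1, True)
        p = ia.normalized_cluster_probs(np.zeros(3), summ, fit)
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_argmax_is_mahalanobis_nearest(self, separated_summary):
        fit = ia.MvnFit(TRUE_MU, TRUE_SIGMA, 10, 10, 1, True)
        mus = separated_summary.mean_vectors()
        Sinv = np.linalg.inv(TRUE_SIGMA)
        rng = np.random.default_rng(99)
        X = rng.normal(TRUE_MU, [40, 4, 3], size=(1000, 3))
        for x in X:
            p = ia.normalized_cluster_probs(x, separated_summary, fit)
            d2 = [(x - m) @ Sinv @ (x - m) for m in mus]
            assert np.argmax(p) == np.argmin(d2)

    def test_marginal_policy_uses_subvector(self, separated_summary):
        fit = ia.MvnFit(TRUE_MU, TRUE_SIGMA, 10, 10, 1, True)
        x = np.array([-80.0, np.nan, np.nan])
        with pytest.raises(ValueError):
            ia.normalized_cluster_probs(x, separated_summary, fit)
        p = ia.normalized_cluster_probs(x, separated_summary, fit,
                                        policy="marginal")
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        # d2h=-80 sits exactly on cluster 2's mean
        assert np.argmax(p) == 1

    def test_unconverged_fit_rejected(self, separated_summary):
        fit = ia.MvnFit(TRUE_MU, TRUE_SIGMA, 10, 10, 1000, False)
        with pytest.raises(ConvergenceError):
            ia.normalized_cluster_probs(np.zeros(3), separated_summary, fit)


@pytest.fixture
def fit():
    return ia.MvnFit(TRUE_MU, TRUE_SIGMA, 171, 171, 1, True)


class TestSimulateAssignments:

    def test_zero_sim_cov_reproduces_point_assignment(self, separated_summary,
                                                      fit):
        rng = np.random.default_rng(1)
        X = rng.normal(TRUE_MU, [30, 3, 2], size=(40, 3))
        mat = ia.simulate_assignments(X, separated_summary, fit, n_sims=50,
                                      seed=4, sim_cov=np.zeros((3, 3)))
        assert set(np.unique(mat.frequencies)) <= {0.0, 1.0}
        winners = mat.cluster_ids[np.argmax(mat.frequencies, axis=1)]
        assert np.array_equal(winners, mat.modal_cluster)
        pop = ia.summarize_counts(mat)
        assert np.allclose(pop.sd_counts, 0.0)

    def test_per_replicate_conservation(self, separated_summary, fit):
        rng = np.random.default_rng(2)
        X = rng.normal(TRUE_MU, [30, 3, 2], size=(25, 3))
        mat = ia.simulate_assignments(X, separated_summary, fit, n_sims=100,
                                      seed=5)
        assert np.all(mat.replicate_counts.sum(axis=1) == 25)
        assert np.allclose(mat.frequencies.sum(axis=1), 1.0)

    def test_determinism(self, separated_summary, fit):
        X = np.tile(TRUE_MU, (10, 1))
        a = ia.simulate_assignments(X, separated_summary, fit, n_sims=60, seed=9)
        b = ia.simulate_assignments(X, separated_summary, fit, n_sims=60, seed=9)
        assert np.array_equal(a.frequencies, b.frequencies)
        assert np.array_equal(a.replicate_counts, b.replicate_counts)

    def test_incomplete_record_rejected(self, separated_summary, fit):
        recs = [FeatherRecord("a", d2h=-60.0, d13c=-18.0, d15n=9.0),
                FeatherRecord("b", d2h=-60.0)]
        with pytest.raises(ValueError, match="b"):
            ia.simulate_assignments(recs, separated_summary, fit, n_sims=5)


class TestSummarizeCounts:
    def test_single_individual(self, separated_summary):
        fit = ia.MvnFit(TRUE_MU, TRUE_SIGMA, 10, 10, 1, True)
        X = separated_summary.mean_vectors()[:1]
        mat = ia.simulate_assignments(X, separated_summary, fit, n_sims=30,
                                      seed=0, sim_cov=np.zeros((3, 3)))
        pop = ia.summarize_counts(mat)
        assert np.array_equal(pop.mean_counts, [1, 0, 0, 0])
        assert np.allclose(pop.sd_counts, 0)

    def test_tally_oracle(self, separated_summary):
        fit = ia.MvnFit(TRUE_MU, TRUE_SIGMA, 30, 30, 1, True)
        rng = np.random.default_rng(3)
        X = rng.normal(TRUE_MU, [50, 5, 3], size=(30, 3))
        mat = ia.simulate_assignments(X, separated_summary, fit, n_sims=200,
                                      seed=6)
        pop = ia.summarize_counts(mat)
        counts = mat.replicate_counts
        assert np.allclose(pop.mean_counts, counts.mean(axis=0))
        assert np.allclose(pop.sd_counts, counts.std(axis=0, ddof=1))
        assert pop.mean_counts.sum() == pytest.approx(30, abs=1e-9)


class TestRecordHandling:
    def test_csv_round_trip(self, tmp_path):
        recs = [FeatherRecord("s1", ring="R1", year=2007, age="adult",
                              d2h=-60.5, d13c=-17.0, d15n=np.nan, sex="m"),
                FeatherRecord("s2", ring="R2", year=2010, age="HY", d2h=-89.0)]
        p = tmp_path / "feathers.csv"
        ia.assignment.write_feather_csv(recs, p)
        back = ia.read_feather_csv(p)
        assert back[0].sample_id == "s1" and back[0].year == 2007
        assert np.isnan(back[0].d15n)
        assert back[1].age == "HY"

    def test_select_assignable_filters(self):
        recs = [
            FeatherRecord("ad1", ring="A", year=2008, age="adult",
                          d2h=-60, d13c=-17, d15n=9),
            FeatherRecord("hy1", ring="B", year=2008, age="HY",
                          d2h=-89, d13c=-21, d15n=16),
            FeatherRecord("bad_year", ring="C", year=2010, age="adult",
                          d2h=-40, d13c=-16, d15n=10),
            FeatherRecord("partial", ring="D", year=2008, age="adult", d2h=-50),
            FeatherRecord("A_later", ring="A", year=2009, age="adult",
                          d2h=-58, d13c=-17, d15n=9),
        ]
        out = select_assignable(recs, exclude_years=[2010])
        assert {r.sample_id for r in out} == {"ad1", "A_later"}
        collapsed = select_assignable(recs, exclude_years=[2010],
                                      collapse_rings=True)
        assert {r.sample_id for r in collapsed} == {"A_later"}

    def test_no_isotope_rejected(self):
        with pytest.raises(ValueError):
            FeatherRecord("empty")

    def test_matrix_shape(self):
        recs = [FeatherRecord("x", d2h=1.0)]
        assert records_to_matrix(recs).shape == (1, 3)
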