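"""Robust centers and Mahalanobis deviance."""

import numpy as np
import pytest
from scipy import stats as ss

from qeegnorm.deviance import (
    RobustCenter,
    age_matched_md,
    deviance_table,
    fit_mcd,
    jackknife_reference_md,
    mahalanobis,
)


def center(u, cov, kind="global"):
    return RobustCenter(
        location=np.asarray(u, float),
        covariance=np.asarray(cov, float),
        support=np.arange(5),
        kind=kind,
    )


class TestMahalanobis:
    def test_distance_to_own_center_is_zero(self):
        c = center([1.0, -2.0], np.eye(2))
        assert mahalanobis([1.0, -2.0], c) == pytest.approx(0.0)

    def test_identity_covariance_is_euclidean(self):
        c = center([0, 0], np.eye(2))
        assert mahalanobis([3.0, 4.0], c) == pytest.approx(5.0)

    def test_hand_inverted_diagonal_case(self):
        c = center([0, 0], [[4.0, 0.0], [0.0, 1.0]])
        assert mahalanobis([2.0, 1.0], c) == pytest.approx(np.sqrt(2.0))

    def test_matches_explicit_inverse_oracle(self, rng):
        for _ in range(20):
            A = rng.standard_normal((2, 2))
            cov = A @ A.T + 0.5 * np.eye(2)
            u = rng.standard_normal(2)
            x = rng.standard_normal(2)
            expected = np.sqrt((x - u) @ np.linalg.inv(cov) @ (x - u))
            assert mahalanobis(x, center(u, cov)) == pytest.approx(expected, abs=1e-10)

    def test_singular_covariance_rejected(self):
        c = center([0, 0], [[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="singular"):
            mahalanobis([1.0, 0.0], c)


class TestMcd:
    def test_clean_gaussian_center_accurate(self, rng):
        scores = rng.multivariate_normal([2.0, -1.0], np.eye(2), 500)
        c = fit_mcd(scores, random_state=0)
        assert np.abs(c.location - [2.0, -1.0]).max() < 0.1

    def test_robust_to_10pct_gross_outliers(self, rng):
        clean = rng.multivariate_normal([0, 0], np.eye(2), 450)
        gross = rng.multivariate_normal([10, 10], 0.1 * np.eye(2), 50)
        c = fit_mcd(np.vstack([clean, gross]), random_state=0)
        assert np.abs(c.location).max() < 0.2

    def test_fewer_than_five_points_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            fit_mcd(rng.standard_normal((4, 2)))

    def test_deterministic_under_fixed_seed(self, rng):
        scores = rng.standard_normal((60, 2))
        c1 = fit_mcd(scores, random_state=7)
        c2 = fit_mcd(scores, random_state=7)
        np.testing.assert_array_equal(c1.covariance, c2.covariance)

    def test_affine_invariance_of_distances(self, rng):
        scores = rng.multivariate_normal([1, 2], [[2, 0.7], [0.7, 1]], 80)
        A = np.array([[1.5, -0.4], [0.3, 2.0]])
        b = np.array([3.0, -1.0])
        mapped = scores @ A.T + b
        d1 = mahalanobis(scores, fit_mcd(scores, random_state=0))
        d2 = mahalanobis(mapped, fit_mcd(mapped, random_state=0))
        np.testing.assert_allclose(d1, d2, atol=1e-8)


class TestJackknife:
    def test_center_subject_has_near_zero_distance(self, rng):
        ring = rng.multivariate_normal([0, 0], np.eye(2), 40)
        ring = np.vstack([ring, -ring])  # symmetric cloud centered at 0
        scores = np.vstack([[0.0, 0.0], ring])
        jk = jackknife_reference_md(scores, random_state=0)
        assert jk[0] < 0.3

    def test_jackknife_weakly_exceeds_plain_on_average(self, rng):
        scores = np.random.default_rng(5).multivariate_normal(
            [0, 0], [[2, 0.5], [0.5, 1]], 96
        )
        jk = jackknife_reference_md(scores, random_state=0)
        plain = mahalanobis(scores, fit_mcd(scores, random_state=0))
        assert jk.mean() >= plain.mean()

    def test_squared_distances_track_chi2_reference(self):
        scores = np.random.default_rng(5).multivariate_normal(
            [0, 0], [[2, 0.5], [0.5, 1]], 96
        )
        jk = jackknife_reference_md(scores, random_state=0)
        # MCD reweighting keeps the chi-square approximation loose
        ks = ss.kstest(jk**2, ss.chi2(2).cdf).statistic
        assert ks < 0.15

    def test_needs_six_subjects(self, rng):
        with pytest.raises(ValueError, match="at least 6"):
            jackknife_reference_md(rng.standard_normal((5, 2)))


class TestAgeMatched:
    def test_window_covering_cohort_equals_global(self, rng):
        scores = rng.standard_normal((60, 2))
        ages = rng.uniform(5, 15, 60)
        x = np.array([0.5, -0.5])
        md_a, n_sup = age_matched_md(x, 10.0, scores, ages, window=100.0, random_state=0)
        md_g = mahalanobis(x, fit_mcd(scores, random_state=0))
        assert n_sup == 60
        assert md_a == pytest.approx(md_g, abs=1e-10)

    def test_age_typical_subject_closer_to_age_matched_center(self, rng):
        ages = np.linspace(4, 18, 96)
        scores = np.column_stack([
            ages + rng.normal(0, 0.5, 96), rng.normal(0, 1, 96)
        ])
        x = np.array([17.0, 0.0])  # typical for age 17, far from global center
        md_a, _ = age_matched_md(x, 17.0, scores, ages, random_state=0)
        md_g = mahalanobis(x, fit_mcd(scores, random_state=0))
        assert md_a < md_g

    def test_insufficient_support_is_an_error_not_a_widening(self, rng):
        scores = rng.standard_normal((30, 2))
        ages = np.linspace(4, 18, 30)
        with pytest.raises(ValueError, match="minimum 10"):
            age_matched_md(np.zeros(2), 10.0, scores, ages, window=0.5, random_state=0)


def test_deviance_table_layout(rng):
    ref = {(0, 1): rng.standard_normal((50, 2)), (0, 2): rng.standard_normal((50, 2))}
    sub = {(0, 1): rng.standard_normal((4, 2)), (0, 2): rng.standard_normal((4, 2))}
    ids = np.array(["P0", "P1", "P2", "P3"])
    ref_ages = np.linspace(5, 15, 50)
    sub_ages = np.array([7.0, 9.0, 11.0, 13.0])
    out = deviance_table(ref, sub, ids, "patient", ref_ages, sub_ages, min_n=5)
    assert len(out) == 8
    assert set(out["pc_pair"]) == {"PC1-PC2", "PC1-PC3"}
    assert (out["md_global"] >= 0).all() and (out["md_age"] >= 0).all()
    assert (out["n_support_age"] >= 5).all()
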