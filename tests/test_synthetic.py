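"""Known-truth generators: planted parameter recovery and determinism."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from qeegnorm.aggregate import NETWORKS, feature_names, split_features
from qeegnorm.bands import CANONICAL_BANDS, make_band_scheme, power_table
from qeegnorm.deviance import fit_mcd, mahalanobis
from qeegnorm.lrtc import amplitude_envelope, dfa
from qeegnorm.normative import fit_normative_space
from qeegnorm.synthetic import (
    ClinicalCohortSpec,
    CohortSpec,
    SignalSpec,
    fgn,
    gen_clinical_cohort,
    gen_cohort_features,
    gen_parcel_timeseries,
    gen_state_pair,
    tdc_like_cohort_spec,
)

FS = 250.0


class TestFgn:
    def test_unit_variance(self):
        x = fgn(50_000, 0.8, np.random.default_rng(0))
        assert np.var(x) == pytest.approx(1.0, abs=0.05)

    def test_invalid_hurst_rejected(self):
        with pytest.raises(ValueError, match="Hurst"):
            fgn(100, 1.2, np.random.default_rng(0))


class TestParcelTimeseries:
    def test_deterministic_under_fixed_seed(self):
        spec = SignalSpec(n_parcels=2, duration=40.0,
                          band_relative_power={"alpha": 0.4}, seed=5)
        a, _ = gen_parcel_timeseries(spec)
        b, _ = gen_parcel_timeseries(spec)
        np.testing.assert_array_equal(a, b)

    def test_planted_alpha_relative_power_recovered(self):
        spec = SignalSpec(n_parcels=4, duration=300.0,
                          band_relative_power={"alpha": 0.6}, seed=7)
        sig, _ = gen_parcel_timeseries(spec)
        scheme = make_band_scheme()
        tbl = power_table(sig, FS, scheme)
        alpha = tbl[tbl["bin"].isin(scheme.groups["alpha"])]
        measured = alpha.groupby("parcel")["relative_pct"].sum().mean() / 100.0
        assert measured == pytest.approx(0.6, abs=0.05)

    def test_planted_alpha_dfa_exponent_recovered(self):
        spec = SignalSpec(n_parcels=6, duration=300.0,
                          band_relative_power={"alpha": 0.6},
                          band_dfa={"alpha": 0.8}, seed=7)
        sig, _ = gen_parcel_timeseries(spec)
        scheme = make_band_scheme()
        band = scheme.band_edges("alpha")
        es = [dfa(amplitude_envelope(sig[p], band, FS), FS).exponent
              for p in range(6)]
        assert 0.72 <= np.mean(es) <= 0.88

    def test_invalid_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            SignalSpec(fs=80.0).validate()

    def test_overfull_power_targets_rejected(self):
        spec = SignalSpec(band_relative_power={"alpha": 0.7, "theta": 0.5})
        with pytest.raises(ValueError, match="sum"):
            spec.validate()

    def test_short_duration_with_dfa_targets_warns_in_truth(self):
        spec = SignalSpec(n_parcels=1, duration=60.0,
                          band_dfa={"alpha": 0.7}, seed=1)
        _, truth = gen_parcel_timeseries(spec)
        assert any("100 s" in w for w in truth["warnings"])


class TestCohortFeatures:
    def test_zero_noise_single_component_rank_one(self):
        L = np.zeros((35, 1))
        L[:7, 0] = 1.0
        spec = CohortSpec(n_subjects=40, loadings=L,
                          component_variances=np.array([2.0]),
                          noise_variance=0.0, seed=0)
        fm, _ = gen_cohort_features(spec)
        _, X = split_features(fm)
        assert np.linalg.matrix_rank(X.to_numpy(), tol=1e-8) == 1

    def test_sample_covariance_matches_planted_model(self):
        spec = tdc_like_cohort_spec(seed=2, n_subjects=500)
        fm, _ = gen_cohort_features(spec)
        _, X = split_features(fm)
        L, v = spec.resolved()
        target = L @ np.diag(v) @ L.T + spec.noise_variance * np.eye(35)
        sample = np.cov(X.to_numpy(), rowvar=False)
        err = np.linalg.norm(sample - target) / np.linalg.norm(target)
        assert err < 0.15

    def test_deterministic(self):
        spec = tdc_like_cohort_spec(seed=9)
        a, _ = gen_cohort_features(spec)
        b, _ = gen_cohort_features(spec)
        assert a.equals(b)

    def test_zero_variance_component_rejected(self):
        spec = CohortSpec(loadings=np.ones((35, 1)),
                          component_variances=np.array([0.0]))
        with pytest.raises(ValueError, match="positive"):
            spec.resolved()


class TestStatePair:
    def test_unit_boosts_give_identical_states(self):
        eor, ecr = gen_state_pair(tdc_like_cohort_spec(seed=4), 1.0, 1.0)
        names = feature_names()
        np.testing.assert_allclose(eor[names], ecr[names])

    def test_network_blocks_sum_to_100(self):
        eor, ecr = gen_state_pair(tdc_like_cohort_spec(seed=4), 2.0, 1.3)
        for df in (eor, ecr):
            for net in NETWORKS:
                cols = [f"{b}_{net}" for b in CANONICAL_BANDS]
                np.testing.assert_allclose(df[cols].sum(axis=1), 100.0, atol=1e-9)

    def test_alpha_boost_increases_md_for_majority(self):
        eor, ecr = gen_state_pair(tdc_like_cohort_spec(seed=11), 2.0, 1.3)
        _, Xe = split_features(eor)
        _, Xc = split_features(ecr)
        scaler, space = fit_normative_space(Xe, random_state=0)
        increased = []
        for pair in space.component_pairs():
            se = space.project_pair(scaler.transform(Xe), pair)
            sc = space.project_pair(scaler.transform(Xc), pair)
            c = fit_mcd(se, random_state=0)
            increased.append(np.mean(mahalanobis(sc, c) > mahalanobis(se, c)))
        assert np.mean(increased) > 0.5  # majority per the state contrast
        assert min(increased) > 0.5

    def test_nonpositive_boost_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            gen_state_pair(tdc_like_cohort_spec(seed=0), 0.0, 1.0)


class TestClinicalCohort:
    def test_independent_latents_uncorrelated(self):
        spec = ClinicalCohortSpec(n_patients=2000, correlation=np.eye(5), seed=0)
        df = gen_clinical_cohort(spec)
        cols = list(spec.names)
        for i in range(5):
            for j in range(i + 1, 5):
                rho = spearmanr(df[cols[i]], df[cols[j]]).statistic
                assert abs(rho) < 0.1

    def test_strong_latent_correlation_matches_copula_oracle(self):
        C = np.eye(5)
        C[0, 1] = C[1, 0] = 0.9
        # Monte-Carlo oracle for the discretized copula correlation
        oracle_df = gen_clinical_cohort(
            ClinicalCohortSpec(n_patients=100_000, correlation=C, seed=99)
        )
        oracle = spearmanr(oracle_df["scale_1"], oracle_df["scale_2"]).statistic
        df = gen_clinical_cohort(
            ClinicalCohortSpec(n_patients=2000, correlation=C, seed=1)
        )
        rho = spearmanr(df["scale_1"], df["scale_2"]).statistic
        assert rho == pytest.approx(oracle, abs=0.1)

    def test_outputs_within_declared_levels(self):
        spec = ClinicalCohortSpec(n_patients=200, seed=3)
        df = gen_clinical_cohort(spec)
        for name, lv in zip(spec.names, spec.levels):
            assert set(df[name]).issubset(set(lv))

    def test_non_psd_matrix_names_eigenvalue(self):
        C = np.array([
            [1.0, 0.99, -0.99],
            [0.99, 1.0, 0.99],
            [-0.99, 0.99, 1.0],
        ])
        spec = ClinicalCohortSpec(
            n_patients=10, correlation=C,
            levels=((1, 2),) * 3, names=("a", "b", "c"),
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            gen_clinical_cohort(spec)
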