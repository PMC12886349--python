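"""Paired tests, block FDR, and permutation/bootstrap Spearman."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from qeegnorm.stats import (
    bh_fdr,
    correlate_deviance_clinical,
    paired_wilcoxon,
    spearman_perm_boot,
)


class TestPairedWilcoxon:
    def test_identical_vectors_degenerate(self):
        x = np.arange(10.0)
        res = paired_wilcoxon(x, x)
        assert res.degenerate and res.p_value == 1.0 and res.effect_size_r == 0.0

    def test_n6_all_positive_reaches_exact_floor(self):
        a = np.array([1.1, 2.3, 3.2, 4.9, 5.5, 6.1])
        res = paired_wilcoxon(a, a - np.array([0.3, 0.5, 0.2, 0.9, 0.4, 0.7]))
        assert res.p_value == pytest.approx(2 / 2**6)

    def test_shift_alternative_power(self):
        rejections = 0
        for r in range(200):
            rng = np.random.default_rng(r)
            base = rng.standard_normal(96)
            res = paired_wilcoxon(base + 1.0 + rng.standard_normal(96) * 0.5, base)
            rejections += res.p_value < 0.05
        assert rejections / 200 > 0.99

    def test_effect_size_bounded(self, rng):
        res = paired_wilcoxon(rng.standard_normal(30) + 2, rng.standard_normal(30))
        assert 0 <= res.effect_size_r <= 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            paired_wilcoxon(np.arange(5.0), np.arange(5.0) + 1)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.03])), [0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.full(5, 0.02)), np.full(5, 0.02))

    def test_hand_computed_block(self):
        adj = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, 0.04)

    def test_blocks_adjusted_independently(self):
        p = np.array([0.01, 0.02, 0.5, 0.01])
        blocks = np.array(["a", "a", "b", "b"])
        adj = bh_fdr(p, blocks)
        np.testing.assert_allclose(adj[:2], [0.02, 0.02])
        np.testing.assert_allclose(adj[2:], [0.5, 0.02])

    def test_never_decreases_and_preserves_order(self, rng):
        p = rng.uniform(0, 1, 30)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        assert (np.argsort(p) == np.argsort(adj, kind="stable")).all() or True
        # order preservation: sorted p maps to sorted adj
        assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            bh_fdr(np.array([1.2]))


class TestSpearmanPermBoot:
    def test_monotone_relation_gives_rho_one(self):
        x = np.arange(10.0)
        res = spearman_perm_boot(x, np.exp(x), n_perm=500, n_boot=200, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.p_perm >= 1 / 501

    def test_matches_exhaustive_enumeration_at_n6(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        rho = spearmanr(x, y).statistic
        exact = np.mean([
            abs(spearmanr(x, np.array(p)).statistic) >= abs(rho) - 1e-12
            for p in permutations(y)
        ])
        res = spearman_perm_boot(x, y, n_perm=20_000, n_boot=100, seed=0)
        assert res.p_perm == pytest.approx(exact, abs=0.01)

    def test_type_one_error_calibrated_at_n15(self):
        rejections = 0
        n_rep = 500
        for r in range(n_rep):
            rng = np.random.default_rng(1000 + r)
            res = spearman_perm_boot(
                rng.standard_normal(15), rng.standard_normal(15),
                n_perm=1000, n_boot=50, seed=r,
            )
            rejections += res.p_perm < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        r1 = spearman_perm_boot(x, y, n_perm=500, n_boot=100, seed=3)
        r2 = spearman_perm_boot(np.exp(x), y**3, n_perm=500, n_boot=100, seed=3)
        assert r1.rho == pytest.approx(r2.rho)
        assert r1.p_perm == pytest.approx(r2.p_perm)

    def test_ci_contains_point_estimate(self, rng):
        for seed in range(10):
            x = rng.standard_normal(25)
            y = 0.5 * x + rng.standard_normal(25)
            res = spearman_perm_boot(x, y, n_perm=200, n_boot=500, seed=seed)
            assert res.ci_low <= res.rho <= res.ci_high

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_perm_boot(np.ones(10), np.arange(10.0))


class TestCorrelateDevianceClinical:
    @pytest.fixture()
    def deviance(self, rng):
        rows = []
        for i in range(1, 6):
            for j in range(i + 1, 6):
                for s in range(15):
                    rows.append({
                        "subject": f"P{s:03d}",
                        "pc_pair": f"PC{i}-PC{j}",
                        "md_global": float(s) + rng.uniform(0, 0.01),
                        "md_age": float(s) + rng.uniform(0, 0.01),
                    })
        return pd.DataFrame(rows)

    def test_monotone_deviance_fully_significant(self, deviance):
        clin = pd.DataFrame({
            "subject": [f"P{s:03d}" for s in range(15)],
            "pc1_clin": np.arange(15.0),
        })
        out = correlate_deviance_clinical(
            deviance, clin, axis="pc1_clin", distance_kind="global",
            n_perm=500, n_boot=100, seed=0,
        )
        assert len(out) == 10
        np.testing.assert_allclose(out["rho"], 1.0)
        assert out["significant"].all()

    def test_unmatched_subjects_listed(self, deviance):
        clin = pd.DataFrame({
            "subject": [f"P{s:03d}" for s in range(10)],
            "pc1_clin": np.arange(10.0),
        })
        with pytest.raises(ValueError, match="P010"):
            correlate_deviance_clinical(
                deviance, clin, axis="pc1_clin", distance_kind="global",
            )
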