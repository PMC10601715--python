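"""Random-effects pooling, tau^2 estimators, and subgroup Qm."""

import shutil
import subprocess

import numpy as np
import pytest

from plastmeta.meta import (
    RandomEffectsMeta,
    benjamini_hochberg,
    estimate_tau2,
    pool,
    subgroup_qm,
)


class TestTau2:
    def test_identical_effects_no_heterogeneity(self):
        e = [0.3] * 6
        v = [0.01, 0.02, 0.03, 0.01, 0.02, 0.03]
        assert estimate_tau2(e, v, method="DL") == 0.0
        assert estimate_tau2(e, v, method="REML") == pytest.approx(0.0, abs=1e-8)

    def test_dl_hand_value(self):
        # w = 100 each; Q = 100*1 + 100*1 = 200; C = 200 - 20000/200 = 100
        # tau2 = (200 - 1) / 100 = 1.99
        assert estimate_tau2([-1, 1], [0.01, 0.01], method="DL") == pytest.approx(1.99)

    def test_reml_recovers_planted_tau2(self, rng):
        # mean relative error over replicates stays within 30% of truth
        tau2_true = 0.04
        ests = []
        for _ in range(200):
            e = rng.normal(0.1, np.sqrt(0.01 + tau2_true), size=200)
            ests.append(estimate_tau2(e, np.full(200, 0.01), method="REML"))
        assert np.mean(ests) == pytest.approx(tau2_true, rel=0.30)

    def test_k_below_two_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="k >= 2"):
            assert estimate_tau2([0.5], [0.01]) == 0.0

    def test_matches_r_metafor_reml(self, tmp_path):
        """Cross-check REML tau^2 and pooled mean against metafor."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        e = [0.12, -0.05, 0.33, 0.08, -0.21, 0.4, 0.02, 0.17, -0.09, 0.25]
        v = [0.02, 0.05, 0.01, 0.03, 0.04, 0.02, 0.06, 0.01, 0.03, 0.02]
        script = tmp_path / "m.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"yi <- c({', '.join(map(str, e))})\n"
            f"vi <- c({', '.join(map(str, v))})\n"
            'r <- rma(yi, vi, method="REML")\n'
            'cat(r$tau2, r$beta[1], r$se, sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_tau2, r_mu, r_se = map(float, out.stdout.split())
        tau2 = estimate_tau2(e, v, method="REML")
        est = pool(e, v, tau2=tau2)
        assert tau2 == pytest.approx(r_tau2, abs=1e-4)
        assert est.mean_effect == pytest.approx(r_mu, abs=1e-5)
        assert est.se == pytest.approx(r_se, abs=1e-5)


class TestPool:
    def test_single_effect_hand_values(self):
        est = pool([0.3], [0.01], tau2=0.0)
        assert est.mean_effect == pytest.approx(0.3)
        assert est.se == pytest.approx(0.1)
        assert est.ci_low == pytest.approx(0.104, abs=5e-4)
        assert est.ci_high == pytest.approx(0.496, abs=5e-4)
        assert est.significant

    def test_equal_weight_average(self):
        est = pool([0.1, 0.3], [0.02, 0.02], tau2=0.0)
        assert est.mean_effect == pytest.approx(0.2)

    def test_zero_effect_not_significant(self):
        est = pool([0.0], [0.04])
        assert not est.significant
        assert est.ci_low < 0 < est.ci_high

    def test_tau2_zero_reduces_to_fixed_effects_identically(self, rng):
        e = rng.normal(0, 1, 30)
        v = rng.uniform(0.01, 0.5, 30)
        est = pool(e, v, tau2=0.0)
        w = 1 / v
        assert est.mean_effect == pytest.approx(np.sum(w * e) / np.sum(w), abs=1e-14)
        assert est.se == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-14)

    def test_pooled_mean_within_effect_range(self, rng):
        for _ in range(20):
            e = rng.normal(0, 1, 15)
            v = rng.uniform(0.01, 1.0, 15)
            tau2 = float(rng.uniform(0, 0.5))
            est = pool(e, v, tau2=tau2)
            assert e.min() - 1e-12 <= est.mean_effect <= e.max() + 1e-12

    def test_significance_rule_matches_ci(self, rng):
        for _ in range(50):
            e = rng.normal(0, 0.3, 8)
            v = rng.uniform(0.005, 0.1, 8)
            est = pool(e, v, tau2=0.01)
            assert est.significant == (est.ci_low > 0 or est.ci_high < 0)
            assert est.ci_low < est.ci_high

    def test_estimator_class_wraps_pool(self, rng):
        e = rng.normal(0.2, 0.3, 40)
        v = np.full(40, 0.02)
        m = RandomEffectsMeta(method="DL").fit(e, v)
        tau2 = estimate_tau2(e, v, method="DL")
        ref = pool(e, v, tau2=tau2)
        assert m.mean_effect_ == pytest.approx(ref.mean_effect)
        assert m.tau2_ == pytest.approx(ref.tau2)
        assert m.get_params()["method"] == "DL"


class TestSubgroupQm:
    def test_single_level_is_an_error(self):
        e = np.zeros(12)
        v = np.full(12, 0.01)
        with pytest.raises(ValueError, match="2 levels"):
            subgroup_qm(e, v, ["a"] * 12)

    def test_small_levels_excluded_by_more_than_rule(self, rng):
        e = rng.normal(0, 0.1, 17)
        v = np.full(17, 0.01)
        g = ["a"] * 6 + ["b"] * 6 + ["c"] * 5  # c has exactly 5: excluded
        res = subgroup_qm(e, v, g, min_n=5)
        assert res.excluded_levels == ["c"]
        assert set(res.estimates) == {"a", "b"}
        assert res.df == 1

    def test_q_additivity(self, rng):
        e = rng.normal(0, 0.4, 60)
        v = rng.uniform(0.01, 0.1, 60)
        g = rng.choice(["a", "b", "c"], 60)
        res = subgroup_qm(e, v, g, min_n=5)
        assert res.q_total == pytest.approx(res.qm + res.q_within, abs=1e-8)
        assert res.qm >= 0

    def test_type_one_error_calibrated(self, rng):
        # equal true effects, known tau2 = 0: Qm p-value is uniform
        n_sim, rejections = 300, 0
        for _ in range(n_sim):
            e = rng.normal(0.2, 0.1, 40)
            v = np.full(40, 0.01)
            g = ["a"] * 20 + ["b"] * 20
            res = subgroup_qm(e, v, g, tau2=0.0)
            rejections += res.p_qm < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.03)

    def test_power_for_half_unit_contrast(self, rng):
        hits = 0
        for _ in range(100):
            e = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(0.5, 0.1, 20)])
            v = np.full(40, 0.01)
            res = subgroup_qm(e, v, ["a"] * 20 + ["b"] * 20, tau2=0.0)
            hits += res.p_qm < 0.05
        assert hits == 100


def test_benjamini_hochberg_monotone():
    p = {"a": 0.01, "b": 0.04, "c": 0.03, "d": 0.9}
    adj = benjamini_hochberg(p)
    assert adj["a"] == pytest.approx(0.04)
    assert adj["d"] == pytest.approx(0.9)
    assert all(adj[k] >= p[k] for k in p)
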