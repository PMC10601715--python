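"""Effect-size formulas, SD imputation, and ordination-distance ratios."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastmeta.effects import (
    UndefinedEffectError,
    aggregate_functionality,
    compute_effect_sizes,
    impute_missing_sd,
    lnrr,
    lnrr_beta_and_structure,
    lnrr_variance,
    ordination_distances,
)
from plastmeta.records import ObservationRecord, OrdinationExtract

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


class TestLnrr:
    def test_identity_and_log_e(self):
        assert lnrr(1.0, 1.0) == 0.0
        assert lnrr(math.e, 1.0) == pytest.approx(1.0)

    @given(a=positive, b=positive)
    def test_antisymmetry(self, a, b):
        assert lnrr(a, b) == pytest.approx(-lnrr(b, a), abs=1e-12)

    @given(x=positive)
    def test_null_at_equal_means(self, x):
        assert lnrr(x, x) == 0.0

    @pytest.mark.parametrize("xt,xc", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_mean_rejected(self, xt, xc):
        with pytest.raises(UndefinedEffectError):
            lnrr(xt, xc)


class TestLnrrVariance:
    def test_hand_value(self):
        # 1/(4*4) + 1/(4*4) = 0.125
        assert lnrr_variance(1, 4, 2, 1, 4, 2) == pytest.approx(0.125)

    def test_zero_sds_give_zero(self):
        assert lnrr_variance(0, 3, 5, 0, 3, 5) == 0.0

    @given(
        st_=st.floats(0.01, 10), sc=st.floats(0.01, 10),
        xt=positive, xc=positive, n=st.integers(1, 20),
    )
    def test_doubling_n_halves_variance(self, st_, sc, xt, xc, n):
        v1 = lnrr_variance(st_, n, xt, sc, n, xc)
        v2 = lnrr_variance(st_, 2 * n, xt, sc, 2 * n, xc)
        assert v2 == pytest.approx(v1 / 2)
        assert v1 >= 0

    def test_missing_sd_is_an_error(self):
        with pytest.raises(ValueError, match="imput"):
            lnrr_variance(float("nan"), 3, 5, 1.0, 3, 5)


def _rec(param, mc, mt, sc, st_, nc=4, nt=4):
    return ObservationRecord(
        study_id="s", parameter_name=param, mean_control=mc, mean_treatment=mt,
        sd_control=sc, sd_treatment=st_, n_control=nc, n_treatment=nt,
    )


class TestImputation:
    def test_pool_mean_cv_times_mean(self):
        # pool CVs {0.1, 0.3} -> mean 0.2; missing sd for mean 5 -> 1.0
        recs = [
            _rec("x", 10.0, 1.0, 1.0, None),  # control CV 0.1
            _rec("x", 10.0, 1.0, 3.0, None),  # control CV 0.3
            _rec("x", 5.0, 5.0, None, None),
        ]
        out, flags = impute_missing_sd(recs, min_pool=2)
        assert out[2].sd_control == pytest.approx(0.2 * 5.0)
        assert out[2].sd_treatment == pytest.approx(0.2 * 5.0)
        assert flags == [True, True, True]

    def test_no_missing_is_a_noop(self):
        recs = [_rec("x", 2.0, 3.0, 0.2, 0.3)]
        out, flags = impute_missing_sd(recs)
        assert out[0] == recs[0]
        assert flags == [False]

    def test_constant_cv_pool(self):
        recs = [
            _rec("x", 10.0, 20.0, 1.5, 3.0),  # CVs 0.15, 0.15
            _rec("x", 8.0, 4.0, None, None),
        ]
        out, _ = impute_missing_sd(recs, min_pool=1)
        assert out[1].sd_control == pytest.approx(0.15 * 8.0)
        assert out[1].sd_treatment == pytest.approx(0.15 * 4.0)

    def test_parameter_pool_preferred_over_global(self):
        recs = [
            _rec("a", 10.0, 10.0, 1.0, 1.0),  # CV 0.1 x2
            _rec("a", 10.0, 10.0, 1.0, 1.0),
            _rec("b", 10.0, 10.0, 5.0, 5.0),  # CV 0.5 x2
            _rec("b", 10.0, 10.0, 5.0, 5.0),
            _rec("a", 4.0, 4.0, None, 0.4),
        ]
        out, _ = impute_missing_sd(recs, min_pool=3)
        # parameter-a pool has 4 complete CVs (>= 3): imputes with 0.1
        assert out[4].sd_control == pytest.approx(0.1 * 4.0)

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError, match="drop SD-less"):
            impute_missing_sd([_rec("x", 5.0, 5.0, None, None)])


class TestOrdination:
    def test_hand_constructed_clouds(self):
        ext = OrdinationExtract(
            control_points=[(0, 0), (0, 2)], treatment_points=[(3, 0), (3, 2)]
        )
        dc, dt, db = ordination_distances(ext)
        assert dc == pytest.approx(2.0)
        assert dt == pytest.approx(2.0)
        assert db == pytest.approx((3 + math.sqrt(13) + math.sqrt(13) + 3) / 4)

    def test_identical_clouds(self):
        pts = [(0.0, 0.0), (1.0, 1.0), (2.0, 0.5)]
        dc, dt, db = ordination_distances(
            OrdinationExtract(control_points=pts, treatment_points=list(pts))
        )
        assert dt == pytest.approx(dc)
        assert db >= 0

    def test_coincident_points_degenerate(self):
        pts = [(1.0, 1.0)] * 3
        dc, dt, db = ordination_distances(
            OrdinationExtract(control_points=pts, treatment_points=pts)
        )
        assert dc == dt == db == 0.0

    def test_single_point_group_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            ordination_distances(
                OrdinationExtract(control_points=[(0, 0)], treatment_points=[(1, 1), (2, 2)])
            )

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(10):
            nc, nt = rng.integers(2, 31, size=2)
            c = rng.normal(size=(nc, 2))
            t = rng.normal(size=(nt, 2))
            dc, dt, db = ordination_distances(
                OrdinationExtract(
                    control_points=[tuple(p) for p in c],
                    treatment_points=[tuple(p) for p in t],
                )
            )
            # brute force over all pairs
            bc = np.mean([np.linalg.norm(c[i] - c[j]) for i in range(nc) for j in range(i + 1, nc)])
            bt = np.mean([np.linalg.norm(t[i] - t[j]) for i in range(nt) for j in range(i + 1, nt)])
            bb = np.mean([np.linalg.norm(ci - tj) for ci in c for tj in t])
            assert dc == pytest.approx(bc, abs=1e-10)
            assert dt == pytest.approx(bt, abs=1e-10)
            assert db == pytest.approx(bb, abs=1e-10)


class TestBetaStructureRatios:
    def test_direct_evaluation(self):
        b, s = lnrr_beta_and_structure(1.0, 2.0, 2.0)
        assert b == pytest.approx(math.log(2))
        assert s == pytest.approx(math.log(2 / 3))

    def test_balanced_case(self):
        b, s = lnrr_beta_and_structure(1.0, 1.0, 2.0)
        assert b == 0.0
        assert s == 0.0

    @given(dc=positive, dt=positive, db=positive)
    def test_beta_sign_flips_when_groups_swap(self, dc, dt, db):
        b1, _ = lnrr_beta_and_structure(dc, dt, db)
        b2, _ = lnrr_beta_and_structure(dt, dc, db)
        assert b1 == pytest.approx(-b2, abs=1e-12)

    @given(dc=positive, dt=positive, db=positive, k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, dc, dt, db, k):
        b1, s1 = lnrr_beta_and_structure(dc, dt, db)
        b2, s2 = lnrr_beta_and_structure(k * dc, k * dt, k * db)
        assert b1 == pytest.approx(b2, rel=1e-9, abs=1e-9)
        assert s1 == pytest.approx(s2, rel=1e-9, abs=1e-9)

    def test_zero_distance_rejected(self):
        with pytest.raises(UndefinedEffectError):
            lnrr_beta_and_structure(0.0, 1.0, 1.0)


class TestComputeAndAggregate:
    def test_nonpositive_means_excluded_with_reason(self):
        recs = [
            _rec("x", 2.0, 3.0, 0.2, 0.3),
            _rec("x", -1.0, 3.0, 0.2, 0.3),
        ]
        effects, excluded = compute_effect_sizes(recs)
        assert len(effects) == 1
        assert excluded[0][0] == 1
        assert "non-positive" in excluded[0][1]

    def test_functionality_filter_semantics(self):
        recs = [
            _rec("soil_respiration", 1, 2, 0.1, 0.1),
            _rec("fda", 1, 2, 0.1, 0.1),
            _rec("fda", 1, 3, 0.1, 0.1),
            _rec("shannon", 1, 2, 0.1, 0.1),
            _rec("biomass", 1, 2, 0.1, 0.1),
        ]
        effects, _ = compute_effect_sizes(recs)
        tagged = aggregate_functionality(effects, ["soil_respiration", "fda"])
        assert len(tagged) == 3
        # input untouched, no sign flipping
        assert all(t in effects for t in tagged)
        assert aggregate_functionality(effects, []) == []
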