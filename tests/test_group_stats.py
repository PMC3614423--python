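"""FCR/RCR arithmetic, duplicate averaging and the statistical toolkit."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suitflux.group_stats import (
    PairingError,
    average_duplicates,
    classify_p,
    compare_groups,
    compute_fcr,
    dagostino_pearson,
    normalize_to_cs,
    students_t_two_sample,
)
from suitflux.suit_protocol import RespState

FULL = {
    RespState.LEAK: 8.0,
    RespState.CI_OXPHOS: 44.0,
    RespState.CI_OXPHOS_CYTC: 44.2,
    RespState.CI_CII_OXPHOS: 67.3,
    RespState.CI_CII_ETS: 100.0,
    RespState.CII_ETS: 28.0,
    RespState.ROX: 0.0,
    RespState.CIV_MAX: 107.0,
}


def _profile(corrected=None, sample_id="s", group="control"):
    return compute_fcr(corrected or FULL, sample_id=sample_id, group=group)


class TestComputeFcr:
    def test_ratio_arithmetic(self):
        prof = _profile()
        assert prof.fcr[RespState.LEAK] == pytest.approx(0.08)
        assert prof.fcr[RespState.CI_CII_OXPHOS] == pytest.approx(0.673)
        assert prof.fcr[RespState.CI_CII_ETS] == 1.0
        assert prof.rcr == pytest.approx(8.4125)

    @settings(derandomize=True, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        base = _profile()
        scaled = _profile({s: k * v for s, v in FULL.items()})
        for s in RespState:
            assert scaled.fcr[s] == pytest.approx(base.fcr[s], rel=1e-9)
        assert scaled.rcr == pytest.approx(base.rcr, rel=1e-9)

    def test_nonpositive_reference_marks_sample_unusable(self):
        bad = FULL | {RespState.CI_CII_ETS: 0.0}
        prof = compute_fcr(bad)
        assert not prof.usable
        assert prof.fcr is None

    def test_nonpositive_leak_leaves_rcr_missing(self):
        prof = compute_fcr(FULL | {RespState.LEAK: 0.0})
        assert prof.usable
        assert prof.rcr is None
        assert prof.fcr[RespState.LEAK] == 0.0


class TestAverageDuplicates:
    def test_identical_duplicates(self):
        p1, p2 = _profile(), _profile()
        avg, var = average_duplicates(p1, p2)
        assert var.scalar_pct == 0.0
        assert avg.fcr == p1.fcr

    def test_two_percent_apart_states(self):
        p1 = _profile({s: 100.0 for s in RespState})
        p2 = _profile({s: 102.0 for s in RespState})
        _, var = average_duplicates(p1, p2)
        # FCRs cancel a common factor; variation measured on the flux maps
        # is |2|/101*100 ~ 1.98 per state
        m1 = {s: 100.0 for s in RespState}
        m2 = {s: 102.0 for s in RespState}
        from suitflux.group_stats import _pair_variation

        v = _pair_variation(m1, m2)
        assert v.scalar_pct == pytest.approx(100 * 2 / 101)
        assert var.scalar_pct == 0.0  # ratio profiles are identical

    def test_mismatched_sample_ids_rejected(self):
        p1 = _profile(sample_id="a")
        p2 = _profile(sample_id="b")
        with pytest.raises(PairingError):
            average_duplicates(p1, p2)

    def test_elementwise_mean(self):
        p1 = _profile({s: v for s, v in FULL.items()})
        p2 = _profile({s: 2 * v for s, v in FULL.items()})
        avg, _ = average_duplicates(p1, p2)
        for s in RespState:
            assert avg.fcr[s] == pytest.approx(p1.fcr[s])  # ratios identical
        assert avg.rcr == pytest.approx(p1.rcr)


class TestNormalizeToCs:
    def test_division(self):
        per_cs = normalize_to_cs({RespState.LEAK: 100.0}, 0.5)
        assert per_cs[RespState.LEAK] == pytest.approx(200.0)

    def test_inverse_scaling(self):
        a = normalize_to_cs(FULL, 0.1)
        b = normalize_to_cs(FULL, 0.2)
        for s in FULL:
            assert b[s] == pytest.approx(a[s] / 2)

    def test_zero_activity_rejected(self):
        with pytest.raises(ValueError, match="must be > 0"):
            normalize_to_cs(FULL, 0.0)

    def test_cs_normalization_inflates_dispersion(self):
        """Variance propagation: dividing by a noisy CS activity must scatter
        more than the internally normalized ratio, at the configured CVs."""
        rng = np.random.default_rng(9)
        n = 4000
        scale = rng.lognormal(0, 0.25, n)
        state = 0.673 * rng.lognormal(0, np.sqrt(np.log1p(0.105**2)), n) * scale
        ref = scale
        cs = 0.12 * rng.lognormal(0, np.sqrt(np.log1p(0.385**2)), n)
        fcr = state / ref
        per_cs = state / cs
        assert np.std(per_cs) / np.mean(per_cs) > np.std(fcr) / np.mean(fcr)


class TestNormalityTest:
    def test_calibration_under_the_null(self):
        rng = np.random.default_rng(123)
        rejections = sum(
            dagostino_pearson(rng.normal(size=100)).p_value < 0.05
            for _ in range(500)
        )
        rate = rejections / 500
        sd = np.sqrt(0.05 * 0.95 / 500)
        assert abs(rate - 0.05) < 3 * sd

    def test_power_against_exponential(self):
        rng = np.random.default_rng(321)
        rejections = sum(
            dagostino_pearson(rng.exponential(size=100)).p_value < 0.05
            for _ in range(200)
        )
        assert rejections / 200 >= 0.95

    def test_small_sample_not_applicable(self):
        res = dagostino_pearson([1.0, 2.0, 3.0])
        assert not res.applicable
        assert "n=3" in res.reason

    def test_constant_sample_skipped_with_reason(self):
        res = dagostino_pearson([2.0] * 20)
        assert not res.applicable
        assert "constant" in res.reason


class TestStudentsT:
    def test_hand_computed_example(self):
        # pooled s^2 = 1, se = sqrt(2/3), t = -1/se = -1.2247, df = 4
        res = students_t_two_sample([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-np.sqrt(1.5), rel=1e-9)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.2878641, rel=1e-4)

    def test_identical_samples(self):
        res = students_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == 1.0

    def test_degenerate_zero_variance(self):
        assert students_t_two_sample([1.0, 1.0], [1.0, 1.0]).p_value == 1.0
        with pytest.warns(UserWarning, match="zero pooled variance"):
            res = students_t_two_sample([1.0, 1.0], [2.0, 2.0])
        assert res.p_value == 0.0

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(77)
        reps = 2000
        hits = sum(
            students_t_two_sample(
                rng.normal(size=12), rng.normal(size=12)
            ).p_value
            < 0.05
            for _ in range(reps)
        )
        rate = hits / reps
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * sd


class TestCompareGroups:
    def _cohort(self, rng, group, n=12, shift=0.0):
        out = []
        for i in range(n):
            vals = {
                s: max(1e-6, FULL[s] * (1 + rng.normal(0, 0.05)) * (1 - shift))
                for s in RespState
                if s is not RespState.ROX
            }
            vals[RespState.ROX] = 0.0
            vals[RespState.CI_CII_ETS] = FULL[RespState.CI_CII_ETS]
            out.append(_profile(vals, sample_id=f"{group}{i}", group=group))
        return out

    def test_identical_cohorts_are_all_ns(self):
        profs = self._cohort(np.random.default_rng(1), "control")
        comps = compare_groups(profs, profs, which="fcr")
        assert len(comps) == 7
        for c in comps:
            assert c.mean_diff == pytest.approx(0.0, abs=1e-12)
            assert c.cls == "ns"

    def test_delegates_to_students_t(self):
        rng = np.random.default_rng(2)
        a = self._cohort(rng, "control")
        b = self._cohort(rng, "affected", shift=0.1)
        comps = {c.state: c for c in compare_groups(a, b, which="fcr")}
        leak_a = [p.fcr[RespState.LEAK] for p in a]
        leak_b = [p.fcr[RespState.LEAK] for p in b]
        oracle = students_t_two_sample(leak_a, leak_b)
        assert comps["LEAK"].t == pytest.approx(oracle.t, rel=1e-12)
        assert comps["LEAK"].p_value == pytest.approx(oracle.p_value, rel=1e-12)

    def test_sem_diff_identity(self):
        rng = np.random.default_rng(3)
        a = self._cohort(rng, "control")
        b = self._cohort(rng, "affected", shift=0.05)
        for c in compare_groups(a, b, which="fcr") + compare_groups(
            a, b, which="rcr"
        ):
            assert c.sem_diff == pytest.approx(
                np.sqrt(c.sem_A**2 + c.sem_B**2), rel=1e-12
            )
            assert c.mean_diff == pytest.approx(c.mean_A - c.mean_B, rel=1e-12)

    def test_rerun_is_bit_identical(self):
        rng = np.random.default_rng(4)
        a = self._cohort(rng, "control")
        b = self._cohort(rng, "affected", shift=0.1)
        first = compare_groups(a, b, "fcr")
        second = compare_groups(a, b, "fcr")
        assert [repr(c) for c in first] == [repr(c) for c in second]

    def test_classification_thresholds(self):
        assert classify_p(0.005) == "sig01"
        assert classify_p(0.03) == "sig05"
        assert classify_p(0.07) == "trend"
        assert classify_p(0.5) == "ns"
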