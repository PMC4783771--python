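import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellkin import (
    GrowthCurve,
    IndexMeasurement,
    KineticConstants,
    KineticRates,
    doubling_time,
    index_from_rate,
    predict_curve,
    predicted_rates,
    rate_from_index,
    reconcile_growth,
)
from cellkin.errors import (
    DataValidationError,
    PairingError,
    ReconciliationError,
)

LN2 = math.log(2.0)


class TestConversions:
    def test_flux_is_product(self):
        assert index_from_rate(0.03, 1.0, "flux") == pytest.approx(0.03)

    def test_zero_rate_both_conventions(self):
        assert index_from_rate(0.0, 5.0, "flux") == 0.0
        assert index_from_rate(0.0, 5.0, "age_structured") == 0.0

    def test_age_structured_closed_form(self):
        # T_M = T_c: every cell is inside the window -> index = 2^1 - 1 = 1
        assert index_from_rate(LN2 / 24, 24.0, "age_structured") == pytest.approx(1.0)

    def test_flux_caps_at_one_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            assert index_from_rate(0.5, 3.0, "flux") == 1.0

    def test_rate_from_index_flux(self):
        assert rate_from_index(0.04, 0.5, "flux") == pytest.approx(0.08)

    def test_rate_from_index_age_structured(self):
        assert rate_from_index(1.0, 24.0, "age_structured") == pytest.approx(
            LN2 / 24, abs=1e-12)

    @pytest.mark.parametrize("rate", [0.001, 0.03, 0.1])
    @pytest.mark.parametrize("convention", ["flux", "age_structured"])
    def test_roundtrip_identity(self, rate, convention):
        window = 1.0
        back = rate_from_index(index_from_rate(rate, window, convention),
                               window, convention)
        assert back == pytest.approx(rate, abs=1e-12)

    @given(st.floats(0.0, 0.2), st.floats(0.1, 4.0))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_property(self, rate, window):
        for convention in ("flux", "age_structured"):
            idx = index_from_rate(rate, window, convention)
            if idx >= 1.0:
                continue  # capped flux index is lossy by design
            assert rate_from_index(idx, window, convention) == pytest.approx(
                rate, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DataValidationError):
            index_from_rate(-0.1, 1.0)
        with pytest.raises(DataValidationError):
            index_from_rate(0.1, 0.0)
        with pytest.raises(DataValidationError):
            rate_from_index(-0.1, 1.0)
        with pytest.raises(DataValidationError):
            index_from_rate(0.1, 1.0, "unknown")

    def test_flux_index_above_one_warns_but_computes(self):
        with pytest.warns(UserWarning):
            assert rate_from_index(1.2, 2.0, "flux") == pytest.approx(0.6)


class TestPredictedRates:
    def test_hand_arithmetic(self):
        mi = IndexMeasurement("mitotic", 40, 1000, "L", "standard")
        ai = IndexMeasurement("apoptotic", 10, 1000, "L", "standard")
        r = predicted_rates(mi, ai, KineticConstants(T_M_h=1.0, T_A_h=4.0))
        assert r.b == pytest.approx(0.04)
        assert r.d_detected == pytest.approx(0.0025)
        assert r.k_pred == pytest.approx(0.0375)

    def test_zero_indices(self):
        mi = IndexMeasurement("mitotic", 0, 1000, "L", "standard")
        ai = IndexMeasurement("apoptotic", 0, 1000, "L", "standard")
        r = predicted_rates(mi, ai, KineticConstants())
        assert (r.b, r.d_detected, r.k_pred) == (0.0, 0.0, 0.0)

    def test_balanced_rates(self):
        mi = IndexMeasurement("mitotic", 20, 1000, "L", "standard")
        ai = IndexMeasurement("apoptotic", 80, 1000, "L", "standard")
        r = predicted_rates(mi, ai, KineticConstants(T_M_h=1.0, T_A_h=4.0))
        assert r.k_pred == pytest.approx(0.0, abs=1e-15)

    def test_mismatched_groups(self):
        mi = IndexMeasurement("mitotic", 10, 1000, "L", "standard")
        ai = IndexMeasurement("apoptotic", 10, 1000, "L", "hypoxia")
        with pytest.raises(PairingError):
            predicted_rates(mi, ai, KineticConstants())

    def test_swapped_kinds(self):
        mi = IndexMeasurement("mitotic", 10, 1000, "L", "standard")
        with pytest.raises(PairingError):
            predicted_rates(mi, mi, KineticConstants())

    def test_k_pred_exact_identity(self):
        r = KineticRates(b=0.0412345, d_detected=0.0012345)
        assert r.k_pred == r.b - r.d_detected


class TestPredictCurve:
    def test_zero_rate_constant(self):
        t = np.arange(0.0, 145.0, 24.0)
        np.testing.assert_allclose(predict_curve(150000, 0.0, t), 150000.0)

    def test_one_doubling(self):
        assert predict_curve(150000, LN2 / 24, [24.0])[0] == pytest.approx(300000.0)

    def test_zero_n0(self):
        np.testing.assert_array_equal(predict_curve(0.0, 0.1, [0, 10, 20]), 0.0)

    @given(st.floats(-0.05, 0.05), st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, deadline=None)
    def test_semigroup_property(self, k, t1, t2):
        n0 = 1e5
        direct = predict_curve(n0, k, [t1 + t2])[0]
        staged = predict_curve(predict_curve(n0, k, [t1])[0], k, [t2])[0]
        assert staged == pytest.approx(direct, rel=1e-12)


class TestDoublingTime:
    def test_unit(self):
        assert doubling_time(LN2) == pytest.approx(1.0)

    def test_24h(self):
        assert doubling_time(LN2 / 24) == pytest.approx(24.0)

    def test_zero_rate_infinite(self):
        assert doubling_time(0.0) == math.inf

    def test_negative_rate_is_signed_halving_time(self):
        assert doubling_time(-LN2 / 12) == pytest.approx(-12.0)


class TestReconcileGrowth:
    def _curve(self, k, n_reps=3, n0=150000.0):
        t = np.arange(0.0, 145.0, 24.0)
        counts = {f"r{i}": n0 * np.exp(k * t) for i in range(1, n_reps + 1)}
        return GrowthCurve("L", "standard", t, counts)

    def _indices(self, k_mi, k_ai=0, n=1000):
        return (IndexMeasurement("mitotic", k_mi, n, "L", "standard"),
                IndexMeasurement("apoptotic", k_ai, n, "L", "standard"))

    def test_self_consistent_zero_excess(self):
        # k_pred = 30/1000/1.0 = 0.03 matches the exact curve slope
        mi, ai = self._indices(30)
        rep = reconcile_growth(self._curve(0.03), mi, ai,
                               KineticConstants(1.0, 3.0), B=200, seed=0)
        assert rep.d_excess == pytest.approx(0.0, abs=1e-10)
        assert rep.ci_low <= 0.0 <= rep.ci_high

    def test_known_difference_on_noiseless_data(self):
        mi, ai = self._indices(35)  # k_pred = 0.035
        rep = reconcile_growth(self._curve(0.02), mi, ai,
                               KineticConstants(1.0, 3.0), B=200, seed=0)
        assert rep.d_excess == pytest.approx(0.015, abs=1e-10)

    def test_point_estimate_inside_ci(self):
        mi, ai = self._indices(40, 10)
        for seed in range(10):
            rep = reconcile_growth(self._curve(0.02), mi, ai,
                                   KineticConstants(1.0, 3.0), B=500, seed=seed)
            assert rep.ci_low <= rep.d_excess <= rep.ci_high

    def test_monotone_in_indices(self):
        curve = self._curve(0.02)
        const = KineticConstants(1.0, 3.0)
        kw = dict(B=50, seed=1)
        base = reconcile_growth(curve, *self._indices(30, 10), const, **kw).d_excess
        more_mi = reconcile_growth(curve, *self._indices(31, 10), const, **kw).d_excess
        more_ai = reconcile_growth(curve, *self._indices(30, 11), const, **kw).d_excess
        assert more_mi > base
        assert more_ai < base

    def test_all_zero_replicate_excluded_with_warning(self):
        t = np.array([0.0, 24.0, 48.0])
        curve = GrowthCurve("L", "standard", t,
                            {"r1": 100 * np.exp(0.03 * t), "r2": [0.0, 0.0, 0.0]})
        mi, ai = self._indices(30)
        with pytest.warns(UserWarning, match="excluded"):
            rep = reconcile_growth(curve, mi, ai, KineticConstants(1.0, 3.0),
                                   B=50, seed=0)
        assert rep.k_obs == pytest.approx(0.03, abs=1e-10)

    def test_no_usable_replicate(self):
        curve = GrowthCurve("L", "standard", [0.0, 24.0], {"r1": [0.0, 0.0]})
        mi, ai = self._indices(30)
        with pytest.warns(UserWarning):
            with pytest.raises(ReconciliationError):
                reconcile_growth(curve, mi, ai, KineticConstants(), B=10, seed=0)

    def test_group_mismatch(self):
        mi = IndexMeasurement("mitotic", 30, 1000, "OTHER", "standard")
        ai = IndexMeasurement("apoptotic", 0, 1000, "OTHER", "standard")
        with pytest.raises(PairingError):
            reconcile_growth(self._curve(0.03), mi, ai, KineticConstants(),
                             B=10, seed=0)

    def test_seed_determinism(self):
        mi, ai = self._indices(40, 10)
        a = reconcile_growth(self._curve(0.02), mi, ai, KineticConstants(1.0, 3.0),
                             B=300, seed=5)
        b = reconcile_growth(self._curve(0.02), mi, ai, KineticConstants(1.0, 3.0),
                             B=300, seed=5)
        assert a == b

    def test_report_dict_schema(self):
        mi, ai = self._indices(40, 10)
        rep = reconcile_growth(self._curve(0.02), mi, ai,
                               KineticConstants(1.0, 3.0), B=100, seed=2)
        d = rep.to_dict()
        assert d["d_excess_per_h"] == pytest.approx(d["k_pred_per_h"] - d["k_obs_per_h"])
        for key in ("cell_line", "condition", "k_obs_per_h", "k_pred_per_h",
                    "d_excess_per_h", "ci_low", "ci_high", "B", "seed",
                    "hidden_death_flag", "convention", "T_M_h", "T_A_h"):
            assert key in d
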