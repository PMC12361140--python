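"""Kinetic model, window-scan selection and replicate aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lacsite import kinetics as K
from lacsite import synthetic as syn

from conftest import make_curve


class TestSmoothedTime:
    @pytest.mark.parametrize(
        "t,t_off,d,expected",
        [
            (20.0, 10.0, 0.0, 10.0),  # hinge limit at d=0
            (10.0, 10.0, 5.0, 2.5),  # at the offset dt = d/2
            (13.0, 10.0, 4.0, (3 + math.sqrt(9 + 16)) / 2),
            (5.0, 10.0, 0.0, 0.0),  # before the lag, d=0
        ],
    )
    def test_known_values(self, t, t_off, d, expected):
        assert K.smoothed_time(t, t_off, d) == pytest.approx(expected, abs=1e-12)

    @given(
        t_off=st.floats(-50, 100),
        d=st.floats(0, 50),
        t1=st.floats(-100, 500),
        t2=st.floats(-100, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_and_monotone(self, t_off, d, t1, t2):
        lo, hi = sorted((t1, t2))
        v_lo, v_hi = K.smoothed_time(lo, t_off, d), K.smoothed_time(hi, t_off, d)
        assert v_lo >= 0
        assert v_hi >= v_lo - 1e-9

    def test_d_zero_limit(self):
        t = np.linspace(-20, 100, 241)
        small = K.smoothed_time(t, 10.0, 1e-6)
        assert np.allclose(small, np.maximum(0.0, t - 10.0), atol=1e-6)


class TestEvalModel:
    def test_halfway_point(self):
        # sl*dt = m makes the hyperbola reach m/2 exactly
        p = K.MonodFitParams(sl=0.001, m=1.0, t_off=0.0, d=0.0)
        assert K.eval_model(p, 1000.0) == pytest.approx(0.5)

    def test_zero_at_offset_when_unsmoothed(self):
        p = K.MonodFitParams(sl=0.01, m=0.5, t_off=30.0, d=0.0)
        assert K.eval_model(p, 30.0) == 0.0
        assert K.eval_model(p, 10.0) == 0.0

    def test_saturates_below_plateau(self):
        p = K.MonodFitParams(sl=0.01, m=0.5, t_off=0.0, d=0.0)
        t = np.linspace(0, 5000, 1001)
        y = K.eval_model(p, t)
        assert np.all(y < 0.5)
        assert y[-1] == pytest.approx(0.5, rel=1e-2)
        assert np.all(np.diff(y) >= -1e-15)  # monotone non-decreasing

    @given(
        sl=st.floats(1e-5, 1e-2),
        m=st.floats(0.05, 2.0),
        t_off=st.floats(-10, 60),
        d=st.floats(0, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_linear_and_plateau(self, sl, m, t_off, d):
        p = K.MonodFitParams(sl=sl, m=m, t_off=t_off, d=d)
        t = np.linspace(0, 240, 49)
        y = K.eval_model(p, t)
        dt = K.smoothed_time(t, t_off, d)
        assert np.all(y <= np.minimum(sl * dt, m) + 1e-12)
        assert np.all(np.diff(y) >= -1e-12)


class TestInitialGuess:
    def test_linear_curve_slope(self):
        t = np.arange(0, 245, 5.0)
        c = K.KineticCurve("s", "ref", 1, 1, t, 0.001 * t)
        g = K.initial_guess(c, len(t) - 1)
        assert g.sl == pytest.approx(0.001, rel=1e-6)

    def test_flat_curve_floor(self):
        t = np.arange(0, 245, 5.0)
        c = K.KineticCurve("s", "ref", 1, 1, t, np.zeros_like(t))
        g = K.initial_guess(c, len(t) - 1)
        assert g.sl == K.SL_FLOOR

    def test_recovers_order_of_magnitude(self):
        c = make_curve(sl=2.4e-4, sigma=0.002, seed=11)
        g = K.initial_guess(c, 48)
        assert 2.4e-5 < g.sl < 2.4e-3


class TestFitWindow:
    def test_noiseless_self_consistency(self):
        c = make_curve(sl=3e-4, m=1.0, t_off=10, d=5, sigma=0.0)
        f = K.fit_window(c, len(c.times) - 1)
        assert f.converged
        assert f.params.sl == pytest.approx(3e-4, rel=1e-6)
        assert f.fit_error == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_within_5pct(self):
        c = make_curve(sl=3e-4, sigma=0.002, seed=5)
        f = K.fit_window(c, len(c.times) - 1)
        assert f.converged
        assert f.params.sl == pytest.approx(3e-4, rel=0.05)

    def test_fixed_d_matches_free_fit_on_exact_data(self):
        c = make_curve(sl=3e-4, m=1.0, t_off=10, d=5, sigma=0.0)
        free = K.fit_window(c, 48)
        fixed = K.fit_window(c, 48, fixed_d=5.0)
        assert fixed.d_was_fixed and not free.d_was_fixed
        assert fixed.params.sl == pytest.approx(free.params.sl, rel=1e-4)
        assert "d" not in fixed.param_se and "d" in free.param_se

    def test_rejects_bad_window(self):
        c = make_curve()
        with pytest.raises(ValueError):
            K.fit_window(c, 4)

    def test_plateau_anchor_disabled_frees_m(self):
        c = make_curve(sl=1.5e-4, sigma=0.002, seed=3)
        anchored = K.fit_window(c, 48)
        free = K.fit_window(c, 48, rules=K.AdequacyRules(m_nominal=None))
        assert anchored.m_was_fixed
        assert not free.m_was_fixed
        assert "m" in free.param_se and "m" not in anchored.param_se


def _oracle_selected(scan):
    """Exhaustive re-derivation of the selected fit from the raw window list."""
    errs = [f.fit_error for f in scan.window_fits]
    mins = []
    for i in range(len(errs)):
        if (i == 0 or errs[i] <= errs[i - 1]) and (i == len(errs) - 1 or errs[i] <= errs[i + 1]):
            mins.append(i)
    cands = [scan.window_fits[i] for i in mins
             if scan.window_fits[i].converged and scan.window_fits[i].adequate]
    if not cands:
        return None
    return min(cands, key=lambda f: (f.param_se["sl"], -f.end_index))


class TestScanAndSelect:
    def test_noiseless_full_window_selected_exactly(self):
        c = make_curve(sl=2.4e-4, m=1.0, t_off=10, d=5, sigma=0.0)
        scan = K.scan_and_select(c)
        assert scan.selected is not None
        assert 48 in scan.local_min_indices
        assert scan.selected.params.sl == pytest.approx(2.4e-4, rel=1e-6)

    def test_late_drift_shortens_window(self):
        # plateau drift after 150 min breaks the model late in the curve
        c = make_curve(sl=4e-4, m=1.0, t_off=10, d=5, sigma=0.0005, seed=9)
        od = c.od410.copy()
        late = c.times > 150
        od[late] += 0.004 * (c.times[late] - 150)  # strong linear drift
        c = K.KineticCurve(c.strain_id, c.condition, c.bio_rep, c.tech_rep, c.times, od)
        scan = K.scan_and_select(c)
        assert scan.selected is not None
        assert scan.selected.end_index < 48
        assert scan.selected.params.sl == pytest.approx(4e-4, rel=0.1)

    def test_pure_noise_selects_nothing(self):
        t = np.arange(0, 245, 5.0)
        rng = np.random.default_rng(17)
        c = K.KineticCurve("s", "ref", 1, 1, t, rng.normal(0, 0.002, t.shape))
        scan = K.scan_and_select(c)
        assert scan.selected is None

    @pytest.mark.parametrize("seed,sl", [(1, 2.412e-4), (2, 1.419e-4), (3, 5e-4)])
    def test_selection_matches_exhaustive_oracle(self, seed, sl):
        c = make_curve(sl=sl, sigma=0.002, seed=seed)
        scan = K.scan_and_select(c)
        oracle = _oracle_selected(scan)
        assert (scan.selected is None) == (oracle is None)
        if oracle is not None:
            assert scan.selected.end_index == oracle.end_index
            assert scan.selected.params.sl == oracle.params.sl

    def test_local_minima_are_local_minima(self):
        c = make_curve(sl=2.4e-4, sigma=0.002, seed=21)
        scan = K.scan_and_select(c)
        errs = {f.end_index: f.fit_error for f in scan.window_fits}
        for k in scan.local_min_indices:
            assert errs[k] <= errs.get(k - 1, np.inf) + 1e-15
            assert errs[k] <= errs.get(k + 1, np.inf) + 1e-15


class TestEstimateSlope:
    def test_adequate_free_fit_passes_through(self):
        c = make_curve(sl=3e-4, sigma=0.001, seed=2)
        scan = K.scan_and_select(c)
        est = K.estimate_slope(c, scan)
        assert est.provenance == "free_fit"
        assert est.slope == scan.selected.params.sl

    def test_failed_without_cohort(self):
        t = np.arange(0, 245, 5.0)
        rng = np.random.default_rng(17)
        c = K.KineticCurve("s", "ref", 1, 1, t, rng.normal(0, 0.002, t.shape))
        est = K.estimate_slope(c, K.scan_and_select(c))
        assert est.provenance == "failed"
        assert est.slope is None

    def test_cohort_d_rescues_inadequate_fit(self):
        # harsh adequacy makes the free fit unusable; sibling d values rescue it
        strict = K.AdequacyRules(max_rel_se_sl=1e-6)
        c = make_curve(sl=2.412e-4, sigma=0.002, seed=4)
        scan = K.scan_and_select(c, rules=strict)
        assert scan.selected is None
        sib = K.scan_and_select(make_curve(sl=2.412e-4, sigma=0.002, seed=5))
        est = K.estimate_slope(c, scan, cohort_tech=[sib])
        assert est.provenance == "d_fixed"
        assert est.slope == pytest.approx(2.412e-4, rel=0.10)


class TestAggregateActivity:
    def _est(self, slope, se=1e-6, bio=1, tech=1):
        return K.SlopeEstimate("s", "ref", bio, tech, slope, se, 0.001, 48, "free_fit")

    def test_identical_replicates(self):
        summ = K.aggregate_activity([self._est(2e-4, tech=i) for i in range(1, 4)])
        assert summ.geo_mean_slope == pytest.approx(2e-4)
        assert summ.geo_se == pytest.approx(1.0)

    def test_geometric_mean_of_two(self):
        summ = K.aggregate_activity([self._est(1e-4, tech=1), self._est(4e-4, tech=2)])
        assert summ.geo_mean_slope == pytest.approx(2e-4)

    def test_bounded_by_extremes_and_permutation_invariant(self):
        slopes = [1.2e-4, 3.1e-4, 2.2e-4]
        ests = [self._est(s, tech=i + 1) for i, s in enumerate(slopes)]
        summ = K.aggregate_activity(ests)
        assert min(slopes) <= summ.geo_mean_slope <= max(slopes)
        rev = K.aggregate_activity(ests[::-1])
        assert rev.geo_mean_slope == pytest.approx(summ.geo_mean_slope)

    def test_error_escalation_to_large_fit_se(self):
        # one replicate's per-fit SE dwarfs the between-replicate scatter
        ests = [self._est(2e-4, se=1e-4, tech=1), self._est(2.05e-4, se=1e-4, tech=2)]
        summ = K.aggregate_activity(ests)
        mean_rel_se = np.mean([1e-4 / 2e-4, 1e-4 / 2.05e-4])
        assert summ.reported_error == pytest.approx(mean_rel_se)
        assert summ.reported_error > math.log(summ.geo_se)

    def test_all_failed_raises(self):
        bad = K.SlopeEstimate("s", "ref", 1, 1, None, None, None, None, "failed")
        with pytest.raises(ValueError):
            K.aggregate_activity([bad])


class TestRecoveryEnsembles:
    def test_exact_recovery_random_parameter_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(12):
            sl = 10 ** rng.uniform(-4, -2.5)
            m = 10 ** rng.uniform(-0.5, 0.3)
            t_off = rng.uniform(0, 30)
            d = rng.uniform(0, 15)
            c = make_curve(sl=sl, m=m, t_off=t_off, d=d, sigma=0.0, seed=1)
            scan = K.scan_and_select(c, rules=K.AdequacyRules(m_nominal=m))
            assert scan.selected is not None, (sl, m, t_off, d)
            assert scan.selected.params.sl == pytest.approx(sl, rel=1e-4)

    @pytest.mark.parametrize("sl", [1e-4, 1.419e-4, 2.412e-4, 5e-4, 1e-3])
    def test_noisy_median_bias_below_5pct(self, sl):
        errs = []
        for seed in range(20):
            c = make_curve(sl=sl, sigma=0.002, seed=1000 + seed)
            scan = K.scan_and_select(c)
            if scan.selected is not None:
                errs.append(scan.selected.params.sl / sl - 1)
        assert len(errs) >= 15
        assert abs(np.median(errs)) < 0.05
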