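"""The binomial-occupancy correction: R, q, Δx, R_eq and aggregation."""

import itertools
import math

import numpy as np
import pytest

from bkrect import occupancy as occ
from bkrect import synthetic_data as sd
from bkrect.errors import FitError, LowOccupancyError, UndefinedRatioError
from bkrect.trace_fit import BiexpFit, TailIV

from conftest import noise_free


def _tails(i_pos, i_neg):
    return TailIV(levels=(-100.0, 100.0), I_inst=(i_neg, i_pos), method="t")


def _fit(A1, C):
    return BiexpFit(A1=A1, tau1=20.0, A2=-max(abs(A1), 1.0), tau2=2.0,
                    C=C, rmse=0.0, converged=True)


class TestRectificationRatio:
    def test_symmetric_currents(self):
        assert occ.rectification_ratio(_tails(2.0, -2.0)) == 1.0

    def test_alpha_only_value(self):
        assert occ.rectification_ratio(_tails(1.12, -1.0)) == pytest.approx(1.12)

    def test_zero_inward_current_undefined(self):
        with pytest.raises(UndefinedRatioError):
            occ.rectification_ratio(_tails(1.0, 0.0))


class TestUnbindingProbability:
    def test_complete_inactivation(self):
        q, flags = occ.unbinding_probability(_fit(1.0, 0.0))
        assert q == 0.0 and not flags

    def test_no_inactivation(self):
        q, _ = occ.unbinding_probability(_fit(0.0, 1.0))
        assert q == 1.0

    def test_pedestal_ratio_inverts_fourth_power(self):
        # 0.48^4 = 0.0531: the C1S-grade pedestal maps back to q = 0.48
        q, _ = occ.unbinding_probability(_fit(1.0, 0.0531))
        assert q == pytest.approx(0.48, abs=5e-4)

    def test_negative_pedestal_clamped(self):
        q, flags = occ.unbinding_probability(_fit(1.0, -0.01))
        assert q == 0.0
        assert "clamped-pedestal" in flags

    def test_nonpositive_amplitude_rejected(self):
        bad = BiexpFit(A1=0.0, tau1=1.0, A2=0.0, tau2=1.0, C=0.1,
                       rmse=0.0, converged=False)
        with pytest.raises(FitError):
            occ.unbinding_probability(bad)


class TestEquivalentRatio:
    def test_full_occupancy_is_identity(self):
        res = occ.equivalent_ratio(1.85, q=0.0, R_alpha=1.12)
        assert res.R_eq == pytest.approx(1.85)

    def test_alpha_level_measurement_stays_alpha(self):
        res = occ.equivalent_ratio(1.12, q=0.4, R_alpha=1.12)
        assert res.R_eq == pytest.approx(1.12)
        assert res.delta_x == pytest.approx(0.0)

    def test_worked_correction(self):
        # R* = 1.22 with q = 0.48: R_eq = 1.12 + 0.10/0.52
        res = occ.equivalent_ratio(1.22, q=0.48, R_alpha=1.12)
        assert res.R_eq == pytest.approx(1.3123, abs=1e-4)

    def test_low_occupancy_refused(self):
        with pytest.raises(LowOccupancyError):
            occ.equivalent_ratio(1.5, q=0.96, R_alpha=1.12)

    @pytest.mark.parametrize("q", [0.0, 0.2, 0.5, 0.8])
    def test_monotone_in_measured_ratio(self, q):
        rs = [occ.equivalent_ratio(r, q, 1.12).R_eq
              for r in np.linspace(1.13, 2.5, 20)]
        assert np.all(np.diff(rs) > 0)

    def test_monotone_in_q_above_alpha(self):
        rs = [occ.equivalent_ratio(1.5, q, 1.12).R_eq
              for q in np.linspace(0.0, 0.9, 19)]
        assert np.all(np.diff(rs) > 0)


class TestEnsembleForward:
    def test_saturated_and_empty_limits(self):
        m = occ.OccupancyModel(R_alpha=1.12, delta_x=0.1825, p=1.0)
        assert occ.ensemble_ratio_forward(m) == pytest.approx(1.85)
        m0 = occ.OccupancyModel(R_alpha=1.12, delta_x=0.1825, p=0.0)
        assert occ.ensemble_ratio_forward(m0) == pytest.approx(1.12)

    def test_wild_type_occupancy(self):
        m = occ.OccupancyModel(R_alpha=1.12, delta_x=0.1825, p=0.93)
        assert occ.ensemble_ratio_forward(m) == pytest.approx(1.7989,
                                                              abs=1e-5)

    def test_explicit_sum_equals_closed_form_on_grid(self):
        """Independent brute-force enumeration over a 100-point (p, Δx)
        grid agrees with the closed form R_α + 4pΔx to 1e-12."""
        for p, dx in itertools.product(np.linspace(0, 1, 10),
                                       np.linspace(0, 0.5, 10)):
            brute = sum(
                math.comb(4, n) * p**n * (1 - p) ** (4 - n) * (1.12 + n * dx)
                for n in range(5)
            )
            model = occ.OccupancyModel(R_alpha=1.12, delta_x=dx, p=p)
            assert abs(occ.ensemble_ratio_forward(model) - brute) < 1e-12
            assert abs(brute - (1.12 + 4 * p * dx)) < 1e-12

    def test_round_trip_identity_over_catalog(self, catalog):
        """forward ensemble ratio → occupancy correction returns each
        preset's R_eq_full exactly."""
        for preset in catalog.values():
            if preset.p_bind <= 0.05:
                continue
            model = occ.OccupancyModel(R_alpha=preset.R_alpha,
                                       delta_x=preset.delta_x,
                                       p=preset.p_bind)
            r_meas = occ.ensemble_ratio_forward(model)
            res = occ.equivalent_ratio(r_meas, preset.q_unbind,
                                       preset.R_alpha)
            assert res.R_eq == pytest.approx(preset.R_eq_full, abs=1e-9)


class TestAnalyzePatch:
    def test_wt_noise_free_recovery(self, wt_preset, fast_test_protocol,
                                    fast_tail_protocol):
        tp = sd.simulate_test_pulse_family(noise_free(wt_preset),
                                           fast_test_protocol)
        tail = sd.simulate_tail_family(noise_free(wt_preset),
                                       fast_tail_protocol)
        res = occ.analyze_patch(tp, tail)
        assert res.q == pytest.approx(0.07, abs=1e-8)
        assert res.R_eq == pytest.approx(1.85, abs=1e-8)

    def test_alpha_only_flagged_not_corrected(self, catalog,
                                              fast_test_protocol,
                                              fast_tail_protocol):
        preset = noise_free(catalog["mSlo1"])
        res = occ.analyze_patch(
            sd.simulate_test_pulse_family(preset, fast_test_protocol),
            sd.simulate_tail_family(preset, fast_tail_protocol))
        assert "alpha-only" in res.flags
        assert math.isnan(res.q)
        assert res.R_eq == pytest.approx(res.R_measured)

    def test_c1s_generator_analyzer_inversion(self, catalog,
                                              fast_test_protocol,
                                              fast_tail_protocol):
        preset = noise_free(catalog["C1S"])
        res = occ.analyze_patch(
            sd.simulate_test_pulse_family(preset, fast_test_protocol),
            sd.simulate_tail_family(preset, fast_tail_protocol))
        assert res.q == pytest.approx(0.48, rel=1e-6)
        assert res.R_eq == pytest.approx(1.38, rel=1e-6)

    def test_stochastic_recovery_across_catalog(self, catalog,
                                                fast_test_protocol,
                                                fast_tail_protocol):
        """At 2 % noise, the 12-seed mean R_eq lands within 2 cohort sd of
        each preset's truth."""
        for preset in catalog.values():
            vals = []
            for seed in range(1, 13):
                tp = sd.simulate_test_pulse_family(preset, fast_test_protocol,
                                                   seed=seed)
                tail = sd.simulate_tail_family(preset, fast_tail_protocol,
                                               seed=seed + 1000)
                vals.append(occ.analyze_patch(tp, tail).R_eq)
            mean, sdv = np.mean(vals), np.std(vals, ddof=1)
            tol = max(2 * sdv, 1e-6)
            assert abs(mean - preset.R_eq_full) <= tol, preset.name


class TestAggregate:
    def _res(self, r_eq, q=0.1):
        return occ.RectificationResult(1.5, q, 1 - q, 0.1, r_eq)

    def test_identical_results_zero_sd(self):
        s = occ.aggregate([self._res(1.5)] * 3, "x")
        assert s.req_sd == 0.0

    def test_hand_computed_moments(self):
        s = occ.aggregate([self._res(1.0), self._res(2.0)], "x")
        assert s.req_mean == pytest.approx(1.5)
        assert s.req_sd == pytest.approx(0.7071, abs=1e-4)

    def test_n_matches_input_length(self):
        s = occ.aggregate([self._res(1.0)] * 5, "x")
        assert s.req_n == 5

    def test_alpha_only_patches_excluded_from_q(self):
        nan = float("nan")
        rows = [self._res(1.2), self._res(1.3),
                occ.RectificationResult(1.2, nan, nan, nan, 1.2,
                                        ("alpha-only",))]
        s = occ.aggregate(rows, "x")
        assert s.req_n == 3 and s.q_n == 2

    def test_sem_option(self):
        s = occ.aggregate([self._res(1.0), self._res(2.0)], "x", sem=True)
        assert s.req_sd == pytest.approx(0.7071 / math.sqrt(2), abs=1e-4)

    def test_too_few_results_rejected(self):
        with pytest.raises(ValueError):
            occ.aggregate([self._res(1.0)], "x")
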