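"""Residual states, rivaroxaban thresholds, corridors and synergy."""

import numpy as np
import pytest

import coagswitch as cs
from coagswitch.assay import reference_clot_time, run_assay, steady_state_levels
from coagswitch.nomogram import monotherapy_bounds, rivaroxaban_threshold


class TestResidualState:
    def test_start_is_warfarin_steady_state(self, network, warfarin_25, switch_25):
        levels, warf = cs.residual_state(switch_25, 0.0)
        expected = steady_state_levels(warfarin_25)
        for p in cs.PROTEINS:
            assert levels[p] == pytest.approx(expected[p], rel=1e-6)
        assert warf.r_level == pytest.approx(warfarin_25.r_level, rel=1e-6)

    def test_pt_at_discontinuation_is_30s(self, network, switch_25):
        levels, _ = cs.residual_state(switch_25, 0.0)
        pt = run_assay(cs.PT_TEST, network, vk_levels=levels).clot_time
        assert pt == pytest.approx(30.0, abs=0.2)

    def test_long_time_recovers_baseline(self, switch_25):
        levels, warf = cs.residual_state(switch_25, 30 * 24.0)
        baselines = cs.TurnoverParams().baselines
        for p in cs.PROTEINS:
            assert levels[p] == pytest.approx(baselines[p], rel=0.01)
        assert warf.s_level < 1e-4

    def test_negative_time_rejected(self, switch_25):
        with pytest.raises(ValueError):
            cs.residual_state(switch_25, -1.0)


class TestThreshold:
    def test_boundary_coincidence_is_zero(self, network):
        """At the reference's own warfarin state no rivaroxaban is needed."""
        levels = steady_state_levels(cs.titrate_profile(network, 4.0))
        ct_ref = reference_clot_time(network, 4.0, cs.EXTRINSIC_STRONG)
        assert rivaroxaban_threshold(network, levels, cs.EXTRINSIC_STRONG, ct_ref) == 0.0

    def test_drug_free_state_needs_positive_exposure(self, network):
        ct_ref = reference_clot_time(network, 4.0, cs.EXTRINSIC_STRONG)
        c = rivaroxaban_threshold(network, None, cs.EXTRINSIC_STRONG, ct_ref)
        assert c > 0.0

    def test_root_residual_within_tolerance(self, network, switch_25):
        levels, _ = cs.residual_state(switch_25, 48.0)
        for trigger, inr in ((cs.EXTRINSIC_STRONG, 4.0), (cs.EXTRINSIC_WEAK, 2.0)):
            ct_ref = reference_clot_time(network, inr, trigger)
            c = rivaroxaban_threshold(network, levels, trigger, ct_ref)
            if c > 0:
                achieved = run_assay(trigger, network, vk_levels=levels,
                                     rivaroxaban_ugL=c).clot_time
                assert abs(achieved - ct_ref) <= max(0.1, 5e-5 * ct_ref)

    def test_unreachable_reference_reports_cmax(self, network):
        with pytest.raises(RuntimeError, match="c_max"):
            rivaroxaban_threshold(network, None, cs.EXTRINSIC_STRONG, 1e9, c_max=100.0)


class TestCorridor:
    def test_bounds_nonnegative_and_risk_ordered(self, coarse_corridor):
        c = coarse_corridor
        assert np.all(c.safety_high_risk >= 0)
        assert np.all(c.safety_normal >= c.safety_high_risk - 1e-9)
        assert np.all(c.efficacy_high_risk >= c.efficacy_normal - 1e-9)

    def test_corridor_widens_after_discontinuation(self, coarse_corridor):
        c = coarse_corridor
        assert c.safety_high_risk[0] < c.safety_high_risk[-1]
        assert c.safety_normal[0] < c.safety_normal[-1]
        # residual warfarin covers efficacy at the start
        assert c.efficacy_high_risk[0] == 0.0

    def test_frame_columns(self, coarse_corridor):
        df = coarse_corridor.to_frame()
        assert list(df.columns) == [
            "time_h",
            "safety_high_risk_ugL",
            "safety_normal_ugL",
            "efficacy_normal_ugL",
            "efficacy_high_risk_ugL",
        ]

    def test_start_inr_15_has_positive_efficacy_bound_at_t0(self):
        scenario = cs.SwitchScenario(1.5, cs.CAUCASIAN_MEDIAN, (0.0, 24.0))
        corr = cs.compute_corridor(scenario)
        assert corr.efficacy_high_risk[0] > 0.0

    def test_converges_to_monotherapy_window(self, network):
        """Residual warfarin gone at 30 days: bounds within 2% of drug-free."""
        mono = monotherapy_bounds(network)
        scenario = cs.SwitchScenario(2.5, cs.CAUCASIAN_MEDIAN, (0.0, 30 * 24.0))
        corr = cs.compute_corridor(scenario)
        for name in mono:
            late = getattr(corr, name)[-1]
            assert late == pytest.approx(mono[name], rel=0.02)


class TestSynergy:
    def test_slope_enhanced_at_discontinuation(self, switch_25):
        s0 = cs.synergy_slope(switch_25, 0.0)
        s_inf = cs.synergy_slope(switch_25, np.inf)
        assert s0 > 2.0 * s_inf

    def test_slope_decays_monotonically(self, switch_25):
        slopes = [cs.synergy_slope(switch_25, t) for t in (0.0, 24.0, 48.0, 72.0, 168.0)]
        assert all(a >= b for a, b in zip(slopes, slopes[1:]))

    def test_far_future_slope_matches_warfarin_free(self, switch_25):
        late = cs.synergy_slope(switch_25, 45 * 24.0)
        assert late == pytest.approx(cs.synergy_slope(switch_25, np.inf), rel=0.02)

    def test_degenerate_grid_rejected(self, switch_25):
        with pytest.raises(ValueError):
            cs.synergy_slope(switch_25, 0.0, conc_grid=(100.0,))

    def test_super_additive_combination(self, network, switch_25):
        """PT(warfarin + rivaroxaban) exceeds the additive prediction for the
        first three days, with a monotonically shrinking synergy gap."""
        base = cs.baseline_pt(network)
        riv_only = run_assay(cs.PT_TEST, network, rivaroxaban_ugL=200.0).clot_time
        gaps = []
        for t in (0.0, 24.0, 48.0, 72.0):
            levels, _ = cs.residual_state(switch_25, t)
            warf_only = run_assay(cs.PT_TEST, network, vk_levels=levels).clot_time
            combined = run_assay(
                cs.PT_TEST, network, vk_levels=levels, rivaroxaban_ugL=200.0
            ).clot_time
            additive = warf_only + (riv_only - base)
            assert combined > additive
            gaps.append(combined - additive)
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestPopulationComparison:
    def test_japanese_caucasian_inr_difference_peaks_near_two_days(self):
        """The S-warfarin clearance difference shows up most strongly about
        two days after discontinuation (INR-normalised comparison)."""
        netC = cs.get_network(cs.CAUCASIAN_MEDIAN)
        netJ = cs.get_network(cs.JAPANESE_MEDIAN)
        scnC = cs.SwitchScenario(2.5, cs.CAUCASIAN_MEDIAN)
        scnJ = cs.SwitchScenario(2.5, cs.JAPANESE_MEDIAN)
        bC, bJ = cs.baseline_pt(netC), cs.baseline_pt(netJ)
        grid = (0.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 168.0, 240.0)
        diffs = []
        for t in grid:
            lC, _ = cs.residual_state(scnC, t)
            lJ, _ = cs.residual_state(scnJ, t)
            inrC = run_assay(cs.PT_TEST, netC, vk_levels=lC).clot_time / bC
            inrJ = run_assay(cs.PT_TEST, netJ, vk_levels=lJ).clot_time / bJ
            diffs.append(abs(inrJ / inrC - 1.0))
        t_peak = grid[int(np.argmax(diffs))]
        assert 24.0 <= t_peak <= 72.0
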