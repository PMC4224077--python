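"""Warfarin pre-factor, enantiomer decay and vitamin K factor turnover."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from coagswitch.turnover import (
    PROTEINS,
    TurnoverParams,
    WarfarinState,
    decay_warfarin,
    simulate_recovery,
    steady_state,
    titrate_to_inr,
    turnover_rhs,
    warfarin_prefactor,
)


class TestPrefactor:
    @pytest.mark.parametrize(
        "r, s, expected",
        [
            (0.0, 0.0, 1.0),
            (0.4, 0.4, 1.0 / ((0.4 + 3.25 * 0.4) ** 2 + 1.0)),  # = 1/3.89
            (1.0, 0.0, 0.5),
        ],
    )
    def test_hand_values(self, r, s, expected):
        assert warfarin_prefactor(r=r, s=s) == pytest.approx(expected, rel=1e-12)

    def test_racemic_04_numeric(self):
        assert warfarin_prefactor(r=0.4, s=0.4) == pytest.approx(0.2571, abs=1e-4)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            warfarin_prefactor(r=-0.1, s=0.0)
        with pytest.raises(ValueError):
            WarfarinState(-1.0, 0.0)

    @given(
        r=st.floats(0.0, 10.0),
        s=st.floats(0.0, 10.0),
        dr=st.floats(1e-6, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_strictly_decreasing(self, r, s, dr):
        w = warfarin_prefactor(r=r, s=s)
        assert 0.0 < w <= 1.0
        assert warfarin_prefactor(r=r + dr, s=s) < w
        assert warfarin_prefactor(r=r, s=s + dr) < w

    def test_unity_only_at_zero(self):
        assert warfarin_prefactor(r=0.0, s=0.0) == 1.0
        assert warfarin_prefactor(r=1e-6, s=0.0) < 1.0


class TestDecay:
    def test_zero_elapsed_is_identity(self):
        state = WarfarinState.racemic(0.4)
        assert decay_warfarin(state, 0.0) == state

    def test_one_halflife_halves(self):
        state = WarfarinState(r_level=0.0, s_level=0.4)
        out = decay_warfarin(state, state.s_halflife)
        assert out.s_level == pytest.approx(0.2, rel=1e-12)

    def test_closed_form_r_decay(self):
        # 0.4 * 2^(-240 h / 45 h) ~ 0.00985
        state = WarfarinState(r_level=0.4, s_level=0.0)
        out = decay_warfarin(state, 240.0 * 3600.0)
        assert out.r_level == pytest.approx(0.4 * 2 ** (-240.0 / 45.0), rel=1e-12)
        assert out.r_level == pytest.approx(0.00992, abs=2e-5)

    def test_halflives_unchanged_and_semigroup(self):
        state = WarfarinState.racemic(1.0)
        one = decay_warfarin(state, 5000.0)
        two = decay_warfarin(decay_warfarin(state, 2500.0), 2500.0)
        assert one.r_halflife == state.r_halflife
        assert one.r_level == pytest.approx(two.r_level, rel=1e-12)
        assert one.s_level == pytest.approx(two.s_level, rel=1e-12)

    def test_negative_elapsed_rejected(self):
        with pytest.raises(ValueError):
            decay_warfarin(WarfarinState.racemic(0.4), -1.0)


class TestTurnoverOde:
    def test_untreated_steady_state_is_baseline(self):
        params = TurnoverParams()
        rhs = turnover_rhs(params.baseline_vector, params, 1.0)
        assert np.allclose(rhs, 0.0)

    def test_inhibited_state_decreases_factor_x(self):
        params = TurnoverParams()
        w = warfarin_prefactor(r=0.4, s=0.4)
        conc = params.baseline_vector.copy()
        rhs = turnover_rhs(conc, params, w)
        assert rhs[PROTEINS.index("fX")] < 0.0

    def test_numeric_steady_state_matches_analytic(self):
        """After 20 half-lives at fixed W the solution sits at k_i * W."""
        params = TurnoverParams()
        w0 = WarfarinState.racemic(0.0)  # W(t) = 1 throughout
        start = steady_state(params, 0.5)  # displaced initial condition
        rec = simulate_recovery(w0, params, duration=20 * max(params.halflives.values()),
                                initial=start)
        final = rec.concentrations[-1]
        assert np.allclose(final, params.baseline_vector, rtol=1e-4)

    def test_recovery_matches_variation_of_constants(self):
        """Numeric trajectory vs the closed-form quadrature solution."""
        params = TurnoverParams()
        w0 = WarfarinState.racemic(0.4)
        rec = simulate_recovery(w0, params, duration=240.0 * 3600.0)
        t_eval = 120.0 * 3600.0
        for protein in ("fVII", "fII"):
            i = PROTEINS.index(protein)
            a = params.rate_vector[i]
            k = params.baseline_vector[i]
            w_init = warfarin_prefactor(w0)

            def source(s):
                return a * k * warfarin_prefactor(decay_warfarin(w0, s)) * np.exp(-a * (t_eval - s))

            integral, _ = quad(source, 0.0, t_eval, limit=400)
            expected = k * w_init * np.exp(-a * t_eval) + integral
            assert rec(t_eval)[i] == pytest.approx(expected, rel=1e-3)

    def test_recovery_monotone_and_ordered_by_halflife(self):
        params = TurnoverParams()
        rec = simulate_recovery(WarfarinState.racemic(0.4), params)
        conc = rec.concentrations
        assert np.all(np.diff(conc, axis=0) >= -1e-12 * params.baseline_vector)
        # recovered fraction at 48 h follows the half-life ordering
        frac = {}
        w0 = warfarin_prefactor(WarfarinState.racemic(0.4))
        at = rec(48.0 * 3600.0)
        for i, p in enumerate(PROTEINS):
            k = params.baseline_vector[i]
            frac[p] = (at[i] - k * w0) / (k - k * w0)
        order = ["fVII", "protein_C", "fIX", "fX", "fII", "protein_S"]
        values = [frac[p] for p in order]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_warfarin_recovery_is_flat(self):
        params = TurnoverParams()
        rec = simulate_recovery(WarfarinState.racemic(0.0), params, duration=24 * 3600.0)
        assert np.allclose(rec.concentrations, params.baseline_vector, rtol=1e-9)

    def test_incomplete_fii_recovery_at_ten_days(self):
        """Slow factors are still below baseline 240 h after stopping."""
        params = TurnoverParams()
        rec = simulate_recovery(WarfarinState.racemic(0.4), params)
        at = rec(240.0 * 3600.0)
        assert at[PROTEINS.index("fII")] < params.baselines["fII"]
        assert at[PROTEINS.index("protein_S")] < params.baselines["protein_S"]


class TestTitration:
    def test_target_one_is_drug_free(self):
        state = titrate_to_inr(1.0, lambda st: 1.0 + st.r_level)
        assert state.r_level == 0.0 and state.s_level == 0.0

    def test_roundtrip_on_synthetic_monotone_inr(self):
        inr = lambda st: 1.0 + 4.0 * st.s_level ** 1.3
        for target in (1.5, 2.5, 3.5):
            st_ = titrate_to_inr(target, inr)
            assert inr(st_) == pytest.approx(target, abs=0.01)
            assert st_.r_level == st_.s_level  # racemic

    def test_monotone_in_target(self):
        inr = lambda st: 1.0 + 4.0 * st.s_level ** 1.3
        levels = [titrate_to_inr(t, inr).s_level for t in (1.5, 2.5, 3.5)]
        assert levels[0] < levels[1] < levels[2]

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            titrate_to_inr(0.5, lambda st: 1.0)

    def test_non_bracketing_interval_reported(self):
        with pytest.raises(ValueError, match="bracket"):
            titrate_to_inr(50.0, lambda st: 1.0 + st.s_level, bracket=(0.0, 1.0))
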