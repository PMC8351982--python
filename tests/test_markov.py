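import numpy as np
import pytest
from dataclasses import replace

from coilcea import (
    HtiEfficacySpec,
    ModelConfig,
    StateSpace,
    Status,
    age_band_utility,
    build_transition_matrix,
    discount_factor,
    enumerate_states,
    evaluate_arms,
    run_cohort,
)
from coilcea.config import STRATEGY_HTI, STRATEGY_STANDARD
from coilcea.errors import ValidationError
from coilcea.psa import draw_feasible

from conftest import make_draw, make_inert_draw


class TestStateSpace:
    def test_enumeration_counts_and_entry_state(self):
        states = enumerate_states()
        assert len(states) == 4 * 3 * 2 + 12 + 1 == 37
        labels = [s.label for s in states]
        assert "coiled(1,MRS0)" in labels
        assert labels[-1] == "dead"
        assert labels == [s.label for s in enumerate_states()]  # stable ordering

    def test_single_absorbing_state(self, mean_draw, config):
        T = build_transition_matrix(mean_draw, config, 0, STRATEGY_STANDARD)
        absorbing = [i for i in range(len(T)) if T[i, i] == 1.0 and T[i].sum() == 1.0]
        assert absorbing == [len(T) - 1]


class TestDiscounting:
    def test_closed_form_values(self):
        assert discount_factor(0, 0.015) == 1.0
        assert discount_factor(2, 0.015, 0.5) == pytest.approx(1 / 1.015)
        assert all(discount_factor(c, 0.0) == 1.0 for c in range(5))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(1, -0.01)


class TestAgeBandUtility:
    def test_band_lookup(self, mean_draw):
        assert age_band_utility(45, mean_draw) == pytest.approx(0.87)
        assert age_band_utility(80, mean_draw) == pytest.approx(0.84)
        # half-open bands: exactly 55 falls in the 55-64 band
        assert age_band_utility(55, mean_draw) == pytest.approx(0.85)


class TestTransitionMatrix:
    @pytest.mark.parametrize("strategy", [STRATEGY_STANDARD, STRATEGY_HTI])
    @pytest.mark.parametrize("cycle", [0, 10, 30, 59])
    def test_rows_are_distributions(self, mean_draw, config, strategy, cycle):
        T = build_transition_matrix(mean_draw, config, cycle, strategy)
        assert np.all(T >= 0) and np.all(T <= 1)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_random_draw_rows_are_distributions(self, specs, config, rng):
        ds, _ = draw_feasible(specs, HtiEfficacySpec("uniform01"), 20, rng)
        for k in range(20):
            T = build_transition_matrix(ds.row(k), config, 5, STRATEGY_HTI)
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)

    def test_inert_draw_freezes_reachable_states(self):
        # with every event probability zero and no background mortality,
        # coiled/unsecured/dead rows are identity; tunnel states (which are
        # unreachable without ruptures) still resolve within one cycle
        cfg = ModelConfig(background_mortality=False)
        T = build_transition_matrix(make_inert_draw(), cfg, 0, STRATEGY_STANDARD)
        sp = StateSpace()
        reachable = [i for i, st in enumerate(sp.states) if st.kind != "asah"]
        for i in reachable:
            assert T[i, i] == 1.0 and T[i].sum() == 1.0

    def test_full_efficacy_stops_index_coil_recanalization(self, config):
        draw = make_draw(rrr=1.0, overrides={6: 0.0})  # no de novo aneurysms
        T = build_transition_matrix(draw, config, 0, STRATEGY_HTI)
        sp = StateSpace()
        for s in (Status.MRS0, Status.MRS1_2, Status.MRS3_5):
            assert T[sp.coiled(1, s), sp.unsecured(1, s)] == 0.0
        # later coils keep their recanalization risk
        assert T[sp.coiled(2, Status.MRS0), sp.unsecured(2, Status.MRS0)] > 0

    def test_hazard_config_reproduces_constant_hazard_flow(self):
        # under the constant-hazard convention with no risk window and no
        # background mortality, the coiled->unsecured flow is the combined
        # recanalization + de novo probability
        cfg = ModelConfig(
            background_mortality=False,
            prob_conversion="hazard",
            recan_window_years=None,
        )
        draw = make_draw(rrr=0.0)
        T = build_transition_matrix(draw, cfg, 0, STRATEGY_STANDARD)
        sp = StateSpace()
        p_rec = 1 - (1 - 0.244) ** (0.5 / 6)
        p_nov = 1 - (1 - 0.006) ** 0.5
        expected = 1 - (1 - p_rec) * (1 - p_nov)
        assert p_rec == pytest.approx(0.02303, abs=5e-5)
        assert T[sp.coiled(1, Status.MRS0), sp.unsecured(1, Status.MRS0)] == pytest.approx(
            expected, abs=1e-12
        )

    def test_recanalization_window_closes(self, mean_draw, config):
        sp = StateSpace()
        late = int(config.recan_window_years / config.cycle_years)
        T = build_transition_matrix(mean_draw, config, late, STRATEGY_STANDARD)
        p_nov_only = T[sp.coiled(1, Status.MRS0), sp.unsecured(1, Status.MRS0)]
        T0 = build_transition_matrix(mean_draw, config, 0, STRATEGY_STANDARD)
        assert p_nov_only < T0[sp.coiled(1, Status.MRS0), sp.unsecured(1, Status.MRS0)]

    def test_cycle_out_of_range(self, mean_draw, config):
        with pytest.raises(ValidationError):
            build_transition_matrix(mean_draw, config, 60, STRATEGY_STANDARD)


class TestCohort:
    def test_annuity_closed_form(self):
        cfg = ModelConfig(discount_rate=0.0, background_mortality=False)
        _, out = run_cohort(make_inert_draw(utility=0.87), cfg, STRATEGY_STANDARD)
        assert out.discounted_qaly == pytest.approx(30 * 0.87, abs=1e-9)
        assert out.discounted_qaly == pytest.approx(out.undiscounted_qaly)

    def test_zero_efficacy_and_price_make_arms_identical(self, config, mean_draw):
        cfg = replace(config, hti_price=0.0)
        draw = make_draw(rrr=0.0)
        _, std = run_cohort(draw, cfg, STRATEGY_STANDARD)
        _, hti = run_cohort(draw, cfg, STRATEGY_HTI)
        assert std.discounted_cost == hti.discounted_cost
        assert std.discounted_qaly == hti.discounted_qaly

    def test_adjunct_price_charged_undiscounted_at_entry(self, config, mean_draw):
        _, std = run_cohort(mean_draw, config, STRATEGY_STANDARD)
        cfg0 = replace(config, hti_price=0.0)
        _, hti0 = run_cohort(make_draw(rrr=0.0), cfg0, STRATEGY_HTI)
        _, hti = run_cohort(make_draw(rrr=0.0), config, STRATEGY_HTI)
        assert hti.discounted_cost - hti0.discounted_cost == pytest.approx(10_000)

    def test_trace_conserves_mass_and_absorbs(self, specs, config, rng):
        ds, _ = draw_feasible(specs, HtiEfficacySpec("uniform01"), 50, rng)
        sp = StateSpace()
        for k in range(50):
            trace, _ = run_cohort(ds.row(k), config, STRATEGY_HTI)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            assert trace.occupancy.min() >= -1e-15
            dead = trace.occupancy[:, sp.dead]
            assert np.all(np.diff(dead) >= -1e-12)

    def test_dominance_under_common_draws(self, specs, rng):
        cfg = ModelConfig(hti_price=0.0)
        ds, _ = draw_feasible(specs, HtiEfficacySpec("uniform01"), 2_000, rng)
        out = evaluate_arms(ds, cfg)
        assert np.all(out["qaly_hti"] - out["qaly_std"] >= -1e-9)
        assert np.all(out["cost_hti"] - out["cost_std"] <= 1e-9)

    def test_discounting_monotone(self, specs, rng):
        ds, _ = draw_feasible(specs, HtiEfficacySpec("uniform01"), 200, rng)
        prev_cost = prev_qaly = None
        for rate in (0.0, 0.015, 0.05):
            out = evaluate_arms(ds, ModelConfig(discount_rate=rate))
            if prev_cost is not None:
                assert np.all(out["cost_std"] <= prev_cost + 1e-9)
                assert np.all(out["qaly_std"] <= prev_qaly + 1e-9)
            prev_cost, prev_qaly = out["cost_std"], out["qaly_std"]

    def test_discounted_never_exceeds_undiscounted(self, mean_draw, config):
        _, out = run_cohort(mean_draw, config, STRATEGY_STANDARD)
        assert out.discounted_cost <= out.undiscounted_cost
        assert out.discounted_qaly <= out.undiscounted_qaly
        assert 0 < out.discounted_qaly < 30 * 0.88
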