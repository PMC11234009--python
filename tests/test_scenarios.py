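"""Scenario grid, survival extraction, comparisons, and rewarming."""

import numpy as np
import pytest

from coldwater import (
    Scenario,
    average_cooling_rate,
    builtin_rewarming_scenarios,
    builtin_scenarios,
    compare_reduction,
    run_rewarming,
    survival_time_from_series,
)
from coldwater.scenarios import summarize_cooling


class TestScenarioDefinitions:
    def test_builtin_cooling_grid(self):
        scenarios = builtin_scenarios()
        assert len(scenarios) == 15  # 1 + 3 + 3 + 4 + 4
        labels = {s.label for s in scenarios}
        assert "fresh_still_5C" in labels
        assert "salt_moving_-2C" in labels

    def test_default_heat_transfer_coefficients(self):
        by_label = {s.label: s for s in builtin_scenarios()}
        assert by_label["fresh_still_5C"].h_eff == 220.0
        assert by_label["fresh_moving_0C"].h_eff == 460.0
        assert by_label["salt_still_-2C"].h_eff == 480.0
        assert by_label["salt_moving_-2C"].h_eff == 680.0
        assert by_label["fresh_still_18.5C"].h_eff == 139.0

    def test_freshwater_freezing_floor(self):
        with pytest.raises(ValueError, match="frozen"):
            Scenario("bad", "fresh_still", -1.0)
        # seawater admits down to -2 °C
        Scenario("ok", "salt_still", -2.0)
        with pytest.raises(ValueError, match="frozen"):
            Scenario("bad", "salt_still", -3.0)

    def test_rewarming_grid(self):
        scenarios = builtin_rewarming_scenarios()
        assert len(scenarios) == 6
        assert all(s.mode == "rewarming" for s in scenarios)
        assert {s.T_ext for s in scenarios} == {41.0, 43.0}


class TestSurvivalExtraction:
    def test_linear_interpolation_between_samples(self):
        # (100 min, 30.2), (101 min, 29.8) -> crossing at 100.5
        t = [99.0, 100.0, 101.0]
        x = [30.6, 30.2, 29.8]
        assert survival_time_from_series(t, x) == pytest.approx(100.5)

    def test_trace_starting_below_threshold(self):
        assert survival_time_from_series([0.0, 1.0], [29.0, 28.0]) == 0.0

    def test_never_crossing_returns_none(self):
        assert survival_time_from_series([0.0, 60.0], [37.0, 36.0]) is None

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            survival_time_from_series([], [])


class TestAverageCoolingRate:
    def test_traverse_convention(self):
        # (37.2 - 30.0)/136; close to the 0.0533 °C/min quoted for 136 min
        assert average_cooling_rate(136.0) == pytest.approx(7.2 / 136.0)
        assert average_cooling_rate(136.0) == pytest.approx(0.0533, rel=0.01)

    def test_direct_division(self):
        assert average_cooling_rate(100.0) == pytest.approx(0.072)

    def test_identity_rate_times_time(self):
        for ts in (57.0, 88.0, 136.0):
            assert average_cooling_rate(ts) * ts == pytest.approx(7.2)

    def test_invalid(self):
        with pytest.raises(ValueError):
            average_cooling_rate(0.0)


class TestCompareReduction:
    def test_published_fresh_water_times_give_16_percent(self):
        # mean of 12.5 %, 18.6 %, 17.0 %
        assert compare_reduction((136, 113, 100), (119, 92, 83)) == pytest.approx(
            16.0, abs=0.05
        )

    def test_published_salt_water_times(self):
        assert compare_reduction((111, 88, 80, 66), (98, 74, 68, 57)) == pytest.approx(
            14.05, abs=0.05
        )

    def test_identity(self):
        assert compare_reduction((10, 20), (10, 20)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_reduction((1, 2), (1, 2, 3))


class TestCoolingSuite:
    """Assertions on the session-scoped full grid run."""

    def test_every_scenario_completed(self, cooling_suite):
        assert len(cooling_suite) == 15
        assert all(s.error is None for s in cooling_suite.values())

    def test_all_cold_scenarios_cross_threshold(self, cooling_suite):
        for label, s in cooling_suite.items():
            if s.T_ext <= 5.0:
                assert s.survival_time_min is not None, label
                assert s.survival_time_min < 160.0

    def test_warm_scenario_stabilizes(self, cooling_suite):
        assert cooling_suite["fresh_still_18.5C"].survival_time_min is None

    def test_survival_monotone_in_water_temperature(self, cooling_suite):
        for prefix, temps in [
            ("fresh_still", (5, 2, 0)),
            ("fresh_moving", (5, 2, 0)),
            ("salt_still", (5, 2, 0, -2)),
            ("salt_moving", (5, 2, 0, -2)),
        ]:
            times = [cooling_suite[f"{prefix}_{t}C"].survival_time_min for t in temps]
            assert all(a > b for a, b in zip(times, times[1:])), prefix

    def test_moving_always_faster_than_still(self, cooling_suite):
        for medium in ("fresh", "salt"):
            temps = (5, 2, 0) if medium == "fresh" else (5, 2, 0, -2)
            for t in temps:
                still = cooling_suite[f"{medium}_still_{t}C"].survival_time_min
                moving = cooling_suite[f"{medium}_moving_{t}C"].survival_time_min
                assert moving < still

    def test_salt_always_faster_than_fresh(self, cooling_suite):
        for flow in ("still", "moving"):
            for t in (5, 2, 0):
                fresh = cooling_suite[f"fresh_{flow}_{t}C"].survival_time_min
                salt = cooling_suite[f"salt_{flow}_{t}C"].survival_time_min
                assert salt < fresh

    def test_thermal_shock_flag_for_cold_water(self, cooling_suite):
        """Mean skin drops below 20 °C within a minute in ≤5 °C water."""
        for label, s in cooling_suite.items():
            if s.T_ext <= 5.0:
                assert s.thermal_shock, label
        assert not cooling_suite["fresh_still_18.5C"].thermal_shock


class TestRewarming:
    def test_rewarming_from_posthypothermic_state(self, body, posthypo_state):
        from coldwater import BioheatModel

        model = BioheatModel(body)
        sc = Scenario("rw41", "fresh_still", 41.0, h=220.0, mode="rewarming",
                      t_max_min=150.0)
        rw = run_rewarming(sc, model=model, initial_state=posthypo_state)
        assert rw.time_to_37_min is not None
        assert rw.rewarming_rate_C_per_h > 0
        assert rw.peak_skin <= 41.0 + 1e-6
        assert not rw.tissue_damage

    def test_bath_colder_than_body_rejected(self, body, posthypo_state):
        from coldwater import BioheatModel

        model = BioheatModel(body)
        sc = Scenario("rw20", "fresh_still", 20.0, h=220.0, mode="rewarming")
        with pytest.raises(ValueError, match="colder"):
            run_rewarming(sc, model=model, initial_state=posthypo_state)

    def test_body_already_at_bath_temperature(self, body):
        from coldwater import BioheatModel

        model = BioheatModel(body)
        state = model.initial_state()  # rectal at 37
        sc = Scenario("rw37", "fresh_still", 37.0, h=220.0, mode="rewarming",
                      t_max_min=5.0)
        rw = run_rewarming(sc, model=model, initial_state=state)
        assert rw.time_to_37_min == 0.0

    def test_posthypothermic_state_rectal_is_30(self, body, posthypo_state):
        from coldwater import BioheatModel

        model = BioheatModel(body)
        assert model.rectal(posthypo_state) == pytest.approx(30.0, abs=1e-9)

    def test_cooling_scenario_rejected(self, body):
        sc = Scenario("cool", "fresh_still", 5.0)
        with pytest.raises(ValueError, match="not a rewarming"):
            run_rewarming(sc, body)
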