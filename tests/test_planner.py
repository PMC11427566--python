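"""Step-count models, executable schedules, and the grid droplet simulator."""

import pytest

from dropletbench import (
    Droplet,
    GridSpec,
    SplitPlan,
    StrategySpec,
    build_schedule,
    simulate_schedule,
    step_count,
    strategy_comparison,
)
from dropletbench.planner import ONE_TO_TWO_STEPS, _chebyshev

GRID = GridSpec(n_cols=96, n_rows=16)


def spec(name, x):
    return StrategySpec(name=name, n_subdroplets=x)


class TestStepCount:
    @pytest.mark.parametrize(
        "name, x, expected",
        [
            ("squeeze", 16, 81),
            ("one_to_three", 16, 97),
            ("one_to_two", 16, 13),
            ("squeeze", 1, 6),
            ("one_to_three", 1, 7),
            ("one_to_two", 1, 1),
            ("one_to_two", 4, 6),
            ("one_to_two", 8, 10),
        ],
    )
    def test_model_values(self, name, x, expected):
        assert step_count(spec(name, x)) == expected

    @pytest.mark.parametrize("name, x", [("squeeze", 17), ("one_to_three", 20), ("one_to_two", 5)])
    def test_domain_errors_cite_range(self, name, x):
        with pytest.raises(ValueError, match="x"):
            step_count(spec(name, x))

    def test_strategy_ordering(self):
        """one_to_two < squeeze < one_to_three for every shared x >= 2."""
        for x in (2, 4, 8, 16):
            s, t, d = (step_count(spec(n, x)) for n in ("squeeze", "one_to_three", "one_to_two"))
            assert d < s < t


class TestStrategyComparison:
    def test_savings_at_sixteen(self):
        comp = strategy_comparison(16)
        assert comp.savings_s[("squeeze", "one_to_two")] == 68.0
        assert comp.savings_s[("one_to_three", "one_to_two")] == 84.0

    def test_durations_at_one(self):
        comp = strategy_comparison(1)
        table = comp.table.set_index("strategy")["duration_s"]
        assert (table["squeeze"], table["one_to_three"], table["one_to_two"]) == (6.0, 7.0, 1.0)


class TestSimulator:
    def test_fixed_point_when_activating_current_support(self):
        d = Droplet(frozenset({(3, 3), (4, 3)}), 2.0)
        out = simulate_schedule([frozenset(d.support)] * 3, GRID, [d])
        assert out == [d]

    def test_tear_into_two(self):
        d = Droplet(frozenset({(3, 3), (4, 3)}), 2.0)
        out = simulate_schedule([frozenset({(2, 3), (5, 3)})], GRID, [d])
        assert sorted(dd.support for dd in out) == [frozenset({(2, 3)}), frozenset({(5, 3)})]
        assert [dd.volume for dd in out] == [1.0, 1.0]

    def test_adjacent_droplets_merge(self):
        a = Droplet(frozenset({(2, 3)}), 1.0)
        b = Droplet(frozenset({(6, 3)}), 1.0)
        steps = [frozenset({(3, 3), (5, 3)}), frozenset({(4, 3), (5, 3)})]
        out = simulate_schedule(steps, GRID, [a, b])
        assert len(out) == 1
        assert out[0].volume == 2.0

    def test_off_grid_activation_rejected(self):
        with pytest.raises(ValueError, match="off-grid"):
            simulate_schedule([frozenset({(-1, 0)})], GRID, [Droplet(frozenset({(0, 0)}))])

    def test_volume_conserved_through_any_plan(self):
        plan = build_schedule(spec("one_to_two", 16), GRID)
        states = simulate_schedule(plan, GRID, history=True)
        total0 = sum(d.volume for d in states[0])
        for state in states:
            assert sum(d.volume for d in state) == pytest.approx(total0)


class TestSchedules:
    @pytest.mark.parametrize("x", sorted(ONE_TO_TWO_STEPS))
    def test_one_to_two_ladder(self, x):
        plan = build_schedule(spec("one_to_two", x), GRID)
        assert plan.step_count == ONE_TO_TWO_STEPS[x]
        final = simulate_schedule(plan, GRID)
        assert len(final) == x

    @pytest.mark.parametrize("name", ["squeeze", "one_to_three"])
    @pytest.mark.parametrize("x", [1, 2, 5, 16])
    def test_linear_strategies_match_model(self, name, x):
        plan = build_schedule(spec(name, x), GRID)
        assert plan.step_count == step_count(spec(name, x))
        assert len(simulate_schedule(plan, GRID)) == x

    def test_squeeze_x2_never_risks_merging(self):
        """During the run no two droplets come within merging (8-adjacency) range."""
        plan = build_schedule(spec("squeeze", 2), GRID)
        assert plan.step_count == 11
        for state in simulate_schedule(plan, GRID, history=True):
            for i in range(len(state)):
                for j in range(i + 1, len(state)):
                    assert _chebyshev(state[i].support, state[j].support) >= 2

    def test_final_spacing_at_least_four(self):
        for name, x in [("squeeze", 4), ("one_to_three", 3), ("one_to_two", 16)]:
            plan = build_schedule(spec(name, x), GRID)
            final = simulate_schedule(plan, GRID)
            for i in range(len(final)):
                for j in range(i + 1, len(final)):
                    assert _chebyshev(final[i].support, final[j].support) >= 4

    @pytest.mark.parametrize("x", [3, 5, 6, 7, 9, 11, 13, 15])
    def test_generalized_doubling_then_trim(self, x):
        plan = build_schedule(spec("one_to_two", x), GRID)
        final = simulate_schedule(plan, GRID)
        assert len(final) == x
        # trimmed plans reuse the parent ladder's step budget
        p = 1
        while p < x:
            p *= 2
        assert plan.step_count == ONE_TO_TWO_STEPS[p]

    def test_grid_too_small_reports_requirement(self):
        with pytest.raises(ValueError, match="at least"):
            build_schedule(spec("squeeze", 16), GridSpec(n_cols=20, n_rows=4))

    def test_plan_duration_tracks_step_duration(self):
        s = StrategySpec(name="one_to_two", n_subdroplets=4, step_duration_s=2.5)
        plan = build_schedule(s, GRID)
        assert plan.duration_s == pytest.approx(plan.step_count * 2.5)
        assert isinstance(plan, SplitPlan)
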