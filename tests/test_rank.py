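"""Ranking attributes, participation-ratio selection and CMY colouring."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itmflow import (
    ModelQuery,
    SelectionCriterion,
    ValidationError,
    build_evolution_operator,
    mix_colors,
    participation_ratio,
    ranking_values,
    select_nodes,
    solve_absorbing,
    solve_emitting,
)


class TestRankingValues:
    def test_single_source_total_equals_per_source(self, path3, emitting_query):
        res = solve_emitting(build_evolution_operator(path3, 0.9, emitting_query))
        assert ranking_values(res, "total") == ranking_values(res, "a")

    def test_absorbing_total_worked_example(self, path3, absorbing_query):
        res = solve_absorbing(build_evolution_operator(path3, 0.9, absorbing_query))
        totals = ranking_values(res, "total")
        assert totals["a"] == pytest.approx(0.81 / 1.19)
        assert totals["b"] == pytest.approx(0.9 / 1.19)

    def test_interference_is_elementwise_min(self):
        from itmflow import make_fixture

        g = make_fixture("path", 5)
        q = ModelQuery("emitting", sources=("a", "e"))
        res = solve_emitting(build_evolution_operator(g, 0.8, q))
        per = [ranking_values(res, s) for s in ("a", "e")]
        inter = ranking_values(res, "interference")
        for n in inter:
            assert inter[n] == min(per[0][n], per[1][n])

    def test_custom_column_passes_through(self, path3, absorbing_query):
        res = solve_absorbing(build_evolution_operator(path3, 0.9, absorbing_query))
        res.custom["myattr"] = {"a": 5.0, "b": 1.0}
        assert ranking_values(res, "myattr") == {"a": 5.0, "b": 1.0}

    def test_unknown_choice_lists_valid_ones(self, path3, absorbing_query):
        res = solve_absorbing(build_evolution_operator(path3, 0.9, absorbing_query))
        with pytest.raises(ValidationError, match="total"):
            ranking_values(res, "bogus")


class TestParticipationRatio:
    @pytest.mark.parametrize(
        "values,expected",
        [({"a": 1, "b": 1, "c": 1, "d": 1}, 4),
         ({"a": 1, "b": 0, "c": 0, "d": 0}, 1),
         ({"a": 2, "b": 1, "c": 1}, 3)],  # round(16/6)
    )
    def test_known_counts(self, values, expected):
        assert participation_ratio(values) == expected

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            participation_ratio({"a": 0.0})

    @given(
        st.lists(st.floats(0.001, 1000.0), min_size=1, max_size=20),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, vals, c):
        values = {f"n{i}": v for i, v in enumerate(vals)}
        scaled = {k: c * v for k, v in values.items()}
        assert participation_ratio(values) == participation_ratio(scaled)


class TestSelection:
    VALUES = {"a": 5.0, "b": 2.0, "c": 0.1}

    def test_strict_cutoff(self):
        sel = select_nodes(self.VALUES, SelectionCriterion("cutoff", 1.0))
        assert sel.selected == ["a", "b"]
        sel2 = select_nodes(self.VALUES, SelectionCriterion("cutoff", 5.0))
        assert sel2.selected == []  # strictly greater

    def test_top_k(self):
        sel = select_nodes(self.VALUES, SelectionCriterion("top_k", 2))
        assert sel.selected == ["a", "b"]

    def test_top_k_limited_to_positive_values(self):
        sel = select_nodes({"a": 1.0, "b": 0.0}, SelectionCriterion("top_k", 5))
        assert sel.selected == ["a"]

    def test_participation_ratio_selection(self):
        sel = select_nodes(
            {"a": 2.0, "b": 1.0, "c": 1.0, "d": 0.0},
            SelectionCriterion("participation_ratio"),
        )
        assert len(sel.selected) == 3

    def test_pr_selection_scale_invariant(self):
        values = {"a": 2.0, "b": 1.0, "c": 1.0, "d": 0.01}
        crit = SelectionCriterion("participation_ratio")
        base = select_nodes(values, crit).selected
        scaled = select_nodes({k: 37.5 * v for k, v in values.items()}, crit).selected
        assert base == scaled

    def test_ties_break_by_node_id(self):
        sel = select_nodes({"z": 1.0, "a": 1.0}, SelectionCriterion("top_k", 2))
        assert sel.selected == ["a", "z"]

    def test_raising_cutoff_never_adds_nodes(self):
        lo = set(select_nodes(self.VALUES, SelectionCriterion("cutoff", 0.05)).selected)
        hi = set(select_nodes(self.VALUES, SelectionCriterion("cutoff", 1.0)).selected)
        assert hi <= lo

    def test_bad_k_rejected(self):
        with pytest.raises(ValidationError):
            SelectionCriterion("top_k", 0)


class TestColors:
    def test_max_node_gets_full_first_hue(self):
        colors = mix_colors([{"a": 4.0, "b": 1.0}], scaling="linear")
        assert colors["a"] == pytest.approx((0.0, 1.0, 1.0))  # pure cyan

    def test_zero_flow_is_white(self):
        colors = mix_colors([{"a": 1.0, "b": 0.0}, {"a": 1.0, "b": 0.0}])
        assert colors["b"] == pytest.approx((1.0, 1.0, 1.0))

    def test_two_equal_maxima_blend_subtractively(self):
        colors = mix_colors([{"a": 2.0}, {"a": 2.0}], scaling="linear")
        assert colors["a"] == pytest.approx((0.0, 0.0, 1.0))  # cyan + magenta

    def test_components_stay_in_unit_interval(self):
        cols = [{"a": 3.0, "b": 0.2}, {"a": 0.1, "b": 9.0}, {"a": 1.0, "b": 1.0}]
        for scaling in ("linear", "sqrt", "log"):
            for rgb in mix_colors(cols, scaling=scaling).values():
                assert all(0.0 <= x <= 1.0 for x in rgb)

    def test_dominant_source_sets_hue(self):
        colors = mix_colors([{"a": 5.0, "b": 0.1}, {"a": 0.1, "b": 5.0}], "linear")
        # node a dominated by the cyan column: red is its smallest component
        assert min(colors["a"]) == colors["a"][0]

    def test_more_than_three_columns_rejected(self):
        with pytest.raises(ValidationError, match="three"):
            mix_colors([{"a": 1.0}] * 4)
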