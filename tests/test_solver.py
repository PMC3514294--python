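"""Linear-solve flow models against closed forms on small graphs.

The a-b-c chain admits hand solutions: with mu = 0.9 and sink c,
F_ac = 0.81/1.19, F_bc = 0.9/1.19; with source a, H_ab = 0.9/0.595 and
H_ac = 0.405/0.595.  These anchor every model before the Monte Carlo
cross-checks in test_oracle.py take over on bigger graphs.
"""

import numpy as np
import pytest

from itmflow import (
    ModelQuery,
    NumericalError,
    ValidationError,
    build_evolution_operator,
    interference,
    make_fixture,
    mean_absorption,
    mean_path_length,
    shortest_boundary_path,
    solve_absorbing,
    solve_channel,
    solve_emitting,
)


class TestEvolutionOperator:
    def test_row_normalisation_with_damping(self, path3, emitting_query):
        op = build_evolution_operator(path3, 0.9, emitting_query)
        P = op.P.toarray()
        i = {n: k for k, n in enumerate(path3.nodes)}
        assert P[i["a"], i["b"]] == pytest.approx(0.9)
        assert P[i["b"], i["a"]] == pytest.approx(0.45)
        assert P[i["b"], i["c"]] == pytest.approx(0.45)

    def test_one_step_leak_is_ten_percent_at_mu_09(self, path3, emitting_query):
        op = build_evolution_operator(path3, 0.9, emitting_query)
        rowsums = np.asarray(op.P.sum(axis=1)).ravel()
        assert rowsums == pytest.approx([0.9, 0.9, 0.9])

    def test_mu_zero_gives_zero_operator(self, path3, emitting_query):
        op = build_evolution_operator(path3, 0.0, emitting_query)
        assert op.P.nnz == 0

    def test_mu_out_of_range_rejected(self, path3, emitting_query):
        with pytest.raises(ValidationError, match="outside"):
            build_evolution_operator(path3, 1.2, emitting_query)

    def test_overlapping_boundaries_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            ModelQuery("channel", sources=("a",), sinks=("a",))


class TestAbsorbing:
    def test_path_worked_example(self, path3, absorbing_query):
        res = solve_absorbing(build_evolution_operator(path3, 0.9, absorbing_query))
        F = dict(zip(res.transient_nodes, res.F.ravel()))
        assert F["a"] == pytest.approx(0.81 / 1.19, abs=1e-12)
        assert F["b"] == pytest.approx(0.9 / 1.19, abs=1e-12)

    def test_no_damping_conserves_probability(self, path3, absorbing_query):
        res = solve_absorbing(build_evolution_operator(path3, 1.0, absorbing_query))
        assert np.allclose(res.F.sum(axis=1), 1.0, atol=1e-10)

    def test_mean_absorption_worked_example(self, path3, absorbing_query):
        res = solve_absorbing(build_evolution_operator(path3, 0.9, absorbing_query))
        assert res.r_bar == pytest.approx((0.81 / 1.19 + 0.9 / 1.19) / 2, abs=1e-12)

    def test_sink_unreachable_node_gets_zero_row(self):
        # directed chain a->b->c plus isolated pair d<->e; sink c
        g = make_fixture("path", 3)
        from itmflow import WeightedDigraph

        wm = g.weight_map()
        wm[("d", "e")] = 1.0
        wm[("e", "d")] = 1.0
        g2 = WeightedDigraph.from_weight_map(wm)
        q = ModelQuery("absorbing", sinks=("c",))
        res = solve_absorbing(build_evolution_operator(g2, 0.5, q))
        F = dict(zip(res.transient_nodes, res.F.ravel()))
        assert F["d"] == 0.0 and F["e"] == 0.0
        # ... and they are excluded from the r_bar average
        op = build_evolution_operator(g2, 0.5, q)
        assert mean_absorption(res, op) == pytest.approx((F["a"] + F["b"]) / 2)

    def test_mu_one_with_unreachable_nodes_names_them(self):
        from itmflow import WeightedDigraph

        g = WeightedDigraph.from_weight_map(
            {("a", "b"): 1.0, ("b", "a"): 1.0, ("b", "c"): 1.0, ("c", "b"): 1.0,
             ("d", "e"): 1.0, ("e", "d"): 1.0}
        )
        q = ModelQuery("absorbing", sinks=("c",))
        with pytest.raises(NumericalError, match="d"):
            solve_absorbing(build_evolution_operator(g, 1.0, q))

    def test_residual_below_tolerance(self, absorbing_query):
        g = make_fixture("random_er", 30, seed=5)
        q = ModelQuery("absorbing", sinks=(g.nodes[0],))
        op = build_evolution_operator(g, 0.9, q)
        res = solve_absorbing(op)
        A = op.transient_system()
        B = np.asarray(op.P[np.ix_(op.transient_idx, op.sink_idx)].todense())
        assert np.abs(A @ res.F - B).max() < 1e-9


class TestEmitting:
    def test_path_worked_example(self, path3, emitting_query):
        res = solve_emitting(build_evolution_operator(path3, 0.9, emitting_query))
        H = dict(zip(res.transient_nodes, res.H[0]))
        assert H["b"] == pytest.approx(0.9 / 0.595, abs=1e-12)
        assert H["c"] == pytest.approx(0.405 / 0.595, abs=1e-12)
        assert res.t_bar == pytest.approx(3.193277310924, abs=1e-9)

    def test_visits_can_exceed_one(self, path3, emitting_query):
        res = solve_emitting(build_evolution_operator(path3, 0.9, emitting_query))
        assert res.H.max() > 1.0  # revisits accumulate

    def test_mu_zero_warns_and_returns_zero(self, path3, emitting_query):
        with pytest.warns(UserWarning, match="mu = 0"):
            res = solve_emitting(build_evolution_operator(path3, 0.0, emitting_query))
        assert not res.H.any()
        assert res.t_bar == 1.0

    def test_isolated_source_has_unit_path_length(self):
        from itmflow import WeightedDigraph

        g = WeightedDigraph.from_weight_map({("b", "c"): 1.0}, extra_nodes=["a"])
        res = solve_emitting(
            build_evolution_operator(g, 0.5, ModelQuery("emitting", sources=("a",)))
        )
        assert mean_path_length(res) == 1.0

    def test_mu_one_rejected(self, path3, emitting_query):
        with pytest.raises(ValidationError, match="mu < 1"):
            solve_emitting(build_evolution_operator(path3, 1.0, emitting_query))

    def test_t_bar_strictly_increasing_in_mu(self, emitting_query):
        g = make_fixture("random_er", 20, seed=3)
        q = ModelQuery("emitting", sources=(g.nodes[0],))
        values = [
            solve_emitting(build_evolution_operator(g, mu, q)).t_bar
            for mu in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_r_bar_nondecreasing_in_mu(self):
        g = make_fixture("random_er", 20, seed=3)
        q = ModelQuery("absorbing", sinks=(g.nodes[0],))
        values = [
            solve_absorbing(build_evolution_operator(g, mu, q)).r_bar
            for mu in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(1.0, abs=1e-10)


class TestChannel:
    @pytest.mark.parametrize("mu", [0.05, 0.3, 0.6, 0.95])
    def test_single_path_intermediate_is_always_one(self, path3, channel_query, mu):
        res = solve_channel(build_evolution_operator(path3, mu, channel_query))
        assert res.Phi_hat.ravel() == pytest.approx([1.0], abs=1e-12)
        assert res.t_bar == pytest.approx(2.0, abs=1e-12)

    def test_source_denominator_is_one_step_extension(self, path3, channel_query):
        mu = 0.7
        res = solve_channel(build_evolution_operator(path3, mu, channel_query))
        # F_sc = P_ab * F_bc = mu * mu/2
        assert res.F_source.ravel() == pytest.approx([mu**2 / 2], abs=1e-12)

    def test_strong_damping_confines_flow_to_shortest_path(self):
        g = make_fixture("parallel_paths", 5)
        q = ModelQuery("channel", sources=("s",), sinks=("t",))
        res = solve_channel(build_evolution_operator(g, 0.01, q))
        off = [
            v for n, v in zip(res.transient_nodes, res.Phi_hat[0])
            if n.startswith("q")
        ]
        assert sum(off) < 1e-3
        on = {
            n: v for n, v in zip(res.transient_nodes, res.Phi_hat[0])
            if n.startswith("p")
        }
        assert all(v > 0.99 for v in on.values())

    def test_path_length_bounded_by_shortest_path(self):
        g = make_fixture("parallel_paths", 5)
        q = ModelQuery("channel", sources=("s",), sinks=("t",))
        for mu in (0.05, 0.5, 0.95):
            op = build_evolution_operator(g, mu, q)
            res = solve_channel(op)
            assert res.t_bar >= shortest_boundary_path(op) - 1e-9

    def test_nearer_sink_captures_larger_share(self):
        # source at one end; near sink 2 hops away, far sink 6 hops away
        g = make_fixture("path", 7)
        q = ModelQuery("channel", sources=(g.nodes[2],),
                       sinks=(g.nodes[0], g.nodes[6]))
        res = solve_channel(build_evolution_operator(g, 0.8, q))
        near, far = res.F_source[0][res.sinks.index(g.nodes[0])], \
            res.F_source[0][res.sinks.index(g.nodes[6])]
        assert near > far

    def test_source_cut_off_from_sinks_is_named(self):
        from itmflow import WeightedDigraph

        g = WeightedDigraph.from_weight_map(
            {("a", "b"): 1.0, ("b", "a"): 1.0, ("c", "d"): 1.0, ("d", "c"): 1.0}
        )
        q = ModelQuery("channel", sources=("a",), sinks=("d",))
        with pytest.raises(ValidationError, match="'a'"):
            solve_channel(build_evolution_operator(g, 0.5, q))


class TestInterference:
    def test_single_source_equals_its_row(self, path3, emitting_query):
        res = solve_emitting(build_evolution_operator(path3, 0.9, emitting_query))
        inter = interference(res)
        assert inter == dict(zip(res.transient_nodes, res.H[0]))

    def test_two_opposed_sources_peak_in_between(self):
        g = make_fixture("path", 5)  # a-b-c-d-e
        q = ModelQuery("emitting", sources=("a", "e"))
        res = solve_emitting(build_evolution_operator(g, 0.9, q))
        inter = interference(res)
        assert max(inter, key=inter.get) == "c"
        assert inter["c"] > inter["b"] and inter["c"] > inter["d"]
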