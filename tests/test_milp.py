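from fractions import Fraction

import pytest

from hyperfactory import (
    FactoryProblem,
    HypergraphError,
    active_sources_of,
    build_hypergraph,
    build_model,
    random_instance,
    solve,
    validate_factory,
)
from hyperfactory.synthetic import ExactCoverInstance, reduce_exact_cover


class TestModelStructure:
    def test_single_edge_constraint_counts(self, single_edge):
        model = build_model(FactoryProblem(single_edge))
        assert len(model.by_tag("conservation")) == 0  # no intermediates
        assert len(model.by_tag("production")) == 1
        assert len(model.by_tag("active_edge")) == 1
        assert len(model.by_tag("reversible")) == 0
        assert model.objective == {"x:e": 1.0}

    def test_chain_has_one_conservation_row(self, chain):
        model = build_model(FactoryProblem(chain, mode="conservation"))
        rows = model.by_tag("conservation")
        assert len(rows) == 1
        assert rows[0].coefs == {"f:e1": 1.0, "f:e2": -1.0}
        assert rows[0].lb == rows[0].ub == 0.0

    def test_accumulation_rows_are_one_sided(self, chain):
        model = build_model(FactoryProblem(chain, mode="accumulation"))
        (row,) = model.by_tag("accumulation")
        assert row.lb == 0.0 and row.ub == float("inf")

    def test_first_order_constraint_per_producer(self):
        H = build_hypergraph(
            [
                {"id": "e", "tail": {"s": 1}, "head": {"t": 1}, "inhibitors": {"v"}},
                {"id": "d", "tail": {"s": 1}, "head": {"v": 1}},
            ],
            sources={"s"},
            targets={"t", "v"},
        )
        model = build_model(FactoryProblem(H, regulation_order=1))
        (con,) = model.by_tag("neg_reg_1")
        assert con.coefs == {"x:e": 1.0, "x:d": 1.0} and con.ub == 1.0
        # order 0 omits the family entirely
        assert not build_model(FactoryProblem(H)).by_tag("neg_reg_1")

    def test_self_inhibiting_producer_is_banned(self):
        # a reaction producing its own inhibitor collapses to 2 x_e <= 1
        H = build_hypergraph(
            [{"id": "e", "tail": {"s": 1}, "head": {"t": 1}, "inhibitors": {"t"}}],
            sources={"s"},
            targets={"t"},
        )
        model = build_model(FactoryProblem(H, regulation_order=1))
        (con,) = model.by_tag("neg_reg_1")
        assert con.coefs == {"x:e": 2.0}

    def test_min_source_has_active_source_rows(self, chain):
        model = build_model(FactoryProblem(chain, objective="min_source"))
        assert len(model.by_tag("active_source")) == 1  # one out-edge of s
        assert model.objective == {"y:s": 1.0}

    def test_empty_targets_rejected(self):
        H = build_hypergraph(
            [{"id": "e1", "tail": {"a": 1}, "head": {"b": 1}},
             {"id": "e2", "tail": {"b": 1}, "head": {"a": 1}}],
        )
        with pytest.raises(HypergraphError, match="empty"):
            build_model(FactoryProblem(H))

    def test_epsilon_bounds_enforced(self, single_edge):
        with pytest.raises((ValueError, HypergraphError)):
            FactoryProblem(single_edge, epsilon=0)
        with pytest.raises(ValueError):
            FactoryProblem(single_edge, epsilon=2)


class TestSolve:
    def test_single_edge_accumulation(self, single_edge):
        sol = FactoryProblem(
            single_edge, mode="accumulation", epsilon=Fraction(1, 2)
        ).solve()
        assert sol.status == "optimal"
        assert sol.objective_value == 1
        assert 0.5 <= sol.flux["e"] <= 1.0
        assert sol.active_sources == {"s"}

    def test_byproduct_splits_modes(self, fixtures):
        # e1: s -> {a, b}, e2: a -> t.  Conservation at b forces f1 = 0.
        H = fixtures["splitter"]
        assert FactoryProblem(H, mode="conservation").solve().status == "infeasible"
        sol = FactoryProblem(H, mode="accumulation").solve()
        assert sol.objective_value == 2

    def test_reduction_k1_optimum_is_six(self):
        H, ell = reduce_exact_cover(
            ExactCoverInstance(["1", "2", "3"], [["1", "2", "3"]])
        )
        sol = FactoryProblem(H, mode="conservation", epsilon=1).solve()
        assert sol.status == "optimal"
        assert sol.objective_value == ell == 6
        assert sol.active_edges == set(H.edge_ids)

    def test_min_edge_reads_weights(self):
        # the 1-edge route weighs 5; the 2-edge route weighs 2
        H = build_hypergraph(
            [
                {"id": "big", "tail": {"s": 1}, "head": {"t": 1}, "weight": 5},
                {"id": "e1", "tail": {"s": 1}, "head": {"a": 1}},
                {"id": "e2", "tail": {"a": 1}, "head": {"t": 1}},
            ],
            sources={"s"},
            targets={"t"},
        )
        sol = FactoryProblem(H).solve()
        assert sol.active_edges == {"e1", "e2"}
        assert sol.objective_value == 2

    def test_infeasible_reports_empty_sets(self, fixtures):
        sol = FactoryProblem(fixtures["splitter"], mode="conservation").solve()
        assert sol.status == "infeasible"
        assert sol.flux == {} and sol.active_edges == set()

    def test_first_order_forces_longer_factory(self, fixtures):
        H = fixtures["first_order_pair"]
        base = FactoryProblem(H, regulation_order=0).solve()
        reg = FactoryProblem(H, regulation_order=1).solve()
        assert base.objective_value == 2
        assert reg.objective_value == 3
        assert not any(
            H.in_index(v) & reg.active_edges
            for e in reg.active_edges
            for v in H.edge(e).inhibitors
        )

    def test_solve_rejects_order_two(self, single_edge):
        with pytest.raises(ValueError, match="second_order"):
            solve(FactoryProblem(single_edge, regulation_order=2))

    def test_summary_mentions_status_and_objective(self, single_edge):
        sol = FactoryProblem(single_edge, mode="accumulation").solve()
        text = sol.summary()
        assert "optimal" in text and "active edges:     1" in text


class TestActiveSources:
    def test_zero_flux_yields_empty(self, chain):
        assert active_sources_of(chain, {"e1": 0.0, "e2": 0.0}, 1e-7) == set()

    def test_single_active_edge(self, chain):
        assert active_sources_of(chain, {"e1": 0.5, "e2": 0.5}, 1e-7) == {"s"}

    def test_flux_out_of_non_sources_ignored(self, chain):
        assert active_sources_of(chain, {"e1": 0.0, "e2": 0.5}, 1e-7) == set()


class TestSolutionInvariants:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("mode", ["conservation", "accumulation"])
    def test_scaled_flux_remains_valid(self, seed, mode):
        H = random_instance(8, 8, seed)
        sol = FactoryProblem(H, mode=mode).solve()
        if sol.status != "optimal":
            return
        peak = max(sol.flux.values())
        scaled = {e: f / peak for e, f in sol.flux.items()}
        report = validate_factory(
            H, scaled, mode=mode, epsilon=1e-4, active_threshold=1e-7 / peak
        )
        assert report.max_conservation_residual <= 1e-7
        assert {e for e, f in scaled.items() if f > 1e-7 / peak} == sol.active_edges

    @pytest.mark.parametrize("seed", range(6))
    def test_no_reverse_pair_jointly_active(self, seed):
        H = random_instance(8, 8, seed, p_reversible=0.5)
        for mode in ("conservation", "accumulation"):
            sol = FactoryProblem(H, mode=mode).solve()
            for eid in sol.active_edges:
                rev = H.edge(eid).reverse_of
                assert rev is None or rev not in sol.active_edges

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_cross_bounds(self, seed):
        # min-edge is a lower bound on the min-source factory's edge count,
        # and min-source on the min-edge factory's source count
        H = random_instance(8, 8, seed)
        for mode in ("conservation", "accumulation"):
            se = FactoryProblem(H, mode=mode, objective="min_edge").solve()
            ss = FactoryProblem(H, mode=mode, objective="min_source").solve()
            if se.status != "optimal" or ss.status != "optimal":
                assert se.status == ss.status == "infeasible"
                continue
            assert se.n_active_edges <= ss.n_active_edges
            assert ss.n_active_sources <= se.n_active_sources

    @pytest.mark.parametrize("seed", range(6))
    def test_accumulation_never_worse_than_conservation(self, seed):
        H = random_instance(8, 8, seed)
        cons = FactoryProblem(H, mode="conservation").solve()
        if cons.status != "optimal":
            return
        acc = FactoryProblem(H, mode="accumulation").solve()
        assert acc.status == "optimal"
        assert acc.objective_value <= cons.objective_value


class TestBicriteria:
    def test_presets_resolve_to_dominating_weights(self, fixtures):
        H = fixtures["useless_cycle"]
        p = FactoryProblem(H, objective="bicriteria")
        we, ws = p.resolved_bicriteria_weights()
        assert we == len(H.sources) + 1 and ws == 1

    def test_edges_then_sources_matches_min_edge_count(self, fixtures):
        H = fixtures["useless_cycle"]
        me = FactoryProblem(H, objective="min_edge").solve()
        bi = FactoryProblem(
            H, objective="bicriteria", bicriteria_weights="edges_then_sources"
        ).solve()
        assert bi.n_active_edges == me.n_active_edges
        assert bi.n_active_sources <= me.n_active_sources

    def test_sources_then_edges_matches_min_source_count(self, fixtures):
        H = fixtures["useless_cycle"]
        ms = FactoryProblem(H, objective="min_source").solve()
        bi = FactoryProblem(
            H, objective="bicriteria", bicriteria_weights="sources_then_edges"
        ).solve()
        assert bi.n_active_sources == ms.n_active_sources
        assert bi.n_active_edges <= ms.n_active_edges

    def test_zero_weights_rejected(self, single_edge):
        with pytest.raises(ValueError):
            FactoryProblem(
                single_edge, objective="bicriteria", bicriteria_weights=(0, 0)
            )


class TestReversibleTrap:
    def test_exclusivity_constraint_blocks_trivial_cycle(self, fixtures):
        H = fixtures["reversible_trap"]
        sol = FactoryProblem(H).solve()
        assert sol.active_edges == {"d1", "d2", "e"}

    def test_without_constraint_the_cycle_wins(self, fixtures):
        # rebuild the model, drop the reverse-pair rows, re-solve
        from hyperfactory.milp import _extract_solution, _run_scipy

        H = fixtures["reversible_trap"]
        problem = FactoryProblem(H)
        model = build_model(problem)
        model.constraints = [c for c in model.constraints if c.tag != "reversible"]
        res = _run_scipy(model, problem.solver)
        sol = _extract_solution(problem, model, res)
        assert sol.active_edges == {"e", "e__rev"}
        assert sol.objective_value == 2
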