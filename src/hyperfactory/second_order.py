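"""Second-order negative regulation via next-best-factory iteration.

First-order constraints only forbid a factory from producing an inhibitor of
one of its own reactions.  Second-order regulation is stronger: no inhibitor
of an active reaction may be producible from the factory's *active sources*
through any reactions in the network, including reactions outside the
factory.  That condition cannot be written as a linear constraint on the
factory MILP directly, so it is enforced iteratively: solve the first-order
MILP, test each inhibitor of an active edge for producibility with a small
feasibility LP, and if any test fires, cut the current solution off (both
its active-edge set and each offending edge/active-source combination) and
re-solve, generating next-best factories until one passes.

Objective values are non-decreasing across iterations and no active-edge set
can repeat, because each iteration adds a cut excluding the previous set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

from .hypergraph import Hypergraph, stoichiometry_matrix
from .milp import (
    FactoryProblem,
    FactorySolution,
    build_model,
    _extract_solution,
    _run_scipy,
)

__all__ = ["IterationRecord", "producible", "check_second_order", "solve_second_order"]

logger = logging.getLogger(__name__)


@dataclass
class IterationRecord:
    """One round of the next-best-factory loop."""

    index: int
    solution_edges: set[str]
    active_sources: set[str]
    violations: list[tuple[str, str]] = field(default_factory=list)
    constraints_added: int = 0
    objective_value: float = math.nan

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "solution_edges": sorted(self.solution_edges),
            "active_sources": sorted(self.active_sources),
            "violations": [list(v) for v in self.violations],
            "constraints_added": self.constraints_added,
            "objective_value": self.objective_value,
        }


def producible(
    H: Hypergraph,
    active_sources: Iterable[str],
    v: str,
    mode: str = "conservation",
    epsilon: float = 1e-4,
    both_sides_rule: str = "zero",
) -> bool:
    """Can substance ``v`` be produced from ``active_sources`` alone?

    Feasibility LP over flux variables only: conservation (or accumulation)
    rows for the intermediates ``V - (S | {v})``, zero flux on out-edges of
    every non-active source, and production ``sum_{e in in(v)} f_e >= eps``
    in place of the target constraints.  A vertex with no in-edges is never
    producible.
    """
    if v not in H.vertices:
        raise ValueError(f"unknown vertex {v!r}")
    in_v = H.in_index(v)
    if not in_v:
        return False
    active = set(active_sources)
    edge_ids = H.edge_ids
    idx = {eid: j for j, eid in enumerate(edge_ids)}
    n = len(edge_ids)

    upper = np.ones(n)
    for s in H.sources - active:
        for eid in H.out_index(s):
            upper[idx[eid]] = 0.0

    intermediates = H.vertices - H.sources - {v}
    M = stoichiometry_matrix(H, rule=both_sides_rule)
    rows: dict[str, dict[int, float]] = {}
    for (u, eid), r in M.entries.items():
        if u in intermediates:
            rows.setdefault(u, {})[idx[eid]] = float(r)

    A_eq, b_eq, A_ub, b_ub = [], [], [], []
    for u in sorted(rows):
        arr = np.zeros(n)
        for j, r in rows[u].items():
            arr[j] = r
        if mode == "conservation":
            A_eq.append(arr)
            b_eq.append(0.0)
        else:
            A_ub.append(-arr)
            b_ub.append(0.0)
    prod = np.zeros(n)
    for eid in in_v:
        prod[idx[eid]] = -1.0
    A_ub.append(prod)
    b_ub.append(-float(epsilon))

    res = linprog(
        np.zeros(n),
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=list(zip(np.zeros(n), upper)),
        method="highs",
    )
    return res.status == 0


def check_second_order(
    H: Hypergraph,
    solution,
    active_sources: Iterable[str] | None = None,
    mode: str = "conservation",
    epsilon: float = 1e-4,
    both_sides_rule: str = "zero",
    _memo: dict | None = None,
) -> list[tuple[str, str]]:
    """All pairs ``(edge, inhibitor)`` violating second-order regulation.

    ``solution`` may be a :class:`FactorySolution` (active sets taken from
    it) or a plain set of active edge ids with ``active_sources`` given
    separately.  An empty list means the solution is second-order valid.
    """
    if hasattr(solution, "active_edges"):
        active_edges = set(solution.active_edges)
        if active_sources is None:
            active_sources = set(solution.active_sources)
    else:
        active_edges = set(solution)
        if active_sources is None:
            raise ValueError("active_sources required when passing a raw edge set")
    A = frozenset(active_sources)
    violations: list[tuple[str, str]] = []
    for eid in sorted(active_edges):
        for v in sorted(H.edge(eid).inhibitors):
            key = (A, v)
            if _memo is not None and key in _memo:
                hit = _memo[key]
            else:
                hit = producible(H, A, v, mode, epsilon, both_sides_rule)
                if _memo is not None:
                    _memo[key] = hit
            if hit:
                violations.append((eid, v))
    return violations


def solve_second_order(
    problem: FactoryProblem, max_iterations: int = 1000
) -> FactorySolution:
    """Minimum-edge factory under second-order negative regulation.

    Starts from the first-order MILP (with active-source indicators) and
    iterates: solve, test every inhibitor of an active edge for
    producibility from the active sources, and on any hit add two cut
    families — ``sum_{e in F} x_e <= |F| - 1`` over the current active set
    ``F``, and ``x_e + sum_{s in A} y_s <= |A|`` for each offending edge
    against the current active sources ``A`` — then re-solve.

    Returns status ``optimal`` with the accepted factory and the full
    iteration log, ``infeasible`` when the cut-augmented MILP runs out of
    factories (no second-order-valid factory exists), or
    ``iteration_limit`` with the last attempt attached.
    """
    if problem.regulation_order != 2:
        raise ValueError("solve_second_order requires regulation_order == 2")
    if problem.objective != "min_edge":
        raise ValueError(
            "the next-best-factory iteration is defined for the min_edge objective"
        )
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")

    from .validate import validate_factory

    H = problem.hypergraph
    eps = float(problem.epsilon)
    model = build_model(problem, with_source_vars=True)
    memo: dict = {}
    log: list[IterationRecord] = []
    last: FactorySolution | None = None
    seen_cut_pairs: set[tuple[str, frozenset]] = set()

    for i in range(1, max_iterations + 1):
        res = _run_scipy(model, problem.solver)
        sol = _extract_solution(problem, model, res)
        if sol.status != "optimal":
            sol.iterations = log
            return sol
        last = sol
        violations = check_second_order(
            H,
            sol.active_edges,
            sol.active_sources,
            mode=problem.mode,
            epsilon=eps,
            both_sides_rule=problem.both_sides_rule,
            _memo=memo,
        )
        record = IterationRecord(
            index=i,
            solution_edges=set(sol.active_edges),
            active_sources=set(sol.active_sources),
            violations=violations,
            objective_value=sol.objective_value,
        )
        log.append(record)
        if not violations:
            sol.iterations = log
            sol.validity = validate_factory(
                H,
                sol.flux,
                mode=problem.mode,
                epsilon=problem.epsilon,
                regulation_order=2,
                both_sides_rule=problem.both_sides_rule,
                active_threshold=problem.active_threshold,
                active_edges=sol.active_edges,
                active_sources=sol.active_sources,
            )
            logger.info(
                "second-order factory accepted at iteration %d (objective %g)",
                i,
                sol.objective_value,
            )
            return sol

        F = sol.active_edges
        model.add(
            "exclusion_edges",
            {f"x:{eid}": 1.0 for eid in F},
            -np.inf,
            float(len(F) - 1),
        )
        added = 1
        A = frozenset(sol.active_sources)
        for eid, v in violations:
            key = (eid, A)
            if key in seen_cut_pairs:
                continue
            seen_cut_pairs.add(key)
            coefs = {f"x:{eid}": 1.0}
            for s in A:
                coefs[f"y:{s}"] = 1.0
            model.add("exclusion_sources", coefs, -np.inf, float(len(A)))
            added += 1
        record.constraints_added = added
        logger.info(
            "iteration %d: %d violation(s), %d cut(s) added, objective %g",
            i,
            len(violations),
            added,
            sol.objective_value,
        )

    out = FactorySolution(
        status="iteration_limit",
        flux=last.flux if last else {},
        active_edges=set(last.active_edges) if last else set(),
        active_sources=set(last.active_sources) if last else set(),
        objective_value=last.objective_value if last else math.nan,
        iterations=log,
        problem=problem,
    )
    return out
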