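"""Independent validation of factory solutions, and brute-force oracles.

MILP solvers can report "optimal" solutions that are not valid factories —
typically when the minimum-flux constant is pushed below the solver's
numerical tolerances and the returned flux has empty support.  Everything in
this module recomputes quantities from scratch (stoichiometry residuals,
target production, regulation violations) without trusting any solver
artifact, so it can serve both as a guard after every solve and as an
independent test oracle on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .hypergraph import Hypergraph, stoichiometry_matrix

__all__ = [
    "ValidityReport",
    "validate_factory",
    "oracle_min_edge",
    "oracle_producible",
    "reduction_soundness_check",
]

#: conservation residual tolerance (coefficients are O(1) after input parsing)
CONSERVATION_ATOL = 1e-8
#: target-production tolerance
PRODUCTION_ATOL = 1e-9


@dataclass
class ValidityReport:
    is_valid: bool
    max_conservation_residual: float
    min_target_production: float
    support_mismatches: list[str] = field(default_factory=list)
    regulation_violations: list[tuple] = field(default_factory=list)
    epsilon_used: float = 0.0

    def to_dict(self) -> dict:
        return {
            "is_valid": self.is_valid,
            "max_conservation_residual": self.max_conservation_residual,
            "min_target_production": self.min_target_production,
            "support_mismatches": sorted(self.support_mismatches),
            "regulation_violations": [list(v) for v in self.regulation_violations],
            "epsilon_used": self.epsilon_used,
        }


def validate_factory(
    H: Hypergraph,
    flux: Mapping[str, float],
    mode: str = "conservation",
    epsilon: float | Fraction = Fraction(1, 10_000),
    regulation_order: int = 0,
    both_sides_rule: str = "zero",
    conservation_atol: float = CONSERVATION_ATOL,
    production_atol: float = PRODUCTION_ATOL,
    active_threshold: float | None = None,
    active_edges: Iterable[str] | None = None,
    active_sources: Iterable[str] | None = None,
) -> ValidityReport:
    """Check that ``flux`` is a valid factory on ``H``; report, never raise.

    Conservation rows are recomputed from the hypergraph's stoichiometry;
    ``active_edges`` (if given, e.g. the solver's binary indicators) are
    cross-checked against the flux support.  First-order regulation is
    checked combinatorially on the active set; second-order (order 2) runs
    the producibility LP for every inhibitor of an active edge against the
    active sources.
    """
    eps = float(epsilon)
    if active_threshold is None:
        active_threshold = eps * 1e-3

    M = stoichiometry_matrix(H, rule=both_sides_rule)
    intermediates = H.intermediates
    rows: dict[str, float] = {v: 0.0 for v in intermediates}
    for (v, eid), r in M.entries.items():
        if v in intermediates:
            rows[v] += float(r) * flux.get(eid, 0.0)

    max_residual = 0.0
    for v, value in rows.items():
        if mode == "conservation":
            max_residual = max(max_residual, abs(value))
        else:
            max_residual = max(max_residual, max(0.0, -value))

    min_production = np.inf
    for t in H.targets:
        total = sum(flux.get(eid, 0.0) for eid in H.in_index(t))
        min_production = min(min_production, total)
    if not H.targets:
        min_production = 0.0

    support = {eid for eid in H.edge_ids if flux.get(eid, 0.0) > active_threshold}
    mismatches: list[str] = []
    if active_edges is not None:
        mismatches = sorted(set(active_edges) ^ support)

    violations: list[tuple] = []
    if regulation_order >= 1:
        for eid in sorted(support):
            for v in sorted(H.edge(eid).inhibitors):
                if H.in_index(v) & support:
                    violations.append((eid, v, 1))
    if regulation_order >= 2:
        from .second_order import check_second_order

        if active_sources is None:
            from .milp import active_sources_of

            active_sources = active_sources_of(H, flux, active_threshold)
        for eid, v in check_second_order(
            H, support, set(active_sources), mode=mode, epsilon=eps
        ):
            violations.append((eid, v, 2))

    ok = (
        max_residual <= conservation_atol
        and min_production >= eps - production_atol
        and not mismatches
        and not violations
    )
    return ValidityReport(
        is_valid=bool(ok),
        max_conservation_residual=float(max_residual),
        min_target_production=float(min_production),
        support_mismatches=mismatches,
        regulation_violations=violations,
        epsilon_used=eps,
    )


# ---------------------------------------------------------------------------
# LP feasibility primitives (independent of the MILP layer)
# ---------------------------------------------------------------------------


def _mode_rows(H, intermediates, edge_index, both_sides_rule):
    M = stoichiometry_matrix(H, rule=both_sides_rule)
    rows: dict[str, dict[int, float]] = {}
    for (v, eid), r in M.entries.items():
        if v in intermediates and eid in edge_index:
            rows.setdefault(v, {})[edge_index[eid]] = float(r)
    return rows


def _support_lp(
    H: Hypergraph,
    support: Sequence[str],
    mode: str,
    epsilon: float,
    both_sides_rule: str = "zero",
    maximize_edge: str | None = None,
):
    """Feasibility LP over flux restricted to ``support`` (others fixed to 0).

    Returns ``None`` when infeasible, else a feasible flux dict (the
    maximizer of ``maximize_edge``'s flux when given).
    """
    idx = {eid: j for j, eid in enumerate(support)}
    n = len(support)
    rows = _mode_rows(H, H.intermediates, idx, both_sides_rule)

    A_eq, b_eq, A_ub, b_ub = [], [], [], []
    for v in sorted(rows):
        arr = np.zeros(n)
        for j, r in rows[v].items():
            arr[j] = r
        if mode == "conservation":
            A_eq.append(arr)
            b_eq.append(0.0)
        else:
            A_ub.append(-arr)  # -row . f <= 0  <=>  row . f >= 0
            b_ub.append(0.0)
    for t in sorted(H.targets):
        arr = np.zeros(n)
        hit = False
        for eid in H.in_index(t):
            if eid in idx:
                arr[idx[eid]] = -1.0
                hit = True
        if not hit:
            return None  # production of t unsatisfiable on this support
        A_ub.append(arr)
        b_ub.append(-epsilon)

    c = np.zeros(n)
    if maximize_edge is not None:
        c[idx[maximize_edge]] = -1.0
    res = linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[(0.0, 1.0)] * n,
        method="highs",
    )
    if res.status != 0:
        return None
    return {eid: float(res.x[j]) for eid, j in idx.items()}


def oracle_producible(
    H: Hypergraph,
    active_sources: Iterable[str],
    v: str,
    mode: str = "conservation",
    epsilon: float = 1e-4,
    both_sides_rule: str = "zero",
) -> bool:
    """Self-contained producibility LP: can ``v`` be made from ``active_sources``
    with all other sources shut off?  Intermediates are ``V - (S | {v})``."""
    active = set(active_sources)
    edge_ids = H.edge_ids
    idx = {eid: j for j, eid in enumerate(edge_ids)}
    n = len(edge_ids)
    intermediates = H.vertices - H.sources - {v}
    rows = _mode_rows(H, intermediates, idx, both_sides_rule)

    ub = np.ones(n)
    for s in H.sources - active:
        for eid in H.out_index(s):
            ub[idx[eid]] = 0.0

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
    arr = np.zeros(n)
    for eid in H.in_index(v):
        arr[idx[eid]] = -1.0
    if not H.in_index(v):
        return False
    A_ub.append(arr)
    b_ub.append(-float(epsilon))

    res = linprog(
        np.zeros(n),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=list(zip(np.zeros(n), ub)),
        method="highs",
    )
    return res.status == 0


def _first_order_ok(H: Hypergraph, F: frozenset | set) -> bool:
    for eid in F:
        for v in H.edge(eid).inhibitors:
            if H.in_index(v) & F:
                return False
    return True


def _reverse_ok(H: Hypergraph, F) -> bool:
    for eid in F:
        r = H.edge(eid).reverse_of
        if r is not None and r in F:
            return False
    return True


def oracle_min_edge(
    H: Hypergraph,
    mode: str = "conservation",
    epsilon: float | Fraction = Fraction(1, 10_000),
    regulation_order: int = 0,
    max_support: int | None = None,
    both_sides_rule: str = "zero",
):
    """Brute-force minimum-edge factory by support enumeration.

    Enumerates edge subsets ``F`` in increasing size (lexicographic within a
    size), filters combinatorially (every target needs an in-edge in ``F``;
    no reverse pair; first-order conflicts when ``regulation_order >= 1``),
    then decides LP feasibility with flux zero off ``F``.  For order 2 the
    support must be *exact* (every edge of ``F`` can carry positive flux
    simultaneously), the active sources are then determined by ``F``'s tails,
    and every inhibitor of an edge in ``F`` must be non-producible from them.

    Returns ``(size, support)`` for the smallest valid support, or
    ``(None, None)`` when no factory exists within ``max_support``.
    """
    eps = float(epsilon)
    edge_ids = H.edge_ids
    if max_support is None:
        max_support = len(edge_ids)
    if max_support < 1:
        raise ValueError("max_support must be >= 1")
    target_in = [frozenset(H.in_index(t)) for t in sorted(H.targets)]
    if any(not s for s in target_in) or not H.targets:
        return (None, None)

    # stoichiometric prunes, valid for minimal (exact-support) factories:
    # every consumed intermediate needs a producer in the support, and under
    # conservation every produced intermediate needs a consumer
    M = stoichiometry_matrix(H, rule=both_sides_rule)
    I = H.intermediates
    consumes: dict[str, frozenset] = {e: frozenset() for e in edge_ids}
    produces: dict[str, frozenset] = {e: frozenset() for e in edge_ids}
    for (v, eid), r in M.entries.items():
        if v in I:
            if r < 0:
                consumes[eid] |= {v}
            else:
                produces[eid] |= {v}

    for size in range(1, min(max_support, len(edge_ids)) + 1):
        for combo in itertools.combinations(edge_ids, size):
            F = frozenset(combo)
            if any(not (ti & F) for ti in target_in):
                continue
            consumed: set = set()
            produced: set = set()
            for eid in combo:
                consumed |= consumes[eid]
                produced |= produces[eid]
            if not consumed <= produced:
                continue
            if mode == "conservation" and not produced <= consumed:
                continue
            if not _reverse_ok(H, F):
                continue
            if regulation_order >= 1 and not _first_order_ok(H, F):
                continue
            if regulation_order < 2:
                if _support_lp(H, combo, mode, eps, both_sides_rule) is not None:
                    return (size, set(F))
                continue
            # order 2: require exact support, then check producibility
            if _support_lp(H, combo, mode, eps, both_sides_rule) is None:
                continue
            exact = True
            for eid in combo:
                sol = _support_lp(
                    H, combo, mode, eps, both_sides_rule, maximize_edge=eid
                )
                if sol is None or sol[eid] <= eps * 1e-3:
                    exact = False
                    break
            if not exact:
                continue
            A = {s for s in H.sources if H.out_index(s) & F}
            bad = False
            for eid in sorted(F):
                for v in sorted(H.edge(eid).inhibitors):
                    if oracle_producible(H, A, v, mode, eps, both_sides_rule):
                        bad = True
                        break
                if bad:
                    break
            if not bad:
                return (size, set(F))
    return (None, None)


def _exact_cover_exists(X: Sequence, Y: Sequence[Iterable]) -> bool:
    """Brute-force Exact Cover by 3-sets decision."""
    ground = set(X)
    k, rem = divmod(len(ground), 3)
    if rem:
        raise ValueError("ground set size must be a multiple of 3")
    sets = [frozenset(y) for y in Y]
    if any(len(s) != 3 or not s <= ground for s in sets):
        raise ValueError("family members must be 3-subsets of the ground set")
    for combo in itertools.combinations(sets, k):
        union = frozenset().union(*combo) if combo else frozenset()
        if len(union) == 3 * k and union == ground:
            return True
    return k == 0


def reduction_soundness_check(X: Sequence, Y: Sequence[Iterable]) -> bool:
    """Does the hardness reduction preserve the decision?

    Compares the brute-force Exact Cover answer with whether the reduced
    hypergraph instance (conservation, eps = 1) admits a factory with at
    most ``7k - 1`` active edges, as decided by :func:`oracle_min_edge`.
    """
    from .synthetic import reduce_exact_cover, ExactCoverInstance

    inst = ExactCoverInstance(ground_set=list(X), family=[list(y) for y in Y])
    H, ell = reduce_exact_cover(inst)
    cover = _exact_cover_exists(X, Y)
    size, _ = oracle_min_edge(H, mode="conservation", epsilon=1.0, max_support=ell)
    factory = size is not None and size <= ell
    return cover == factory
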