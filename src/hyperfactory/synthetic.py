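"""Synthetic instances: the hardness-reduction gadget and random networks.

The reduction gadget encodes Exact Cover by 3-sets as a minimum-hyperedge
factory instance under conservation: a single source feeds one edge per
candidate 3-set (ratios -1/+3), each 3-set vertex feeds its three element
vertices (ratios -1/+1), and a daisy chain of two-tail hyperedges funnels
all element vertices into the single target.  The instance admits a factory
with at most ``7k - 1`` active edges (ground set size ``3k``, minimum-flux
constant 1) exactly when an exact cover exists, which makes the gadget both
a correctness fixture and a stress generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .hypergraph import (
    Hypergraph,
    add_reverse_edges,
    build_hypergraph,
    detect_sources_targets,
)

__all__ = [
    "ExactCoverInstance",
    "reduce_exact_cover",
    "random_instance",
    "forcing_fixtures",
]


@dataclass
class ExactCoverInstance:
    """Ground set of ``3k`` elements and a family of 3-element subsets."""

    ground_set: list
    family: list[list]

    def __post_init__(self):
        if len(self.ground_set) % 3 != 0 or not self.ground_set:
            raise ValueError("ground set size must be a positive multiple of 3")
        if len(set(self.ground_set)) != len(self.ground_set):
            raise ValueError("ground set elements must be distinct")
        ground = set(self.ground_set)
        for y in self.family:
            if len(set(y)) != 3 or not set(y) <= ground:
                raise ValueError(f"family member {y!r} is not a 3-subset of the ground set")

    @property
    def k(self) -> int:
        return len(self.ground_set) // 3


def reduce_exact_cover(
    inst: ExactCoverInstance, epsilon: Fraction = Fraction(1)
) -> tuple[Hypergraph, int]:
    """Build the factory instance encoding ``inst``; returns ``(H, 7k - 1)``.

    Solve it under conservation with minimum-flux constant 1 (``epsilon`` is
    part of the reduction and defaults to 1): an exact cover exists iff a
    factory with at most ``7k - 1`` active edges does.  Duplicate family
    subsets are kept (they become parallel gadget branches).
    """
    X = list(inst.ground_set)
    n = len(X)
    k = inst.k
    w = {x: f"w_{x}" for x in X}
    specs = []
    for j, Y in enumerate(inst.family):
        vy = f"vY{j}"
        specs.append({"id": f"top{j}", "tail": {"s": 1}, "head": {vy: 3}})
        for x in sorted(Y, key=X.index):
            specs.append(
                {"id": f"mid{j}_{x}", "tail": {vy: 1}, "head": {w[x]: 1}}
            )
    # daisy chain funnelling all w_x into the target
    for i in range(1, n):
        if i == 1:
            tail = {w[X[0]]: 1, w[X[1]]: 1}
        else:
            tail = {f"u{i - 1}": 1, w[X[i]]: 1}
        head = {f"u{i}": 1} if i < n - 1 else {"t": 1}
        specs.append({"id": f"chain{i}", "tail": tail, "head": head})
    H = build_hypergraph(specs, sources=set(), targets=set())
    H.add_vertex("s")  # an empty family leaves the source unreferenced
    H.set_sources({"s"})
    H.set_targets({"t"})
    return H, 7 * k - 1


def random_instance(
    n_vertices: int,
    n_edges: int,
    seed: int | np.random.Generator,
    max_tail: int = 3,
    max_head: int = 3,
    coef_range: tuple[int, int] = (1, 3),
    p_reversible: float = 0.0,
    p_inhibitor: float = 0.0,
    p_both_sides: float = 0.0,
    avoid_self_loops: bool = True,
    max_resample: int = 200,
) -> Hypergraph:
    """Random metabolic-like hypergraph, reproducible for a fixed seed.

    Tail/head sizes are uniform on ``[1, max_tail]`` / ``[1, max_head]``
    with disjoint vertex draws (unless ``p_both_sides`` puts a catalyst-like
    vertex on both sides); integer coefficients are uniform on
    ``coef_range``; each edge independently gains an inhibitor drawn from
    its non-tail vertices with probability ``p_inhibitor`` and a reverse
    partner with probability ``p_reversible``.  Sources and targets are
    auto-detected after reverse edges are added; instances without at least
    one pure source and one pure target are resampled.
    """
    if n_vertices < 2 or n_edges < 1:
        raise ValueError("need at least 2 vertices and 1 edge")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vertices = [f"v{i}" for i in range(n_vertices)]
    lo, hi = coef_range

    for _ in range(max_resample):
        specs = []
        reversible = []
        for j in range(n_edges):
            t_size = int(rng.integers(1, max_tail + 1))
            h_size = int(rng.integers(1, max_head + 1))
            if avoid_self_loops and t_size + h_size > n_vertices:
                t_size = max(1, min(t_size, n_vertices - 1))
                h_size = max(1, min(h_size, n_vertices - t_size))
            pool = rng.permutation(n_vertices)
            tail_ids = pool[:t_size]
            if avoid_self_loops:
                head_ids = pool[t_size : t_size + h_size]
            else:
                head_ids = rng.choice(n_vertices, size=h_size, replace=False)
            tail = {vertices[i]: int(rng.integers(lo, hi + 1)) for i in tail_ids}
            head = {vertices[i]: int(rng.integers(lo, hi + 1)) for i in head_ids}
            if p_both_sides > 0 and rng.random() < p_both_sides:
                v = vertices[int(tail_ids[0])]
                head.setdefault(v, tail[v])
            inhibitors = set()
            if p_inhibitor > 0 and rng.random() < p_inhibitor:
                candidates = [v for v in vertices if v not in tail]
                if candidates:
                    inhibitors.add(candidates[int(rng.integers(len(candidates)))])
            specs.append(
                {"id": f"e{j}", "tail": tail, "head": head, "inhibitors": inhibitors}
            )
            if p_reversible > 0 and rng.random() < p_reversible:
                reversible.append(f"e{j}")
        H = build_hypergraph(specs, sources=set(), targets=set())
        if reversible:
            add_reverse_edges(H, reversible)
        auto_s, auto_t = detect_sources_targets(H)
        srcs = auto_s - auto_t
        tgts = auto_t - auto_s
        if srcs and tgts:
            H.set_sources(srcs)
            H.set_targets(tgts)
            return H
    raise ValueError(
        "could not sample an instance with a pure source and target; "
        "relax the parameters"
    )


def forcing_fixtures() -> dict[str, Hypergraph]:
    """Hand-built instances that pin down one model behaviour each.

    - ``splitter``: a byproduct makes conservation infeasible while
      accumulation succeeds.
    - ``first_order_pair``: the cheap route produces an inhibitor of itself
      (via a second required target), forcing a longer first-order factory.
    - ``second_order_triple``: the cheap route's inhibitor is producible
      from the active source by a reaction outside the factory, forcing the
      iterative solver onto a different source.
    - ``useless_cycle``: the unique min-source factory (one source) needs
      strictly more reactions than the min-edge factory (two sources); a
      free-floating flux cycle is present for the solver to ignore.
    - ``reversible_trap``: without the reverse-pair exclusivity constraint a
      reversible reaction fakes production through a two-cycle.
    - ``epsilon_gate``: stoichiometry caps the target flux at 1e-3, so the
      instance is infeasible for eps = 1e-2 but optimal for eps = 1e-4.
    """
    fixtures: dict[str, Hypergraph] = {}

    fixtures["splitter"] = build_hypergraph(
        [
            {"id": "e1", "tail": {"s": 1}, "head": {"a": 1, "b": 1}},
            {"id": "e2", "tail": {"a": 1}, "head": {"t": 1}},
        ],
        sources={"s"},
        targets={"t"},
    )

    fixtures["first_order_pair"] = build_hypergraph(
        [
            {"id": "e1", "tail": {"s": 1}, "head": {"t": 1}, "inhibitors": {"v"}},
            {"id": "d", "tail": {"s": 1}, "head": {"v": 1}},
            {"id": "e2", "tail": {"s": 1}, "head": {"a": 1}},
            {"id": "e3", "tail": {"a": 1}, "head": {"t": 1}},
        ],
        sources={"s"},
        targets={"t", "v"},
    )

    fixtures["second_order_triple"] = build_hypergraph(
        [
            {"id": "e1", "tail": {"s": 1}, "head": {"t": 1}, "inhibitors": {"v"}},
            {"id": "d", "tail": {"s": 1}, "head": {"v": 1}},
            {"id": "e2", "tail": {"s2": 1}, "head": {"t": 1}},
        ],
        sources={"s", "s2"},
        targets={"t"},
    )

    fixtures["useless_cycle"] = build_hypergraph(
        [
            {"id": "e1", "tail": {"s": 1}, "head": {"a": 1}},
            {"id": "e2", "tail": {"a": 1}, "head": {"t1": 1}},
            {"id": "e3", "tail": {"a": 1}, "head": {"t2": 1}},
            {"id": "d1", "tail": {"s1": 1}, "head": {"t1": 1}},
            {"id": "d2", "tail": {"s2": 1}, "head": {"t2": 1}},
            {"id": "cyc1", "tail": {"b": 1}, "head": {"c": 1}},
            {"id": "cyc2", "tail": {"c": 1}, "head": {"b": 1}},
        ],
        sources={"s", "s1", "s2"},
        targets={"t1", "t2"},
    )

    trap = build_hypergraph(
        [
            {"id": "d1", "tail": {"s": 1}, "head": {"c": 1}},
            {"id": "d2", "tail": {"c": 1}, "head": {"a": 1}},
            {"id": "e", "tail": {"a": 1}, "head": {"t": 1}},
        ],
        sources={"s"},
        targets={"t"},
    )
    add_reverse_edges(trap, {"e"})
    fixtures["reversible_trap"] = trap

    fixtures["epsilon_gate"] = build_hypergraph(
        [
            {"id": "e1", "tail": {"s": 1}, "head": {"a": Fraction(1, 1000)}},
            {"id": "e2", "tail": {"a": 1}, "head": {"t": 1}},
        ],
        sources={"s"},
        targets={"t"},
    )

    return fixtures
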