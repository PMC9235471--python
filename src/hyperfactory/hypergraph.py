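"""Directed-hypergraph data model for metabolic networks.

A metabolic network is represented as a directed hypergraph ``G = (V, E)``:
vertices are substances (metabolites, proteins, complexes) and each hyperedge
is a reaction directed from its set of input reactants (the *tail*) to its set
of output products (the *head*), with a strictly positive stoichiometric ratio
per participating vertex.  Reactions may carry negative regulators (inhibitor
vertices) and positive regulators (enzymes); reversible reactions are modelled
as a pair of mutually linked hyperedges with tail and head swapped.

Coefficients are stored as exact :class:`fractions.Fraction` values and only
converted to floating point when a solver model is assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

__all__ = [
    "HypergraphError",
    "Hyperedge",
    "Hypergraph",
    "StoichiometryMatrix",
    "build_hypergraph",
    "detect_sources_targets",
    "add_reverse_edges",
    "stoichiometry_matrix",
    "as_coefficient",
]


class HypergraphError(ValueError):
    """Raised for structurally invalid hypergraphs or edge descriptions."""


def as_coefficient(value) -> Fraction:
    """Coerce ``value`` to an exact positive :class:`Fraction`.

    Accepts ints, Fractions, decimal or ``p/q`` strings, and floats (floats go
    through their shortest decimal representation, so ``0.1`` becomes 1/10).
    """
    if isinstance(value, Fraction):
        coef = value
    elif isinstance(value, int):
        coef = Fraction(value)
    elif isinstance(value, float):
        coef = Fraction(str(value))
    elif isinstance(value, str):
        coef = Fraction(value)
    else:
        raise HypergraphError(f"cannot interpret coefficient {value!r}")
    if coef <= 0:
        raise HypergraphError(f"coefficient must be positive, got {coef}")
    return coef


def _coef_map(m: Mapping[str, object] | Iterable[str]) -> dict[str, Fraction]:
    # bare iterables of vertex ids get unit coefficients
    if isinstance(m, Mapping):
        return {str(v): as_coefficient(c) for v, c in m.items()}
    return {str(v): Fraction(1) for v in m}


@dataclass
class Hyperedge:
    """A reaction: ``tail`` consumed, ``head`` produced, per-vertex ratios."""

    id: str
    tail: dict[str, Fraction]
    head: dict[str, Fraction]
    inhibitors: set[str] = field(default_factory=set)
    positive_regulators: set[str] = field(default_factory=set)
    reverse_of: str | None = None
    weight: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        self.tail = _coef_map(self.tail)
        self.head = _coef_map(self.head)
        self.inhibitors = set(self.inhibitors)
        self.positive_regulators = set(self.positive_regulators)
        self.weight = as_coefficient(self.weight)
        if not self.tail:
            raise HypergraphError(f"edge {self.id!r}: empty tail")
        if not self.head:
            raise HypergraphError(f"edge {self.id!r}: empty head")

    @property
    def vertices(self) -> set[str]:
        return set(self.tail) | set(self.head) | self.inhibitors


class Hypergraph:
    """Vertices, ordered hyperedges, candidate sources S and targets T.

    Incidence indexes ``in_index(v) = {e : v in head(e)}`` and
    ``out_index(v) = {e : v in tail(e)}`` are maintained on every mutation;
    intermediates ``I = V - (S | T)`` are always derived, never stored.
    """

    def __init__(self) -> None:
        self.vertices: set[str] = set()
        self._edges: dict[str, Hyperedge] = {}
        self.sources: set[str] = set()
        self.targets: set[str] = set()
        self._in: dict[str, set[str]] = {}
        self._out: dict[str, set[str]] = {}

    # -- access ----------------------------------------------------------
    @property
    def edges(self) -> list[Hyperedge]:
        return list(self._edges.values())

    @property
    def edge_ids(self) -> list[str]:
        return list(self._edges)

    def edge(self, edge_id: str) -> Hyperedge:
        try:
            return self._edges[edge_id]
        except KeyError:
            raise HypergraphError(f"unknown edge {edge_id!r}") from None

    def has_edge(self, edge_id: str) -> bool:
        return edge_id in self._edges

    def in_index(self, v: str) -> set[str]:
        return set(self._in.get(v, set()))

    def out_index(self, v: str) -> set[str]:
        return set(self._out.get(v, set()))

    @property
    def intermediates(self) -> set[str]:
        return self.vertices - self.sources - self.targets

    def __len__(self) -> int:
        return len(self._edges)

    # -- mutation --------------------------------------------------------
    def add_vertex(self, v: str) -> None:
        self.vertices.add(v)

    def add_edge(self, edge: Hyperedge) -> None:
        if edge.id in self._edges:
            raise HypergraphError(f"duplicate edge id {edge.id!r}")
        self._edges[edge.id] = edge
        self.vertices |= edge.vertices
        for v in edge.head:
            self._in.setdefault(v, set()).add(edge.id)
        for v in edge.tail:
            self._out.setdefault(v, set()).add(edge.id)

    def set_sources(self, sources: Iterable[str]) -> None:
        sources = set(sources)
        unknown = sources - self.vertices
        if unknown:
            raise HypergraphError(f"unknown vertices in sources: {sorted(unknown)}")
        if sources & self.targets:
            raise HypergraphError(
                f"sources and targets overlap: {sorted(sources & self.targets)}"
            )
        self.sources = sources

    def set_targets(self, targets: Iterable[str]) -> None:
        targets = set(targets)
        unknown = targets - self.vertices
        if unknown:
            raise HypergraphError(f"unknown vertices in targets: {sorted(unknown)}")
        if targets & self.sources:
            raise HypergraphError(
                f"sources and targets overlap: {sorted(targets & self.sources)}"
            )
        self.targets = targets

    def copy(self) -> "Hypergraph":
        other = Hypergraph()
        other.vertices = set(self.vertices)
        for e in self.edges:
            other.add_edge(
                Hyperedge(
                    id=e.id,
                    tail=dict(e.tail),
                    head=dict(e.head),
                    inhibitors=set(e.inhibitors),
                    positive_regulators=set(e.positive_regulators),
                    reverse_of=e.reverse_of,
                    weight=e.weight,
                )
            )
        other.sources = set(self.sources)
        other.targets = set(self.targets)
        return other

    def validate(self) -> None:
        """Check structural invariants; raise :class:`HypergraphError` on failure."""
        for e in self.edges:
            missing = e.vertices - self.vertices
            if missing:
                raise HypergraphError(f"edge {e.id!r} references unknown {missing}")
            if e.reverse_of is not None:
                d = self.edge(e.reverse_of)
                if d.reverse_of != e.id or d.tail != e.head or d.head != e.tail:
                    raise HypergraphError(
                        f"edges {e.id!r}/{d.id!r}: inconsistent reverse pairing"
                    )


def build_hypergraph(
    edge_specs: Iterable[Mapping | Hyperedge],
    sources: Iterable[str] | None = None,
    targets: Iterable[str] | None = None,
    merge_positive_regulators: bool = True,
) -> Hypergraph:
    """Assemble a :class:`Hypergraph` from edge descriptions.

    Each spec is a mapping with keys ``id``, ``tail``, ``head`` and optional
    ``inhibitors``, ``positive_regulators``, ``weight`` (or an already-built
    :class:`Hyperedge`).  Positive regulators are merged into both the tail
    and the head of their reaction with coefficient 1: they are then required
    reactants but impose no net stoichiometric drain under the default
    both-sides rule.  When ``sources``/``targets`` are omitted they are
    auto-detected from vertex degrees (:func:`detect_sources_targets`).
    """
    H = Hypergraph()
    for spec in edge_specs:
        if isinstance(spec, Hyperedge):
            edge = spec
        else:
            edge = Hyperedge(
                id=str(spec["id"]),
                tail=spec["tail"],
                head=spec["head"],
                inhibitors=set(spec.get("inhibitors", ())),
                positive_regulators=set(spec.get("positive_regulators", ())),
                reverse_of=spec.get("reverse_of"),
                weight=spec.get("weight", Fraction(1)),
            )
        if merge_positive_regulators:
            for p in edge.positive_regulators:
                edge.tail.setdefault(p, Fraction(1))
                edge.head.setdefault(p, Fraction(1))
        H.add_edge(edge)

    auto_s, auto_t = detect_sources_targets(H)
    # isolated vertices appear in both auto sets; assign them to neither
    H.set_sources(set(sources) if sources is not None else auto_s - auto_t)
    H.set_targets(set(targets) if targets is not None else auto_t - auto_s)
    H.validate()
    return H


def detect_sources_targets(H: Hypergraph) -> tuple[set[str], set[str]]:
    """Vertices with no in-edges are sources; no out-edges, targets.

    An isolated vertex lands in both returned sets; the caller decides.  The
    hypergraph is not mutated.
    """
    srcs = {v for v in H.vertices if not H.in_index(v)}
    tgts = {v for v in H.vertices if not H.out_index(v)}
    return srcs, tgts


def add_reverse_edges(H: Hypergraph, reversible_ids: Iterable[str]) -> Hypergraph:
    """Append the reverse direction of each listed reaction, in place.

    The reverse edge swaps tail and head (equal coefficients), keeps the
    inhibitors and weight, and both edges are linked through ``reverse_of``.
    """
    for eid in reversible_ids:
        e = H.edge(eid)
        if e.reverse_of is not None:
            raise HypergraphError(f"edge {eid!r} already has a reverse partner")
        rid = f"{eid}__rev"
        if H.has_edge(rid):
            raise HypergraphError(f"reverse id {rid!r} already taken")
        rev = Hyperedge(
            id=rid,
            tail=dict(e.head),
            head=dict(e.tail),
            inhibitors=set(e.inhibitors),
            positive_regulators=set(e.positive_regulators),
            reverse_of=eid,
            weight=e.weight,
        )
        e.reverse_of = rid
        H.add_edge(rev)
    return H


@dataclass
class StoichiometryMatrix:
    """Sparse signed stoichiometry ``r_{v,e}``: negative consumed, positive produced.

    A vertex appearing on both sides of a reaction gets ratio 0 under rule
    ``"zero"`` (the default) or the head-minus-tail difference under rule
    ``"net_difference"``.  Absent entries are 0.
    """

    entries: dict[tuple[str, str], Fraction]
    vertex_order: list[str]
    edge_order: list[str]
    both_sides_rule: str = "zero"

    def ratio(self, v: str, e: str) -> Fraction:
        return self.entries.get((v, e), Fraction(0))

    def row(self, v: str) -> dict[str, Fraction]:
        return {e: r for (u, e), r in self.entries.items() if u == v}

    def to_dense(self):
        """Dense float matrix with rows in ``vertex_order``, columns ``edge_order``."""
        import numpy as np

        M = np.zeros((len(self.vertex_order), len(self.edge_order)))
        vi = {v: i for i, v in enumerate(self.vertex_order)}
        ej = {e: j for j, e in enumerate(self.edge_order)}
        for (v, e), r in self.entries.items():
            M[vi[v], ej[e]] = float(r)
        return M


def stoichiometry_matrix(H: Hypergraph, rule: str = "zero") -> StoichiometryMatrix:
    """Build the signed stoichiometry matrix of ``H`` under the given both-sides rule."""
    if rule not in ("zero", "net_difference"):
        raise HypergraphError(f"unknown both-sides rule {rule!r}")
    entries: dict[tuple[str, str], Fraction] = {}
    for e in H.edges:
        both = set(e.tail) & set(e.head)
        for v, c in e.tail.items():
            if v not in both:
                entries[(v, e.id)] = -c
        for v, c in e.head.items():
            if v not in both:
                entries[(v, e.id)] = c
        for v in both:
            if rule == "net_difference":
                net = e.head[v] - e.tail[v]
                if net != 0:
                    entries[(v, e.id)] = net
            # rule "zero": omit — absent entries are 0
    return StoichiometryMatrix(
        entries=entries,
        vertex_order=sorted(H.vertices),
        edge_order=H.edge_ids,
        both_sides_rule=rule,
    )
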