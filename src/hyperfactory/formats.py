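"""Readers and writers: the hypergraph text format, SBML import, solution files.

The text format is line-oriented, tab-separated, UTF-8 with ``#`` comments::

    EDGE <id> <tail> <head> [w=<weight>]
    REVERSIBLE <edge-id>
    INHIBIT <edge-id> <vertex>[,<vertex>...]
    ENHANCE <edge-id> <vertex>[,...]
    SOURCES <vertex>[,...]
    TARGETS <vertex>[,...]

where ``<tail>``/``<head>`` are comma-separated ``vertex[:coef]`` terms and
coefficients are decimals or ``p/q`` rationals (default 1).  ``SOURCES`` /
``TARGETS`` lines override degree-based auto-detection; a ``REVERSIBLE``
line expands the named reaction into a mutually-linked edge pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import IO, Iterable

from .hypergraph import (
    Hyperedge,
    Hypergraph,
    HypergraphError,
    add_reverse_edges,
    as_coefficient,
    build_hypergraph,
    detect_sources_targets,
)

__all__ = [
    "FormatError",
    "HypergraphDocument",
    "read_hypergraph",
    "write_hypergraph",
    "import_sbml",
    "write_solution",
    "read_solution",
]

logger = logging.getLogger(__name__)

RECORD_KINDS = ("EDGE", "REVERSIBLE", "INHIBIT", "ENHANCE", "SOURCES", "TARGETS")


class FormatError(ValueError):
    """Syntax or reference error in a hypergraph document, with line number."""


@dataclass
class HypergraphDocument:
    """Parsed, order-preserving view of a text-format document."""

    format_version: str = "1"
    records: list[tuple[int, str, list[str]]] = field(default_factory=list)
    # each record: (line number, kind, fields after the kind)


def _open(path_or_stream, mode: str):
    if hasattr(path_or_stream, "read") or hasattr(path_or_stream, "write"):
        return path_or_stream, False
    return open(path_or_stream, mode, encoding="utf-8", newline="\n"), True


def _parse_terms(text: str, lineno: int) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for term in text.split(","):
        term = term.strip()
        if not term:
            raise FormatError(f"line {lineno}: empty vertex term")
        if ":" in term:
            v, _, c = term.rpartition(":")
            try:
                coef = as_coefficient(c)
            except (HypergraphError, ValueError, ZeroDivisionError) as exc:
                raise FormatError(f"line {lineno}: bad coefficient {c!r}: {exc}") from None
        else:
            v, coef = term, Fraction(1)
        if not v:
            raise FormatError(f"line {lineno}: missing vertex id in {term!r}")
        if v in out:
            raise FormatError(f"line {lineno}: repeated vertex {v!r}")
        out[v] = coef
    return out


def parse_document(stream: IO[str]) -> HypergraphDocument:
    doc = HypergraphDocument()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].rstrip("\n").rstrip()
        if not line:
            continue
        fields = line.split("\t")
        kind = fields[0]
        if kind not in RECORD_KINDS:
            raise FormatError(f"line {lineno}: unknown record kind {kind!r}")
        doc.records.append((lineno, kind, fields[1:]))
    return doc


def document_to_hypergraph(doc: HypergraphDocument) -> Hypergraph:
    specs: list[dict] = []
    by_id: dict[str, dict] = {}
    reversible: list[str] = []
    sources: set[str] | None = None
    targets: set[str] | None = None
    deferred: list[tuple[int, str, list[str]]] = []

    for lineno, kind, fields in doc.records:
        if kind == "EDGE":
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: EDGE needs <id> <tail> <head>, got {len(fields)} fields"
                )
            eid, tail_s, head_s = fields[0], fields[1], fields[2]
            weight = Fraction(1)
            for extra in fields[3:]:
                if extra.startswith("w="):
                    try:
                        weight = as_coefficient(extra[2:])
                    except (HypergraphError, ValueError) as exc:
                        raise FormatError(f"line {lineno}: bad weight: {exc}") from None
                else:
                    raise FormatError(f"line {lineno}: unknown field {extra!r}")
            if eid in by_id:
                raise FormatError(f"line {lineno}: duplicate edge id {eid!r}")
            spec = {
                "id": eid,
                "tail": _parse_terms(tail_s, lineno),
                "head": _parse_terms(head_s, lineno),
                "inhibitors": set(),
                "positive_regulators": set(),
                "weight": weight,
            }
            specs.append(spec)
            by_id[eid] = spec
        else:
            deferred.append((lineno, kind, fields))

    known_vertices: set[str] = set()
    for spec in specs:
        known_vertices |= set(spec["tail"]) | set(spec["head"])

    for lineno, kind, fields in deferred:
        if kind == "REVERSIBLE":
            if len(fields) != 1:
                raise FormatError(f"line {lineno}: REVERSIBLE takes one edge id")
            if fields[0] not in by_id:
                raise FormatError(f"line {lineno}: unknown edge {fields[0]!r}")
            reversible.append(fields[0])
        elif kind in ("INHIBIT", "ENHANCE"):
            if len(fields) != 2:
                raise FormatError(f"line {lineno}: {kind} takes <edge-id> <vertices>")
            eid, verts = fields
            if eid not in by_id:
                raise FormatError(f"line {lineno}: unknown edge {eid!r}")
            names = [v.strip() for v in verts.split(",") if v.strip()]
            if not names:
                raise FormatError(f"line {lineno}: {kind} lists no vertices")
            if kind == "INHIBIT":
                unknown = set(names) - known_vertices
                if unknown:
                    raise FormatError(
                        f"line {lineno}: unknown vertices in INHIBIT: {sorted(unknown)}"
                    )
                by_id[eid]["inhibitors"].update(names)
            else:
                by_id[eid]["positive_regulators"].update(names)
        elif kind in ("SOURCES", "TARGETS"):
            if len(fields) != 1:
                raise FormatError(f"line {lineno}: {kind} takes one vertex list")
            names = {v.strip() for v in fields[0].split(",") if v.strip()}
            # ENHANCE vertices become tail/head members, so re-derive later;
            # for now only check against everything mentioned anywhere
            mentioned = known_vertices | {
                p for s in specs for p in s["positive_regulators"]
            }
            unknown = names - mentioned
            if unknown:
                raise FormatError(
                    f"line {lineno}: unknown vertices in {kind}: {sorted(unknown)}"
                )
            if kind == "SOURCES":
                sources = names
            else:
                targets = names

    if not specs:
        raise FormatError("document declares no edges")

    H = build_hypergraph(specs, sources=set(), targets=set())
    if reversible:
        add_reverse_edges(H, reversible)
    auto_s, auto_t = detect_sources_targets(H)
    try:
        H.set_sources(sources if sources is not None else auto_s - auto_t)
        H.set_targets(targets if targets is not None else auto_t - auto_s - H.sources)
    except HypergraphError as exc:
        raise FormatError(str(exc)) from None
    return H


def read_hypergraph(path_or_stream) -> Hypergraph:
    """Parse the text format into a :class:`Hypergraph`.

    ``SOURCES``/``TARGETS`` lines override auto-detection; absent lines fall
    back to degree-based detection after reversible expansion.
    """
    stream, close = _open(path_or_stream, "r")
    try:
        return document_to_hypergraph(parse_document(stream))
    finally:
        if close:
            stream.close()


def _fmt_coef(c: Fraction) -> str:
    return str(c.numerator) if c.denominator == 1 else f"{c.numerator}/{c.denominator}"


def _fmt_terms(coefs: dict[str, Fraction], drop: set[str]) -> str:
    terms = []
    for v in sorted(set(coefs) - drop):
        c = coefs[v]
        terms.append(v if c == 1 else f"{v}:{_fmt_coef(c)}")
    return ",".join(terms)


def write_hypergraph(H: Hypergraph, path_or_stream) -> None:
    """Emit canonical text form; reading it back reproduces ``H``.

    Reverse pairs are serialized as one ``EDGE`` plus a ``REVERSIBLE``
    marker; merged positive regulators (coefficient 1 on both sides) are
    re-extracted into ``ENHANCE`` lines; vertex terms within a side are
    sorted lexicographically.
    """
    stream, close = _open(path_or_stream, "w")
    edge_pos = {e.id: i for i, e in enumerate(H.edges)}
    try:
        reversible: list[str] = []
        kept: list[Hyperedge] = []
        for e in H.edges:
            if e.reverse_of is not None and edge_pos[e.reverse_of] < edge_pos[e.id]:
                continue  # the partner line plus REVERSIBLE covers this edge
            kept.append(e)
            if e.reverse_of is not None:
                reversible.append(e.id)
        for e in kept:
            merged = {
                p
                for p in e.positive_regulators
                if e.tail.get(p) == 1 and e.head.get(p) == 1
            }
            fields = [
                "EDGE",
                e.id,
                _fmt_terms(e.tail, merged),
                _fmt_terms(e.head, merged),
            ]
            if e.weight != 1:
                fields.append(f"w={_fmt_coef(e.weight)}")
            stream.write("\t".join(fields) + "\n")
        for eid in reversible:
            stream.write(f"REVERSIBLE\t{eid}\n")
        for e in kept:
            if e.inhibitors:
                stream.write(f"INHIBIT\t{e.id}\t{','.join(sorted(e.inhibitors))}\n")
            merged = {
                p
                for p in e.positive_regulators
                if e.tail.get(p) == 1 and e.head.get(p) == 1
            }
            if merged:
                stream.write(f"ENHANCE\t{e.id}\t{','.join(sorted(merged))}\n")
        if H.sources:
            stream.write(f"SOURCES\t{','.join(sorted(H.sources))}\n")
        if H.targets:
            stream.write(f"TARGETS\t{','.join(sorted(H.targets))}\n")
    finally:
        if close:
            stream.close()


def import_sbml(path) -> Hypergraph:
    """Import species/reactions/stoichiometry/reversibility from SBML.

    Species become vertices and each reaction a hyperedge (reactant side as
    tail, product side as head); missing stoichiometries default to 1;
    reversible reactions are expanded into edge pairs; sources and targets
    are auto-detected.  Reactions with an empty reactant or product list are
    skipped with a logged warning (count on the returned hypergraph as
    ``sbml_skipped_reactions``).  Core SBML has no negative-regulation
    encoding, so no inhibitors are imported.

    The parser walks the XML directly (namespace-agnostic on local names),
    reading only the level-2/3 core subset this package needs — ``species``,
    ``reaction``, ``speciesReference`` stoichiometry and the ``reversible``
    flag — without touching flux-bound or FBC annotations.
    """
    from lxml import etree

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"unparseable SBML file {path}: {exc}") from None
    root = tree.getroot()
    if local(root.tag) != "sbml":
        raise FormatError(f"{path} is not an SBML document (root {root.tag!r})")

    species_ids = [
        el.get("id")
        for el in root.iter()
        if local(el.tag) == "species" and el.get("id")
    ]

    def side_of(rxn_el, list_name: str) -> dict[str, Fraction]:
        out: dict[str, Fraction] = {}
        for child in rxn_el:
            if local(child.tag) != list_name:
                continue
            for ref in child:
                if local(ref.tag) != "speciesReference":
                    continue
                sid = ref.get("species")
                if sid is None:
                    continue
                stoich = ref.get("stoichiometry")
                coef = as_coefficient(stoich) if stoich is not None else Fraction(1)
                out[sid] = out.get(sid, Fraction(0)) + coef
        return out

    specs = []
    reversible = []
    skipped = 0
    for i, el in enumerate(e for e in root.iter() if local(e.tag) == "reaction"):
        rid = el.get("id") or f"reaction{i}"
        tail = side_of(el, "listOfReactants")
        head = side_of(el, "listOfProducts")
        if not tail or not head:
            skipped += 1
            logger.warning(
                "skipping reaction %r: empty %s side",
                rid,
                "reactant" if not tail else "product",
            )
            continue
        specs.append({"id": rid, "tail": tail, "head": head})
        # SBML level-2 default for a missing attribute is reversible
        if el.get("reversible", "true") == "true":
            reversible.append(rid)
    if not specs:
        raise FormatError(f"no usable reactions in SBML file {path}")

    H = build_hypergraph(specs, sources=set(), targets=set())
    for sid in species_ids:  # species not appearing in any reaction
        H.add_vertex(sid)
    if reversible:
        add_reverse_edges(H, reversible)
    auto_s, auto_t = detect_sources_targets(H)
    H.set_sources(auto_s - auto_t)
    H.set_targets(auto_t - auto_s)
    H.sbml_skipped_reactions = skipped
    return H


def _solution_payload(sol) -> dict:
    payload = {
        "status": sol.status,
        "objective_value": None
        if sol.objective_value != sol.objective_value  # NaN
        else sol.objective_value,
        "flux": {
            eid: f for eid, f in sorted(sol.flux.items()) if f > 0.0
        },
        "active_edges": sorted(sol.active_edges),
        "active_sources": sorted(sol.active_sources),
        "iterations": [
            rec.to_dict() if hasattr(rec, "to_dict") else rec for rec in sol.iterations
        ],
        "validity": sol.validity.to_dict() if sol.validity is not None else None,
    }
    if sol.problem is not None:
        payload["problem"] = {
            "mode": sol.problem.mode,
            "objective": sol.problem.objective,
            "regulation_order": sol.problem.regulation_order,
            "epsilon": float(sol.problem.epsilon),
        }
    return payload


def write_solution(sol, path_or_stream, format: str = "json") -> None:
    """Serialize a solution (status, objective, nonzero flux, active sets,
    iteration log, validity report) as JSON or TSV with stable key order."""
    if format not in ("json", "tsv"):
        raise ValueError(f"unknown solution format {format!r}")
    payload = _solution_payload(sol)
    stream, close = _open(path_or_stream, "w")
    try:
        if format == "json":
            json.dump(payload, stream, indent=2, sort_keys=False)
            stream.write("\n")
        else:
            stream.write(f"status\t{payload['status']}\n")
            obj = payload["objective_value"]
            stream.write(f"objective_value\t{'' if obj is None else obj}\n")
            stream.write(f"active_edges\t{','.join(payload['active_edges'])}\n")
            stream.write(f"active_sources\t{','.join(payload['active_sources'])}\n")
            stream.write(f"iterations\t{len(payload['iterations'])}\n")
            if payload["validity"] is not None:
                stream.write(f"is_valid\t{payload['validity']['is_valid']}\n")
            for eid, f in payload["flux"].items():
                stream.write(f"flux\t{eid}\t{f!r}\n")
    finally:
        if close:
            stream.close()


def read_solution(path_or_stream) -> dict:
    """Read back a JSON solution file (the format ``write_solution`` emits)."""
    stream, close = _open(path_or_stream, "r")
    try:
        return json.load(stream)
    finally:
        if close:
            stream.close()
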