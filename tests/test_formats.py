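import io
import json
from fractions import Fraction

import pytest

from hyperfactory import (
    FactoryProblem,
    FormatError,
    import_sbml,
    random_instance,
    read_hypergraph,
    read_solution,
    write_hypergraph,
    write_solution,
)


def roundtrip(H):
    buf = io.StringIO()
    write_hypergraph(H, buf)
    return read_hypergraph(io.StringIO(buf.getvalue())), buf.getvalue()


def assert_same_hypergraph(A, B):
    assert A.edge_ids == B.edge_ids
    assert A.vertices == B.vertices
    assert A.sources == B.sources
    assert A.targets == B.targets
    for a in A.edges:
        b = B.edge(a.id)
        assert a.tail == b.tail and a.head == b.head
        assert a.inhibitors == b.inhibitors
        assert a.positive_regulators == b.positive_regulators
        assert a.weight == b.weight
        assert a.reverse_of == b.reverse_of


class TestRead:
    def test_minimal_document(self):
        H = read_hypergraph(io.StringIO("EDGE\te\ts\tt\nSOURCES\ts\nTARGETS\tt\n"))
        assert len(H) == 1 and H.vertices == {"s", "t"}
        assert H.sources == {"s"} and H.targets == {"t"}

    def test_missing_coefficients_default_to_one(self):
        H = read_hypergraph(io.StringIO("EDGE\te\ta,b\tc\n"))
        e = H.edge("e")
        assert e.tail == {"a": Fraction(1), "b": Fraction(1)}

    def test_explicit_coefficients_and_rationals(self):
        H = read_hypergraph(io.StringIO("EDGE\te\ta:2,b:1/3\tc:0.5\n"))
        e = H.edge("e")
        assert e.tail == {"a": Fraction(2), "b": Fraction(1, 3)}
        assert e.head == {"c": Fraction(1, 2)}

    def test_inhibit_line(self):
        H = read_hypergraph(
            io.StringIO("EDGE\te1\ts\tt\nEDGE\te2\ts\tv\nINHIBIT\te1\tv\n")
        )
        assert H.edge("e1").inhibitors == {"v"}

    def test_reversible_line_expands(self):
        H = read_hypergraph(io.StringIO("EDGE\te\ta\tb\nREVERSIBLE\te\n"))
        assert len(H) == 2
        assert H.edge("e").reverse_of is not None

    def test_auto_detection_runs_after_reversal(self):
        H = read_hypergraph(
            io.StringIO("EDGE\te\ta\tb\nEDGE\td\ts\ta\nREVERSIBLE\te\n")
        )
        assert H.sources == {"s"}
        assert "b" not in H.targets  # b has an out-edge via the reverse

    @pytest.mark.parametrize(
        "doc,match",
        [
            ("BOGUS\tx\n", "line 1.*unknown record"),
            ("EDGE\te\ts:0\tt\n", "line 1.*coefficient"),
            ("EDGE\te\ts\tt\nSOURCES\tzz\n", "line 2.*unknown vertices"),
            ("EDGE\te\ts\tt\nEDGE\te\ts\tt\n", "line 2.*duplicate"),
            ("EDGE\te\ts\tt\nINHIBIT\te\tzz\n", "line 2.*unknown vertices"),
            ("EDGE\te\ts\n", "line 1.*EDGE needs"),
        ],
    )
    def test_errors_carry_line_numbers(self, doc, match):
        with pytest.raises(FormatError, match=match):
            read_hypergraph(io.StringIO(doc))


class TestWrite:
    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_random_instance(self, seed):
        H = random_instance(
            24, 20, seed, p_reversible=0.3, p_inhibitor=0.3, p_both_sides=0.2
        )
        H2, _ = roundtrip(H)
        assert_same_hypergraph(H, H2)

    def test_roundtrip_is_canonical(self):
        # writing a re-read document reproduces the byte stream
        H = random_instance(10, 12, 3, p_reversible=0.4, p_inhibitor=0.4)
        H2, text1 = roundtrip(H)
        _, text2 = roundtrip(H2)
        assert text1 == text2

    def test_reverse_pair_serialized_once(self):
        H = read_hypergraph(io.StringIO("EDGE\te\ta\tb\nREVERSIBLE\te\n"))
        buf = io.StringIO()
        write_hypergraph(H, buf)
        text = buf.getvalue()
        assert text.count("EDGE") == 1
        assert "REVERSIBLE\te" in text

    def test_positive_regulators_reextracted(self):
        H = read_hypergraph(io.StringIO("EDGE\te\ts\tt\nENHANCE\te\tp\n"))
        assert H.edge("e").tail["p"] == 1  # merged on read
        H2, text = roundtrip(H)
        assert "ENHANCE\te\tp" in text
        assert_same_hypergraph(H, H2)

    def test_no_targets_line_when_empty(self):
        # a pure cycle auto-detects neither sources nor targets
        H = read_hypergraph(io.StringIO("EDGE\te1\ta\tb\nEDGE\te2\tb\ta\n"))
        buf = io.StringIO()
        write_hypergraph(H, buf)
        assert "TARGETS" not in buf.getvalue()


class TestSBML:
    def test_minimal_import(self, sbml_factory):
        path = sbml_factory(
            "a.sbml",
            ["A", "B"],
            [{"id": "R1", "reactants": [("A", 1)], "products": [("B", 1)]}],
        )
        H = import_sbml(path)
        assert len(H) == 1
        assert H.edge("R1").tail == {"A": Fraction(1)}
        assert H.sources == {"A"} and H.targets == {"B"}

    def test_reversible_reaction_becomes_edge_pair(self, sbml_factory):
        path = sbml_factory(
            "b.sbml",
            ["A", "B"],
            [
                {
                    "id": "R1",
                    "reversible": True,
                    "reactants": [("A", 1)],
                    "products": [("B", 1)],
                }
            ],
        )
        H = import_sbml(path)
        assert len(H) == 2
        assert H.edge("R1").reverse_of is not None

    def test_missing_stoichiometry_defaults_to_unit(self, sbml_factory):
        path = sbml_factory(
            "c.sbml",
            ["A", "B", "C"],
            [
                {
                    "id": "R1",
                    "reactants": [("A", None), ("B", 2)],
                    "products": [("C", None)],
                }
            ],
        )
        H = import_sbml(path)
        e = H.edge("R1")
        assert e.tail == {"A": Fraction(1), "B": Fraction(2)}
        assert e.head == {"C": Fraction(1)}

    def test_empty_side_skipped_and_counted(self, sbml_factory):
        path = sbml_factory(
            "d.sbml",
            ["A", "B"],
            [
                {"id": "R1", "reactants": [("A", 1)], "products": [("B", 1)]},
                {"id": "EX", "reactants": [("A", 1)], "products": []},
            ],
        )
        H = import_sbml(path)
        assert len(H) == 1
        assert H.sbml_skipped_reactions == 1

    def test_import_then_text_roundtrip_isomorphic(self, sbml_factory):
        path = sbml_factory(
            "e.sbml",
            ["A", "B", "C"],
            [
                {"id": "R1", "reactants": [("A", 1)], "products": [("B", 2)]},
                {
                    "id": "R2",
                    "reversible": True,
                    "reactants": [("B", 1)],
                    "products": [("C", 1)],
                },
            ],
        )
        H = import_sbml(path)
        H2, _ = roundtrip(H)
        assert_same_hypergraph(H, H2)

    def test_not_sbml_raises(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<notsbml/>")
        with pytest.raises(FormatError, match="not an SBML"):
            import_sbml(bad)


class TestSolutionFiles:
    def test_single_edge_solution_json(self, single_edge, tmp_path):
        sol = FactoryProblem(single_edge, mode="accumulation").solve()
        path = tmp_path / "sol.json"
        write_solution(sol, path)
        payload = read_solution(path)
        assert payload["status"] == "optimal"
        assert list(payload["flux"]) == ["e"]
        assert payload["active_edges"] == ["e"]
        assert payload["problem"]["epsilon"] == pytest.approx(1e-4)

    def test_infeasible_solution_serializes_empty(self, fixtures, tmp_path):
        sol = FactoryProblem(fixtures["splitter"], mode="conservation").solve()
        path = tmp_path / "sol.json"
        write_solution(sol, path)
        payload = read_solution(path)
        assert payload["status"] == "infeasible"
        assert payload["flux"] == {}

    def test_second_order_solution_records_iterations(self, fixtures, tmp_path):
        sol = FactoryProblem(
            fixtures["second_order_triple"], regulation_order=2
        ).solve()
        path = tmp_path / "sol.json"
        write_solution(sol, path)
        payload = read_solution(path)
        assert len(payload["iterations"]) >= 1
        assert payload["iterations"][0]["index"] == 1

    def test_tsv_output(self, single_edge, tmp_path):
        sol = FactoryProblem(single_edge, mode="accumulation").solve()
        path = tmp_path / "sol.tsv"
        write_solution(sol, path, format="tsv")
        lines = path.read_text().splitlines()
        assert lines[0] == "status\toptimal"
        assert any(line.startswith("flux\te\t") for line in lines)
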