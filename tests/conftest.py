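import textwrap

import pytest

from hyperfactory import build_hypergraph, forcing_fixtures


@pytest.fixture
def fixtures():
    return forcing_fixtures()


@pytest.fixture
def single_edge():
    """The smallest feasible instance: one reaction s -> t."""
    return build_hypergraph(
        [{"id": "e", "tail": {"s": 1}, "head": {"t": 1}}],
        sources={"s"},
        targets={"t"},
    )


@pytest.fixture
def chain():
    """s -> a -> t: one intermediate with a conservation row."""
    return build_hypergraph(
        [
            {"id": "e1", "tail": {"s": 1}, "head": {"a": 1}},
            {"id": "e2", "tail": {"a": 1}, "head": {"t": 1}},
        ],
        sources={"s"},
        targets={"t"},
    )


SBML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="m">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
{species}
    </listOfSpecies>
    <listOfReactions>
{reactions}
    </listOfReactions>
  </model>
</sbml>
"""


def make_sbml(species, reactions):
    """Assemble a small SBML document from (id,) species and reaction dicts
    {id, reversible, reactants: [(species, stoich-or-None)], products: [...]}.
    """
    sp = "\n".join(
        f'      <species id="{s}" compartment="c" hasOnlySubstanceUnits="false"'
        ' boundaryCondition="false" constant="false"/>'
        for s in species
    )
    rx_parts = []
    for r in reactions:
        def refs(side):
            out = []
            for name, stoich in side:
                attr = "" if stoich is None else f' stoichiometry="{stoich}"'
                out.append(
                    f'          <speciesReference species="{name}"{attr} constant="true"/>'
                )
            return "\n".join(out)

        reactants = refs(r.get("reactants", []))
        products = refs(r.get("products", []))
        body = ""
        if reactants:
            body += f"        <listOfReactants>\n{reactants}\n        </listOfReactants>\n"
        if products:
            body += f"        <listOfProducts>\n{products}\n        </listOfProducts>\n"
        rx_parts.append(
            f'      <reaction id="{r["id"]}" reversible="{str(r.get("reversible", False)).lower()}" fast="false">\n'
            + body
            + "      </reaction>"
        )
    return SBML_TEMPLATE.format(species=sp, reactions="\n".join(rx_parts))


@pytest.fixture
def sbml_factory(tmp_path):
    def write(name, species, reactions):
        path = tmp_path / name
        path.write_text(make_sbml(species, reactions))
        return path

    return write
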