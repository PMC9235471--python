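# hyperfactory

Optimal *factories* in metabolic networks modelled as directed hypergraphs,
with first- and second-order negative regulation, solved by mixed-integer
linear programming.

## The problem

A metabolic network is a directed hypergraph `G = (V, E)`: vertices are
substances, and each hyperedge (reaction) `e` points from its set of input
reactants `tail(e)` to its set of output products `head(e)`, with a
stoichiometric ratio per participant.  Given candidate sources `S`, targets
`T` and a minimum-flux constant `ε > 0`, a **factory** is a flux vector
`f ∈ [0,1]^E` that produces every target,

```
Σ_{e ∈ in(t)} f_e ≥ ε        for every t ∈ T,
```

while every intermediate metabolite `v ∈ I = V − (S ∪ T)` is either exactly
balanced (**conservation**, `M|I · f = 0`) or at least not depleted
(**accumulation**, `M|I · f ≥ 0`), where `M` is the signed stoichiometry
matrix.  A **min-edge factory** uses the fewest (weighted) reactions with
positive flux; a **min-source factory** uses the fewest sources with positive
outgoing flux; a bicriteria objective combines both.

Negative regulation enters in two discrete orders:

* **first order** — no active reaction's inhibitor may be produced by
  another active reaction (MILP constraints `x_e + x_d ≤ 1` for every
  producer `d` of an inhibitor of `e`);
* **second order** — additionally, no active reaction's inhibitor may be
  *producible* from the factory's active sources through any reactions in
  the network.  This is not linear in the original variables, so it is
  solved by a next-best-factory iteration: solve the first-order MILP, test
  each inhibitor with a producibility LP, cut off the offending active-edge
  set and edge/source combinations, and re-solve.

Finding a min-edge factory is NP-complete (by reduction from Exact Cover by
3-sets — the reduction gadget ships as a test-instance generator), but the
MILPs solve quickly in practice.  Every solver output is re-validated
independently: conservation residuals, target production, indicator/support
agreement and regulation violations are recomputed from the stoichiometry,
never trusted from the solver.

Who this is for: anyone doing pathway inference or metabolic engineering on
stoichiometric network models who needs the *fewest-reaction* route to a set
of products — with inhibition taken seriously — rather than flux-balance
optima or exhaustive elementary-flux-mode enumeration.

## Worked example

The network below has a one-reaction route `e1: s → t`, but `e1` is
inhibited by `v`, and `v` is itself a required target (produced by `d`).

```
EDGE	e1	s	t
EDGE	d	s	v
EDGE	e2	s	a
EDGE	e3	a	t
INHIBIT	e1	v
SOURCES	s
TARGETS	t,v
```

```python
from hyperfactory import FactoryProblem

problem = FactoryProblem.from_file("pair.hg", mode="conservation",
                                   regulation_order=1)
print(problem.solve().summary())
```

```
Factory solution
================
objective kind:   min_edge
mode:             conservation
regulation order: 1
status:           optimal
objective:        3
active edges:     3
active sources:   1
validated:        True
max conservation residual: 0
min target production:     1
edges: d, e2, e3
sources: s
```

Ignoring regulation (`regulation_order=0`) the optimum is 2 reactions
(`{e1, d}`), but that factory produces the inhibitor of its own reaction
`e1`.  Under first-order regulation the solver must route around it:
3 reactions (`d, e2, e3`), still from the single source `s`, with
conservation residual 0 and both targets produced at flux 1.

The same is available from the shell:

```sh
hyperfactory solve --mode conservation --order 1 pair.hg
hyperfactory generate reduction --k 1 --sets "1,2,3" -o gadget.hg   # prints ell=6
hyperfactory validate solution.json pair.hg
hyperfactory convert model.sbml model.hg
```

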