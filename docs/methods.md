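# Methods

## Model

A network is a directed hypergraph `G = (V, E)` with candidate sources
`S ⊆ V` and targets `T ⊆ V − S`.  Each hyperedge `e` carries positive
stoichiometric ratios on its tail (consumed) and head (produced) vertices,
an optional inhibitor set, optional positive regulators, an optional reverse
partner, and a positive weight (default 1).  The signed stoichiometry matrix
`M = (r_{v,e})` has `r_{v,e} = −(tail ratio)` for pure tail members and
`+(head ratio)` for pure head members.  A vertex on both sides of a reaction
(a catalyst-like participant) is assigned `r_{v,e} = 0` by default; the
alternative `net_difference` rule (head minus tail ratio) is available via
`both_sides_rule` — both conventions appear in the literature and the
package treats the explicit zero assignment as canonical while leaving the
choice to the caller.

A factory is a flux `f ∈ [0,1]^E` with `M|I · f = 0` (conservation) or
`M|I · f ≥ 0` (accumulation) over the intermediates `I = V − (S ∪ T)`, and
`Σ_{e ∈ in(t)} f_e ≥ ε` for each target.  Since any feasible flux stays
feasible under positive scaling, fluxes are normalized to `[0, 1]` and
"production" must be expressed through the strictly positive constant `ε`.

### The MILP

Variables: continuous flux `f_e ∈ [0,1]`; binary active-edge indicators
`x_e`; binary active-source indicators `y_s` (present for min-source /
bicriteria objectives and for second-order runs).  Constraints, each tagged
with its provenance in the model description:

| tag             | constraint                                   |
|-----------------|----------------------------------------------|
| conservation    | `M|I · f = 0` (row per intermediate)         |
| accumulation    | `M|I · f ≥ 0`                                |
| production      | `Σ_{e ∈ in(t)} f_e ≥ ε` per target           |
| active_edge     | `x_e ≥ f_e`                                  |
| reversible      | `x_e + x_rev(e) ≤ 1` per reverse pair        |
| active_source   | `y_s ≥ f_e` for `e ∈ out(s)`                 |
| neg_reg_1       | `x_e + x_d ≤ 1` per inhibitor producer pair  |
| exclusion_edges / exclusion_sources | second-order cuts (below) |

Objectives: `min Σ w_e x_e` (min-edge), `min Σ y_s` (min-source), or a
weighted sum.  The bicriteria presets use strictly dominating weights:
`edges_then_sources` weights edges by `|S| + 1` so one extra reaction always
costs more than any change in source count; `sources_then_edges` weights
sources by (total edge weight + 1) symmetrically.  First-order pairs are
deduplicated, and a reaction producing its own inhibitor yields
`2 x_e ≤ 1`, banning it outright.  A target with no in-edges produces an
all-zero production row with a positive lower bound, i.e. clean
infeasibility rather than a special case.

### Second-order iteration

Second-order validity — no inhibitor of an active edge producible from the
active sources via *any* reactions — cannot be written linearly in `(f, x,
y)`.  The solver iterates: solve the first-order MILP; for each active edge
with an inhibitor `v`, decide producibility of `v` from the active sources
`A` by a feasibility LP (flux variables only, mode rows over `V − (S ∪
{v})`, zero flux on out-edges of `S − A`, production `Σ_{in(v)} f_e ≥ ε`);
if any test fires, add the cut `Σ_{e ∈ F} x_e ≤ |F| − 1` over the current
active set `F` plus `x_e + Σ_{s ∈ A} y_s ≤ |A|` per offending edge, and
re-solve.  The edge cut makes active-edge sets non-repeating and objective
values non-decreasing; an infeasible augmented MILP proves no valid factory
exists.  Producibility results are memoized per `(A, v)`.  The iteration is
defined for the min-edge objective; `max_iterations` (default 1000) guards
against instances whose factories must all be enumerated before failing.

Two choices here were genuinely open and are fixed as follows: the
producibility LP treats `v` as the sole pseudo-target, so the original
targets become ordinary intermediates (mirroring the main model's
structure), and it inherits the problem's conservation/accumulation mode so
that the two LP families share semantics.

## Numerical choices

* `ε = 10⁻⁴` by default: small enough not to exclude factories whose
  rescaled flux through some route is genuinely small, large enough to sit
  far above solver tolerances.  Overridable everywhere; the `--epsilon-sweep`
  CLI flag reports the objective per candidate value, since a too-large `ε`
  silently discards valid factories and a too-small one invites numerically
  invalid solver output.
* Activity threshold `ε · 10⁻³` for flux support and active sources: strict
  `f > 0` is meaningless in floating point.
* HiGHS (via `scipy.optimize.milp`) is run with primal/MIP feasibility
  tolerances of 10⁻⁹; at its default 10⁻⁶ the MIP can accept incumbents
  whose active set admits no exactly feasible flux.
* The MILP decides only the *active set*.  The reported flux is re-derived
  by an exact support LP that zeroes all other edges and maximizes the
  minimum support flux, so every reported edge is strictly active and
  conservation residuals are at basic-solution precision.  If that LP is
  infeasible the solve raises rather than returning a numerically fake
  factory.
* Validation tolerances: conservation residual ≤ 10⁻⁸, production ≥
  ε − 10⁻⁹ — an order of magnitude beyond LP solver defaults.  Validation
  recomputes everything from the hypergraph and reports; it never raises.
* Coefficients are exact `Fraction`s end-to-end (text format accepts
  decimals and `p/q`) and become floats only when a solver matrix is built.

## Oracles

`oracle_min_edge` enumerates edge subsets in increasing size and decides
each by LP, independently of the MILP machinery.  Pruning keeps this exact
but fast: every target needs an in-edge in the support; no reverse pair;
no first-order conflict (order ≥ 1); every consumed intermediate needs a
producer in the support, and under conservation every produced intermediate
needs a consumer — all valid for minimal exact supports, which is what the
enumeration returns first.  For order 2 the oracle additionally requires the
support to be *exactly* realizable (each edge individually maximizable to
positive flux; convexity then gives a simultaneous all-positive point),
derives the active sources from the support's tails, and re-checks
producibility with its own standalone LP.

`reduction_soundness_check` compares a brute-force Exact Cover decision
against the oracle on the reduction gadget (conservation, `ε = 1`, bound
`7k − 1`): the gadget has one source, one target, `(−1, +3)` top-level
ratios, unit intermediate ratios, and a daisy chain of two-tail hyperedges
replacing the conceptual all-elements hyperedge.

## Synthetic data

`random_instance` emulates sparse metabolic networks: small tail/head sizes
(defaults ≤ 3), small integer stoichiometries (1–3), optional reversibility,
optional catalyst-like both-sides vertices, and inhibitors drawn from
non-tail vertices.  Sources/targets are degree-detected after reversible
expansion, and sampling retries until a pure source and a pure target exist.
It does **not** emulate hub metabolites with extreme degrees,
compartmentalization, realistic degree distributions, or curated regulator
annotations — so passing tests demonstrate correctness of the optimization
and validation machinery, not biological fidelity on genome-scale networks.
The forcing fixtures each isolate one behaviour (mode split, first-order
rerouting, second-order source switching, min-source edge inflation,
reversible two-cycle trap, ε-gating); sizes of everything the test-suite
and acceptance script solve (≤ 10–20 edges for oracle comparisons, chosen so
exhaustive enumeration stays exact) are stated in the tests themselves.

## Limitations

* Second-order support is min-edge only, matching how the iteration is
  defined; third-order regulation (inhibitors inhibiting each other) is out
  of scope.
* Enumerating *all* optimal factories is not a supported API; repeated
  solving with exclusion cuts approximates it without completeness
  guarantees.
* The SBML importer reads the core species/reaction/stoichiometry/reversible
  subset only — no BioPAX, no FBC bounds, no regulation (core SBML cannot
  express it).
* Min-source factories may legitimately contain flux cycles that do not
  serve the targets; only the min-edge objective suppresses them.
* The solver backend is HiGHS through scipy; the model-description layer is
  backend-agnostic, but no other backend ships.
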