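"""Mixed-integer linear programs for optimal metabolic factories.

A *factory* is a nonnegative flux vector ``f`` over the reactions of a
directed hypergraph that produces every target from the candidate sources
while conserving (``M|I . f = 0``) or merely not depleting
(``M|I . f >= 0``) each intermediate metabolite, where ``M|I`` is the
stoichiometry matrix restricted to intermediates ``I = V - (S | T)``.
Production of a target ``t`` is enforced through a minimum-flux constant
``eps > 0``: ``sum_{e in in(t)} f_e >= eps``.

The model minimizes either the (weighted) number of active reactions
(*min-edge factory*), the number of active sources (*min-source factory*),
or a weighted combination of the two (bicriteria).  Binary indicators
``x_e >= f_e`` mark active reactions, ``y_s >= f_e`` for ``e in out(s)``
mark active sources, and pairs of reverse reactions are kept mutually
exclusive (``x_e + x_rev(e) <= 1``) so a reversible reaction cannot fake
production through a trivial two-cycle.  First-order negative regulation
adds ``x_e + x_d <= 1`` whenever reaction ``d`` produces an inhibitor of
reaction ``e``: a factory may not itself synthesize a substance that shuts
one of its reactions down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint
from scipy.optimize import milp as _scipy_milp

from .hypergraph import Hypergraph, HypergraphError, as_coefficient, stoichiometry_matrix

__all__ = [
    "SolverSettings",
    "FactoryProblem",
    "ModelDescription",
    "Constraint",
    "FactorySolution",
    "FactoryValidationError",
    "SolverError",
    "build_model",
    "solve",
    "active_sources_of",
]

MODES = ("conservation", "accumulation")
OBJECTIVES = ("min_edge", "min_source", "bicriteria")
BICRITERIA_PRESETS = ("edges_then_sources", "sources_then_edges")

#: constraint provenance tags
TAGS = (
    "domain",
    "conservation",
    "accumulation",
    "production",
    "active_edge",
    "reversible",
    "active_source",
    "neg_reg_1",
    "exclusion_edges",
    "exclusion_sources",
)


class SolverError(RuntimeError):
    """The MILP backend returned an unexpected status."""


class FactoryValidationError(RuntimeError):
    """Solver output failed independent validation (see the validity report)."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


@dataclass
class SolverSettings:
    """Backend knobs.  HiGHS (via scipy) is deterministic; ``threads`` and
    ``seed`` are accepted for interface stability and passed through only
    where the backend supports them."""

    time_limit: float | None = None
    mip_gap: float = 0.0
    integrality_tolerance: float = 1e-9
    #: HiGHS row-feasibility tolerances; the default 1e-6 lets the MIP accept
    #: incumbents whose active set is not exactly realizable
    feasibility_tolerance: float = 1e-9
    threads: int = 1
    seed: int = 0


@dataclass
class Constraint:
    """One tagged linear constraint ``lb <= sum coefs[var]*var <= ub``."""

    tag: str
    coefs: dict[str, float]
    lb: float
    ub: float

    def __post_init__(self):
        if self.tag not in TAGS:
            raise ValueError(f"unknown constraint tag {self.tag!r}")


@dataclass
class ModelDescription:
    """A solver-agnostic factory model: variables, tagged constraints, objective.

    Variables are named ``f:<edge>`` (continuous flux in [0,1]),
    ``x:<edge>`` (binary active-edge) and ``y:<source>`` (binary
    active-source); the domain constraints 0..1 are carried in ``bounds``.
    """

    variables: list[tuple[str, str]]  # (name, "continuous" | "binary")
    constraints: list[Constraint]
    objective: dict[str, float]

    def by_tag(self, tag: str) -> list[Constraint]:
        return [c for c in self.constraints if c.tag == tag]

    def add(self, tag: str, coefs: Mapping[str, float], lb: float, ub: float) -> None:
        self.constraints.append(Constraint(tag, dict(coefs), lb, ub))

    def to_scipy(self):
        """Compile to (c, LinearConstraint, integrality, Bounds) for scipy.optimize.milp."""
        index = {name: i for i, (name, _) in enumerate(self.variables)}
        n = len(self.variables)
        c = np.zeros(n)
        for name, coef in self.objective.items():
            c[index[name]] = coef
        rows, cols, vals, lbs, ubs = [], [], [], [], []
        for i, con in enumerate(self.constraints):
            for name, coef in con.coefs.items():
                rows.append(i)
                cols.append(index[name])
                vals.append(coef)
            lbs.append(con.lb)
            ubs.append(con.ub)
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.constraints), n)
        )
        integrality = np.array(
            [0 if kind == "continuous" else 1 for _, kind in self.variables]
        )
        bounds = Bounds(np.zeros(n), np.ones(n))
        return c, LinearConstraint(A, np.array(lbs), np.array(ubs)), integrality, bounds


@dataclass
class FactoryProblem:
    """A factory optimization instance: the model object of this package.

    Parameters
    ----------
    hypergraph : Hypergraph
        Network with candidate sources ``S`` and targets ``T`` already set.
    mode : {"conservation", "accumulation"}
        Whether intermediates must balance exactly or may accumulate.
    objective : {"min_edge", "min_source", "bicriteria"}
    bicriteria_weights : pair of nonnegative numbers, or preset name
        ``"edges_then_sources"`` uses (|S|+1, 1) so the edge count strictly
        dominates; ``"sources_then_edges"`` uses (1, total edge weight + 1).
    regulation_order : {0, 1, 2}
        0 ignores negative regulation; 1 forbids a factory from producing an
        inhibitor of one of its own reactions; 2 additionally forbids
        inhibitors producible from the factory's active sources via any
        reactions in the network (solved iteratively, see
        :mod:`hyperfactory.second_order`).
    epsilon : positive rational in (0, 1]
        Minimum total flux into each target.  10^-4 by default: large enough
        to stay clear of solver tolerances, small enough not to exclude
        factories whose rescaled flux through some route is genuinely small.
    """

    hypergraph: Hypergraph
    mode: str = "conservation"
    objective: str = "min_edge"
    bicriteria_weights: tuple | str | None = None
    regulation_order: int = 0
    epsilon: Fraction = Fraction(1, 10_000)
    both_sides_rule: str = "zero"
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.objective not in OBJECTIVES:
            raise ValueError(
                f"objective must be one of {OBJECTIVES}, got {self.objective!r}"
            )
        if self.regulation_order not in (0, 1, 2):
            raise ValueError("regulation_order must be 0, 1 or 2")
        self.epsilon = as_coefficient(self.epsilon)
        if self.epsilon > 1:
            raise ValueError("epsilon must lie in (0, 1]")
        if isinstance(self.bicriteria_weights, str):
            if self.bicriteria_weights not in BICRITERIA_PRESETS:
                raise ValueError(
                    f"unknown bicriteria preset {self.bicriteria_weights!r}"
                )
        elif self.bicriteria_weights is not None:
            we, ws = self.bicriteria_weights
            if we < 0 or ws < 0 or (we == 0 and ws == 0):
                raise ValueError("bicriteria weights must be nonnegative, not both 0")

    # -- convenience -----------------------------------------------------
    @classmethod
    def from_file(cls, path, **kwargs) -> "FactoryProblem":
        from .formats import read_hypergraph

        return cls(hypergraph=read_hypergraph(path), **kwargs)

    @property
    def active_threshold(self) -> float:
        """Flux support cutoff: strict ``f > 0`` is meaningless in floating
        point, so activity means flux above eps * 1e-3 — far below any
        meaningful flux, far above LP solver tolerances."""
        return float(self.epsilon) * 1e-3

    def resolved_bicriteria_weights(self) -> tuple[float, float]:
        w = self.bicriteria_weights or "edges_then_sources"
        if w == "edges_then_sources":
            return (float(len(self.hypergraph.sources)) + 1.0, 1.0)
        if w == "sources_then_edges":
            total_w = float(sum(e.weight for e in self.hypergraph.edges))
            return (1.0, total_w + 1.0)
        return (float(w[0]), float(w[1]))

    def solve(self, **kwargs) -> "FactorySolution":
        """Fit the model: dispatch on regulation order and return a solution."""
        if self.regulation_order == 2:
            from .second_order import solve_second_order

            return solve_second_order(self, **kwargs)
        return solve(self, **kwargs)


def _needs_sources(problem: FactoryProblem) -> bool:
    return problem.objective in ("min_source", "bicriteria") or problem.regulation_order == 2


def build_model(problem: FactoryProblem, with_source_vars: bool | None = None) -> ModelDescription:
    """Assemble the tagged MILP for ``problem``.

    Raises on an empty target set (nothing to produce) rather than returning
    a trivially feasible model.
    """
    H = problem.hypergraph
    if not H.targets:
        raise HypergraphError("target set is empty")
    eps = float(problem.epsilon)

    if with_source_vars is None:
        with_source_vars = _needs_sources(problem)

    variables: list[tuple[str, str]] = []
    for eid in H.edge_ids:
        variables.append((f"f:{eid}", "continuous"))
    for eid in H.edge_ids:
        variables.append((f"x:{eid}", "binary"))
    src_order = sorted(H.sources)
    if with_source_vars:
        for s in src_order:
            variables.append((f"y:{s}", "binary"))

    model = ModelDescription(variables=variables, constraints=[], objective={})

    # conservation / accumulation rows for intermediates
    M = stoichiometry_matrix(H, rule=problem.both_sides_rule)
    rows: dict[str, dict[str, float]] = {}
    for (v, eid), r in M.entries.items():
        if v in H.intermediates:
            rows.setdefault(v, {})[f"f:{eid}"] = float(r)
    for v in sorted(rows):
        if problem.mode == "conservation":
            model.add("conservation", rows[v], 0.0, 0.0)
        else:
            model.add("accumulation", rows[v], 0.0, np.inf)

    # production of each target (a target with no in-edges yields an
    # all-zero row with lb=eps, i.e. manifest infeasibility)
    for t in sorted(H.targets):
        coefs = {f"f:{eid}": 1.0 for eid in sorted(H.in_index(t))}
        model.add("production", coefs, eps, np.inf)

    # x_e >= f_e
    for eid in H.edge_ids:
        model.add("active_edge", {f"f:{eid}": 1.0, f"x:{eid}": -1.0}, -np.inf, 0.0)

    # reverse pairs mutually exclusive
    seen_pairs = set()
    for e in H.edges:
        if e.reverse_of is not None:
            pair = frozenset((e.id, e.reverse_of))
            if pair not in seen_pairs:
                seen_pairs.add(pair)
                model.add(
                    "reversible",
                    {f"x:{e.id}": 1.0, f"x:{e.reverse_of}": 1.0},
                    -np.inf,
                    1.0,
                )

    # active-source indicators
    if with_source_vars:
        for s in src_order:
            for eid in sorted(H.out_index(s)):
                model.add(
                    "active_source", {f"f:{eid}": 1.0, f"y:{s}": -1.0}, -np.inf, 0.0
                )

    # first-order negative regulation: no active edge may have its inhibitor
    # produced by another active edge (d == e collapses to 2 x_e <= 1,
    # banning a reaction that produces its own inhibitor)
    if problem.regulation_order >= 1:
        reg_pairs = set()
        for e in H.edges:
            for v in e.inhibitors:
                for d in H.in_index(v):
                    reg_pairs.add(frozenset((e.id, d)))
        for pair in sorted(reg_pairs, key=sorted):
            coefs: dict[str, float] = {}
            for eid in pair:
                coefs[f"x:{eid}"] = coefs.get(f"x:{eid}", 0.0) + 1.0
            if len(pair) == 1:
                (eid,) = pair
                coefs = {f"x:{eid}": 2.0}
            model.add("neg_reg_1", coefs, -np.inf, 1.0)

    # objective
    edge_term = {f"x:{e.id}": float(e.weight) for e in H.edges}
    source_term = {f"y:{s}": 1.0 for s in src_order}
    if problem.objective == "min_edge":
        model.objective = edge_term
    elif problem.objective == "min_source":
        model.objective = source_term
    else:
        we, ws = problem.resolved_bicriteria_weights()
        model.objective = {k: we * v for k, v in edge_term.items()}
        for k, v in source_term.items():
            model.objective[k] = model.objective.get(k, 0.0) + ws * v
    return model


def _run_scipy(model: ModelDescription, settings: SolverSettings):
    import warnings

    c, lin, integrality, bounds = model.to_scipy()
    options = {
        # scipy warns about these but forwards them to HiGHS verbatim
        "mip_feasibility_tolerance": settings.feasibility_tolerance,
        "primal_feasibility_tolerance": settings.feasibility_tolerance,
    }
    if settings.time_limit is not None:
        options["time_limit"] = settings.time_limit
    if settings.mip_gap:
        options["mip_rel_gap"] = settings.mip_gap
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Unrecognized options")
        res = _scipy_milp(
            c, constraints=lin, integrality=integrality, bounds=bounds, options=options
        )
    return res


@dataclass
class FactorySolution:
    """Fit result: flux assignment, active sets, diagnostics.

    ``status`` is one of ``optimal``, ``infeasible``, ``time_limit``,
    ``iteration_limit``.  ``iterations`` is populated only by the
    second-order solver.  ``validity`` holds the independent validation
    report recomputed from the flux (never from solver internals).
    """

    status: str
    flux: dict[str, float]
    active_edges: set[str]
    active_sources: set[str]
    objective_value: float
    iterations: list = field(default_factory=list)
    validity: object = None
    problem: FactoryProblem | None = None

    @property
    def n_active_edges(self) -> int:
        return len(self.active_edges)

    @property
    def n_active_sources(self) -> int:
        return len(self.active_sources)

    def summary(self) -> str:
        lines = ["Factory solution", "================"]
        if self.problem is not None:
            lines += [
                f"objective kind:   {self.problem.objective}",
                f"mode:             {self.problem.mode}",
                f"regulation order: {self.problem.regulation_order}",
            ]
        lines += [
            f"status:           {self.status}",
            f"objective:        {self.objective_value:g}",
            f"active edges:     {self.n_active_edges}",
            f"active sources:   {self.n_active_sources}",
        ]
        if self.iterations:
            lines.append(f"iterations:       {len(self.iterations)}")
        if self.validity is not None:
            lines.append(f"validated:        {self.validity.is_valid}")
            lines.append(
                f"max conservation residual: {self.validity.max_conservation_residual:.3g}"
            )
            lines.append(
                f"min target production:     {self.validity.min_target_production:.3g}"
            )
        if self.active_edges:
            lines.append("edges: " + ", ".join(sorted(self.active_edges)))
        if self.active_sources:
            lines.append("sources: " + ", ".join(sorted(self.active_sources)))
        return "\n".join(lines)


def active_sources_of(
    H: Hypergraph, flux: Mapping[str, float], threshold: float
) -> set[str]:
    """Sources whose total outgoing flux exceeds ``threshold``."""
    out = set()
    for s in H.sources:
        total = sum(flux.get(eid, 0.0) for eid in H.out_index(s))
        if total > threshold:
            out.add(s)
    return out


def _repair_flux(
    problem: FactoryProblem, support: Iterable[str]
) -> dict[str, float] | None:
    """Recompute flux exactly on a fixed active set via a max–min-flux LP.

    MIP solvers tolerate per-row residuals around 1e-6; re-solving the pure
    LP on the chosen support (zero flux elsewhere) restores residuals to
    basic-solution precision and, by maximizing the minimum flux over the
    support, keeps every chosen edge strictly active whenever the support is
    simultaneously realizable.  Returns ``None`` if it is not.
    """
    from scipy.optimize import linprog

    H = problem.hypergraph
    support = sorted(support)
    idx = {eid: j for j, eid in enumerate(support)}
    n = len(support)
    if n == 0:
        return None
    t_col = n  # auxiliary minimum-flux variable

    M = stoichiometry_matrix(H, rule=problem.both_sides_rule)
    I = H.intermediates
    rows: dict[str, dict[int, float]] = {}
    for (v, eid), r in M.entries.items():
        if v in I and eid in idx:
            rows.setdefault(v, {})[idx[eid]] = float(r)

    A_eq, b_eq, A_ub, b_ub = [], [], [], []
    for v in sorted(rows):
        arr = np.zeros(n + 1)
        for j, r in rows[v].items():
            arr[j] = r
        if problem.mode == "conservation":
            A_eq.append(arr)
            b_eq.append(0.0)
        else:
            A_ub.append(-arr)
            b_ub.append(0.0)
    for t in sorted(H.targets):
        arr = np.zeros(n + 1)
        hit = False
        for eid in H.in_index(t):
            if eid in idx:
                arr[idx[eid]] = -1.0
                hit = True
        if not hit:
            return None
        A_ub.append(arr)
        b_ub.append(-float(problem.epsilon))
    for j in range(n):  # f_j >= t
        arr = np.zeros(n + 1)
        arr[j] = -1.0
        arr[t_col] = 1.0
        A_ub.append(arr)
        b_ub.append(0.0)

    c = np.zeros(n + 1)
    c[t_col] = -1.0  # maximize the minimum support flux
    res = linprog(
        c,
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(A_eq) if A_eq else None,
        b_eq=np.array(b_eq) if b_eq else None,
        bounds=[(0.0, 1.0)] * (n + 1),
        method="highs",
    )
    if res.status != 0:
        return None
    flux = {eid: 0.0 for eid in H.edge_ids}
    for eid, j in idx.items():
        flux[eid] = max(0.0, float(res.x[j]))
    return flux


def _extract_solution(
    problem: FactoryProblem, model: ModelDescription, res
) -> FactorySolution:
    from .validate import validate_factory

    H = problem.hypergraph
    thr = problem.active_threshold
    if res.status == 2:
        sol = FactorySolution(
            status="infeasible",
            flux={},
            active_edges=set(),
            active_sources=set(),
            objective_value=float("nan"),
            problem=problem,
        )
        return sol
    if res.status == 1:
        # HiGHS hit its iteration/time limit; attach nothing reliable
        return FactorySolution(
            status="time_limit",
            flux={},
            active_edges=set(),
            active_sources=set(),
            objective_value=float("nan"),
            problem=problem,
        )
    if res.status != 0:
        raise SolverError(f"MILP backend failure: {res.message}")

    values = dict(zip((name for name, _ in model.variables), res.x))
    raw_flux = {eid: max(0.0, values[f"f:{eid}"]) for eid in H.edge_ids}
    x_active = {
        eid for eid in H.edge_ids if values.get(f"x:{eid}", 0.0) >= 0.5
    }

    if problem.objective in ("min_edge", "bicriteria"):
        # at a true min-edge optimum x marks exactly the flux support
        active_edges = x_active
    else:
        # min_source leaves x unminimized; activity is read from the flux
        active_edges = {eid for eid, f in raw_flux.items() if f > thr}

    # the MILP fixes the active set; the flux itself is recomputed by an
    # exact support LP so conservation holds to basic-solution precision
    flux = _repair_flux(problem, active_edges)
    if flux is None:
        raise FactoryValidationError(
            "solver reported optimal but its active set "
            f"{sorted(active_edges)} is not simultaneously realizable"
        )
    support = {eid for eid, f in flux.items() if f > thr}
    mismatches: list[str] = []
    if problem.objective in ("min_edge", "bicriteria"):
        mismatches = sorted(x_active ^ support)

    active_sources = active_sources_of(H, flux, thr)

    if problem.objective == "min_edge":
        objective_value = float(
            sum(float(H.edge(eid).weight) for eid in active_edges)
        )
    elif problem.objective == "min_source":
        objective_value = float(len(active_sources))
    else:
        we, ws = problem.resolved_bicriteria_weights()
        objective_value = we * sum(
            float(H.edge(eid).weight) for eid in active_edges
        ) + ws * len(active_sources)

    report = validate_factory(
        H,
        flux,
        mode=problem.mode,
        epsilon=problem.epsilon,
        regulation_order=min(problem.regulation_order, 1),
        both_sides_rule=problem.both_sides_rule,
        active_threshold=thr,
        active_edges=active_edges if problem.objective != "min_source" else None,
    )
    sol = FactorySolution(
        status="optimal",
        flux=flux,
        active_edges=active_edges,
        active_sources=active_sources,
        objective_value=objective_value,
        validity=report,
        problem=problem,
    )
    if mismatches:
        raise FactoryValidationError(
            f"active-edge indicators disagree with flux support on {mismatches}",
            report,
        )
    if not report.is_valid:
        raise FactoryValidationError(
            "solver reported optimal but the factory failed independent validation: "
            f"max residual {report.max_conservation_residual:.3g}, "
            f"min production {report.min_target_production:.3g}, "
            f"regulation violations {report.regulation_violations}",
            report,
        )
    return sol


def solve(problem: FactoryProblem, model: ModelDescription | None = None) -> FactorySolution:
    """Solve a zeroth- or first-order factory problem to optimality.

    Second-order problems go through
    :func:`hyperfactory.second_order.solve_second_order`.
    Every reported-optimal solution is independently validated (stoichiometry
    residuals, target production, indicator/support agreement) before being
    returned; validation failure raises :class:`FactoryValidationError`.
    """
    if problem.regulation_order not in (0, 1):
        raise ValueError(
            "solve() handles regulation orders 0 and 1; use solve_second_order"
        )
    if model is None:
        model = build_model(problem)
    res = _run_scipy(model, problem.solver)
    return _extract_solution(problem, model, res)
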