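"""Epitope selection: greedy heuristics, binary linear programs, brute force.

Five procedures select an antibody set on the protein–epitope cover graph:

* ``greedy_cover`` — classic greedy set cover: repeatedly take the epitope
  covering the most still-uncovered proteins. Approximation ratio H(n),
  the harmonic number of the largest capture size.
* ``greedy_multicover`` — greedy with a two-term score
  s_cov · (#new proteins) + s_mcov · (#re-covered proteins); only epitopes
  adding at least one new protein are eligible, so it still terminates with
  at most |P| epitopes.
* ``ilp_cover`` — minimize the number of selected epitopes subject to every
  protein being covered at least once (binary LP).
* ``ilp_multicover`` — same objective, but proteins of degree ≥ 2 must be
  covered at least twice (enforced multicover).
* ``ilp_max_multicover`` — maximize the number of multiply covered proteins
  within a full cover using at most ``cost_max`` epitopes (budgeted
  max-multicover with linking variables).

``brute_force_cover`` solves all three exact variants by subset enumeration
and serves as the independent test oracle on small instances.

ILPs are solved with the HiGHS backend via ``scipy.optimize.milp``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .covergraph import CoverGraph, Solution, score_solution
from .combinations import Epitope

__all__ = [
    "GreedyParams",
    "IlpParams",
    "SolveResult",
    "greedy_cover",
    "greedy_multicover",
    "ilp_cover",
    "ilp_multicover",
    "ilp_max_multicover",
    "brute_force_cover",
    "solve",
    "elongation_pairs",
]

ILP_VARIANTS = ("cover", "multicover", "max_multicover")


@dataclass
class GreedyParams:
    """Weights for the multicoverage greedy score.

    Proteome-scale graphs favour innovation over redundancy (s_cov ≫ s_mcov,
    default 100 : 1); for small target lists (a few hundred proteins) the
    opposite regime s_mcov > s_cov is the productive one, 1 : 10 by default.
    """

    s_cov: float = 100.0
    s_mcov: float = 1.0

    SMALL_DATASET_THRESHOLD = 500

    def __post_init__(self) -> None:
        if self.s_cov < 0 or self.s_mcov < 0 or self.s_cov + self.s_mcov <= 0:
            raise ValueError("weights must be non-negative with a positive sum")

    @classmethod
    def for_graph(cls, graph: CoverGraph) -> "GreedyParams":
        if len(graph.proteins) <= cls.SMALL_DATASET_THRESHOLD:
            return cls(s_cov=1.0, s_mcov=10.0)
        return cls(s_cov=100.0, s_mcov=1.0)


@dataclass
class IlpParams:
    variant: str = "cover"
    cost_max: Optional[int] = None
    time_limit: float = 300.0
    solver_backend: str = "highs"
    mip_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in ILP_VARIANTS:
            raise ValueError(f"variant must be one of {ILP_VARIANTS}")
        if self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if self.solver_backend != "highs":
            raise ValueError(
                f"unknown solver backend {self.solver_backend!r}; available: 'highs'"
            )
        if self.cost_max is not None and self.cost_max < 1:
            raise ValueError("cost_max must be a positive integer")


@dataclass
class SolveResult:
    solution: Optional[Solution]
    objective: Optional[float]
    status: str  # optimal | feasible_time_limit | infeasible
    solver_log: str = ""

    def to_dict(self) -> dict:
        d = {"status": self.status, "objective": self.objective}
        if self.solution is not None:
            d.update(self.solution.summary())
        return d


def _ordered_epitopes(graph: CoverGraph) -> list[Epitope]:
    return sorted(graph.epitopes, key=lambda e: (e.side, e.sequence))


def _check_feasible(graph: CoverGraph) -> Optional[SolveResult]:
    """Return an infeasible result naming degree-0 proteins, or None."""
    orphans = sorted(p for p, d in graph.protein_degrees().items() if d == 0)
    if orphans:
        return SolveResult(
            solution=None,
            objective=None,
            status="infeasible",
            solver_log=f"uncoverable proteins (degree 0): {', '.join(orphans)}",
        )
    return None


def greedy_cover(graph: CoverGraph) -> SolveResult:
    """Greedy set cover (highest new coverage first).

    Ties are broken deterministically: largest new coverage, then
    lexicographically smallest (side, sequence).
    """
    return greedy_multicover(graph, GreedyParams(s_cov=1.0, s_mcov=0.0))


def greedy_multicover(
    graph: CoverGraph, params: Optional[GreedyParams] = None
) -> SolveResult:
    """Multicoverage greedy selection.

    Per iteration every unselected epitope a is scored
    ``s_cov * |new(a)| + s_mcov * |recovered(a)|``; only epitopes covering at
    least one new protein are eligible. With s_mcov = 0 this reduces exactly
    to the plain greedy set cover.
    """
    if params is None:
        params = GreedyParams.for_graph(graph)
    infeasible = _check_feasible(graph)
    if infeasible is not None:
        return infeasible

    adj = graph.adjacency()
    order = _ordered_epitopes(graph)
    covered: set[str] = set()
    selected: list[Epitope] = []
    remaining = set(order)

    while covered != graph.proteins:
        best: Optional[Epitope] = None
        best_key: Optional[tuple[float, int]] = None
        for e in order:
            if e not in remaining:
                continue
            new = len(adj[e] - covered)
            if new == 0:
                continue
            score = params.s_cov * new + params.s_mcov * (len(adj[e]) - new)
            key = (score, new)
            if best_key is None or key > best_key:
                best, best_key = e, key
        if best is None:  # cannot happen on a feasible graph
            break
        selected.append(best)
        remaining.discard(best)
        covered |= adj[best]

    solution = score_solution(graph, selected)
    return SolveResult(
        solution=solution,
        objective=float(len(selected)),
        status="optimal" if solution.is_full_cover() else "infeasible",
        solver_log=f"greedy: {len(selected)} epitopes, s_cov={params.s_cov}, "
        f"s_mcov={params.s_mcov}",
    )


def _coverage_matrix(
    graph: CoverGraph,
) -> tuple[list[str], list[Epitope], sparse.csr_matrix]:
    """Protein × epitope 0/1 incidence matrix in deterministic order."""
    proteins = sorted(graph.proteins)
    epitopes = _ordered_epitopes(graph)
    p_index = {p: i for i, p in enumerate(proteins)}
    e_index = {e: j for j, e in enumerate(epitopes)}
    rows, cols = [], []
    for e, p in graph.edges:
        rows.append(p_index[p])
        cols.append(e_index[e])
    mat = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(proteins), len(epitopes))
    )
    return proteins, epitopes, mat


def _milp_status(raw_status: int, message: str) -> str:
    if raw_status == 0:
        return "optimal"
    if raw_status == 1:
        return "feasible_time_limit"
    return "infeasible"


def _run_milp(c, constraints, integrality, bounds, params: IlpParams):
    return milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=bounds,
        options={"time_limit": params.time_limit, "mip_rel_gap": params.mip_gap},
    )


def ilp_cover(graph: CoverGraph, params: Optional[IlpParams] = None) -> SolveResult:
    """Exact minimum set cover: min Σ s_a s.t. every protein covered ≥ once."""
    return _ilp_cover_variant(graph, params, multicover=False)


def ilp_multicover(
    graph: CoverGraph, params: Optional[IlpParams] = None
) -> SolveResult:
    """Enforced multicover: proteins of degree ≥ 2 must be covered ≥ twice."""
    return _ilp_cover_variant(graph, params, multicover=True)


def _ilp_cover_variant(
    graph: CoverGraph, params: Optional[IlpParams], multicover: bool
) -> SolveResult:
    if params is None:
        params = IlpParams(variant="multicover" if multicover else "cover")
    infeasible = _check_feasible(graph)
    if infeasible is not None:
        return infeasible

    proteins, epitopes, mat = _coverage_matrix(graph)
    n_a = len(epitopes)
    degrees = np.asarray(mat.sum(axis=1)).ravel()
    lb = np.minimum(degrees, 2) if multicover else np.ones(len(proteins))

    res = _run_milp(
        c=np.ones(n_a),
        constraints=[LinearConstraint(mat, lb=lb, ub=np.inf)],
        integrality=np.ones(n_a),
        bounds=Bounds(0, 1),
        params=params,
    )
    status = _milp_status(res.status, res.message)
    if res.x is None:
        return SolveResult(None, None, "infeasible", solver_log=res.message)
    chosen = [epitopes[j] for j in np.flatnonzero(res.x > 0.5)]
    solution = score_solution(graph, chosen)
    return SolveResult(
        solution=solution,
        objective=float(round(res.fun)),
        status=status,
        solver_log=res.message,
    )


def ilp_max_multicover(graph: CoverGraph, params: IlpParams) -> SolveResult:
    """Budgeted max-multicover.

    Maximize Σ_i S_i (the number of multiply covered proteins) subject to a
    full cover, the linking constraint Σ_{a adj i} s_a ≥ 1 + S_i for every
    protein i, and the budget Σ_a s_a ≤ cost_max. A lower bound for a
    feasible cost_max is the minimum set cover size; an upper bound worth
    using is the enforced-multicover optimum, at which every degree-≥2
    protein is multicovered.
    """
    if params.cost_max is None:
        raise ValueError("max_multicover requires cost_max")
    infeasible = _check_feasible(graph)
    if infeasible is not None:
        return infeasible

    proteins, epitopes, mat = _coverage_matrix(graph)
    n_a, n_p = len(epitopes), len(proteins)

    # variables: [s_a (n_a), S_i (n_p)]
    cover = sparse.hstack([mat, sparse.csr_matrix((n_p, n_p))])
    linking = sparse.hstack([mat, -sparse.identity(n_p, format="csr")])
    budget = sparse.hstack(
        [sparse.csr_matrix(np.ones((1, n_a))), sparse.csr_matrix((1, n_p))]
    )
    constraints = [
        LinearConstraint(cover, lb=1, ub=np.inf),
        LinearConstraint(linking, lb=1, ub=np.inf),
        LinearConstraint(budget, lb=0, ub=params.cost_max),
    ]
    c = np.concatenate([np.zeros(n_a), -np.ones(n_p)])
    res = _run_milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n_a + n_p),
        bounds=Bounds(0, 1),
        params=params,
    )
    if res.x is None:
        lower = ilp_cover(graph, IlpParams(time_limit=params.time_limit))
        bound = None if lower.objective is None else int(lower.objective)
        return SolveResult(
            None,
            None,
            "infeasible",
            solver_log=(
                f"no full cover within cost_max={params.cost_max}; "
                f"minimum cover size (lower bound) is {bound}"
            ),
        )
    chosen = [epitopes[j] for j in np.flatnonzero(res.x[:n_a] > 0.5)]
    solution = score_solution(graph, chosen)
    return SolveResult(
        solution=solution,
        objective=float(round(-res.fun)),
        status=_milp_status(res.status, res.message),
        solver_log=res.message,
    )


BRUTE_FORCE_GUARD = 20


def brute_force_cover(
    graph: CoverGraph, variant: str = "cover", cost_max: Optional[int] = None
) -> SolveResult:
    """Exact optimum by subset enumeration (test oracle; |A| ≤ 20).

    ``cover``/``multicover``: smallest feasible subset, enumerated in size
    order. ``max_multicover``: over all full covers of size ≤ cost_max, the
    maximum count of proteins covered at least twice.
    """
    if variant not in ILP_VARIANTS:
        raise ValueError(f"variant must be one of {ILP_VARIANTS}")
    epitopes = _ordered_epitopes(graph)
    if len(epitopes) > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"brute force refused: |A| = {len(epitopes)} exceeds "
            f"guard {BRUTE_FORCE_GUARD}"
        )
    if not graph.proteins:
        return SolveResult(
            solution=score_solution(graph, []), objective=0.0, status="optimal"
        )
    infeasible = _check_feasible(graph)
    if infeasible is not None:
        return infeasible

    proteins, epitopes, mat = _coverage_matrix(graph)
    dense = np.asarray(mat.todense())
    degrees = dense.sum(axis=1)
    required = np.minimum(degrees, 2) if variant == "multicover" else 1

    if variant in ("cover", "multicover"):
        for size in range(0, len(epitopes) + 1):
            for combo in itertools.combinations(range(len(epitopes)), size):
                counts = dense[:, list(combo)].sum(axis=1)
                if np.all(counts >= required):
                    chosen = [epitopes[j] for j in combo]
                    return SolveResult(
                        solution=score_solution(graph, chosen),
                        objective=float(size),
                        status="optimal",
                    )
        return SolveResult(None, None, "infeasible")

    if cost_max is None:
        raise ValueError("max_multicover requires cost_max")
    best_multi, best_combo = -1, None
    for size in range(0, min(cost_max, len(epitopes)) + 1):
        for combo in itertools.combinations(range(len(epitopes)), size):
            counts = dense[:, list(combo)].sum(axis=1)
            if np.all(counts >= 1):
                multi = int(np.sum(counts >= 2))
                if multi > best_multi:
                    best_multi, best_combo = multi, combo
    if best_combo is None:
        return SolveResult(None, None, "infeasible")
    chosen = [epitopes[j] for j in best_combo]
    return SolveResult(
        solution=score_solution(graph, chosen),
        objective=float(best_multi),
        status="optimal",
    )


def elongation_pairs(selected: Sequence[Epitope]) -> list[tuple[Epitope, Epitope]]:
    """Pairs in a solution where one epitope terminally extends another.

    Enforced multicover tends to admit such pairs (e.g. IER and EIER at a C
    terminus) just to satisfy double-coverage constraints; they are surfaced
    as a warning so a designer can judge whether the redundancy is real.
    """
    pairs = []
    for a, b in itertools.combinations(selected, 2):
        if a.side != b.side:
            continue
        short, long = (a, b) if len(a.sequence) <= len(b.sequence) else (b, a)
        if len(short.sequence) == len(long.sequence):
            continue
        if short.side == "c" and long.sequence.endswith(short.sequence):
            pairs.append((short, long))
        elif short.side == "n" and long.sequence.startswith(short.sequence):
            pairs.append((short, long))
    return pairs


def solve(
    graph: CoverGraph,
    method: str,
    greedy_params: Optional[GreedyParams] = None,
    ilp_params: Optional[IlpParams] = None,
) -> SolveResult:
    """Dispatch by method name: greedy | greedy-mc | ip | ip-mc | ip-mmc."""
    if method == "greedy":
        return greedy_cover(graph)
    if method == "greedy-mc":
        return greedy_multicover(graph, greedy_params)
    if method == "ip":
        return ilp_cover(graph, ilp_params)
    if method == "ip-mc":
        return ilp_multicover(graph, ilp_params)
    if method == "ip-mmc":
        if ilp_params is None or ilp_params.cost_max is None:
            raise ValueError("ip-mmc requires IlpParams with cost_max")
        return ilp_max_multicover(graph, ilp_params)
    raise ValueError(f"unknown method {method!r}")
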