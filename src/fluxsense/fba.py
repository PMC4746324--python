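"""Flux balance analysis: max c'v subject to Sv = 0, LB <= v <= UB.

The objective is the biomass reaction; the LP is solved with the
deterministic HiGHS backend in scipy. Because alternate optima are common
in genome-scale models, :func:`solve_unique` resolves degeneracy with a
parsimonious second stage (minimize total absolute flux at fixed maximal
biomass), making downstream sensitivity coefficients well defined.

:func:`enumerate_optimum` is an exhaustive basic-feasible-solution
reference solver for tiny LPs (<= ~10 columns). It shares no code with the
HiGHS path and exists purely as an independent check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .netcore import MetabolicNetwork, StoichMatrix, build_stoich_matrix

__all__ = [
    "LPProblem",
    "FluxSolution",
    "FBAError",
    "assemble_lp",
    "solve_fba",
    "solve_unique",
    "enumerate_optimum",
]

FEAS_TOL = 1e-9
STEADY_STATE_TOL = 1e-6


class FBAError(RuntimeError):
    pass


@dataclass
class LPProblem:
    """Matrices of the biomass-maximization LP.

    ``c`` has a single 1 at the biomass column; ``reaction_ids`` maps
    columns back to the network.
    """

    S: sparse.csr_matrix
    c: np.ndarray
    LB: np.ndarray
    UB: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    objective_index: int

    def __post_init__(self) -> None:
        n = self.S.shape[1]
        if not (len(self.c) == len(self.LB) == len(self.UB) == n):
            raise FBAError("LP vector dimensions do not match S")
        if int(np.count_nonzero(self.c)) != 1:
            raise FBAError("objective vector must have exactly one nonzero")
        if np.any(self.LB > self.UB):
            raise FBAError("LB > UB for some reaction")


@dataclass
class FluxSolution:
    """One solved condition: fluxes in mmol/gDW/h (biomass in 1/h)."""

    fluxes: dict[str, float]
    objective: float
    status: str  # optimal | infeasible | unbounded

    @property
    def v(self) -> np.ndarray:
        return np.array(list(self.fluxes.values()))


def assemble_lp(net: MetabolicNetwork, matrix: StoichMatrix | None = None) -> LPProblem:
    """Build the LP from a network; the objective column is ``net.objective_id``."""
    if net.objective_id not in net.reactions:
        raise FBAError(f"objective reaction {net.objective_id!r} absent")
    matrix = matrix if matrix is not None else build_stoich_matrix(net)
    reaction_ids = sorted(net.reactions)
    metabolite_ids = sorted(net.metabolites)
    n = len(reaction_ids)
    c = np.zeros(n)
    obj_idx = reaction_ids.index(net.objective_id)
    c[obj_idx] = 1.0
    LB = np.array([net.reactions[r].lb for r in reaction_ids], dtype=float)
    UB = np.array([net.reactions[r].ub for r in reaction_ids], dtype=float)
    return LPProblem(
        S=matrix.to_sparse(),
        c=c,
        LB=LB,
        UB=UB,
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        objective_index=obj_idx,
    )


def _status_name(status_code: int) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(status_code, "failed")


def _run_linprog(c_min, A_eq, b_eq, bounds):
    return linprog(c_min, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")


def solve_fba(lp: LPProblem) -> FluxSolution:
    """Maximize the biomass flux; never silently swallows solver failure."""
    bounds = list(zip(lp.LB, lp.UB))
    res = _run_linprog(-lp.c, lp.S, np.zeros(lp.S.shape[0]), bounds)
    status = _status_name(res.status)
    if status == "optimal":
        v = res.x
        resid = np.abs(lp.S @ v).max() if lp.S.shape[0] else 0.0
        if resid > STEADY_STATE_TOL:
            raise FBAError(f"steady-state residual {resid:.3g} exceeds tolerance")
        fluxes = dict(zip(lp.reaction_ids, v))
        return FluxSolution(fluxes=fluxes, objective=float(-res.fun), status=status)
    return FluxSolution(fluxes={}, objective=float("nan"), status=status)


def solve_unique(lp: LPProblem) -> FluxSolution:
    """Parsimonious optimum: among maximal-biomass flux vectors, minimize sum |v|.

    Stage 1 finds the biomass maximum z*; stage 2 solves
    min sum t_j  s.t.  Sv = 0, c'v = z*, -t <= v <= t, LB <= v <= UB.
    """
    first = solve_fba(lp)
    if first.status != "optimal":
        return first
    z_star = first.objective
    n = lp.S.shape[1]
    m = lp.S.shape[0]
    # variables [v; t]
    c_min = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sparse.hstack([lp.S, sparse.csr_matrix((m, n))]).tocsr()
    A_eq = sparse.vstack([A_eq, sparse.hstack([sparse.csr_matrix(lp.c), sparse.csr_matrix((1, n))])]).tocsr()
    b_eq = np.concatenate([np.zeros(m), [z_star]])
    eye = sparse.eye(n, format="csr")
    # v - t <= 0 and -v - t <= 0
    A_ub = sparse.vstack([sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])]).tocsr()
    b_ub = np.zeros(2 * n)
    t_ub = np.maximum(np.abs(lp.LB), np.abs(lp.UB))
    bounds = list(zip(lp.LB, lp.UB)) + [(0.0, float(t)) for t in t_ub]
    res = linprog(c_min, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        # fixing z* exactly can be borderline-infeasible numerically; retry
        # with a hair of slack on the objective row
        b_eq[-1] = z_star - 1e-9 * max(1.0, abs(z_star))
        res = linprog(c_min, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status != 0:
            raise FBAError(f"parsimonious stage failed: {res.message}")
    v = res.x[:n]
    fluxes = dict(zip(lp.reaction_ids, v))
    return FluxSolution(fluxes=fluxes, objective=z_star, status="optimal")


# ---------------------------------------------------------------------------
# exhaustive reference solver

def enumerate_optimum(lp: LPProblem, atol: float = 1e-9) -> tuple[str, float]:
    """Brute-force optimum over all basic feasible solutions of a tiny LP.

    Enumerates every choice of variables fixed at a finite bound such that
    the remaining columns of S are linearly independent, solves the square
    system, and keeps feasible vertices. All bounds must be finite.
    Returns (status, objective). Intended for n <= ~10 only.
    """
    S = lp.S.toarray()
    m, n = S.shape
    if n > 12:
        raise ValueError("enumeration oracle is for tiny LPs only")
    if not (np.all(np.isfinite(lp.LB)) and np.all(np.isfinite(lp.UB))):
        raise ValueError("enumeration oracle requires finite bounds")
    best = None
    for k in range(n + 1):
        for fixed in itertools.combinations(range(n), n - k):
            free = [j for j in range(n) if j not in fixed]
            S_free = S[:, free]
            if free and np.linalg.matrix_rank(S_free) < len(free):
                continue
            for assignment in itertools.product((0, 1), repeat=len(fixed)):
                v = np.empty(n)
                for j, a in zip(fixed, assignment):
                    v[j] = lp.LB[j] if a == 0 else lp.UB[j]
                if free:
                    rhs = -S[:, list(fixed)] @ v[list(fixed)] if fixed else np.zeros(m)
                    sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                    v[free] = sol
                if np.abs(S @ v).max(initial=0.0) > 1e-7:
                    continue
                if np.any(v < lp.LB - 1e-9) or np.any(v > lp.UB + 1e-9):
                    continue
                obj = float(lp.c @ v)
                if best is None or obj > best:
                    best = obj
    if best is None:
        return "infeasible", float("nan")
    return "optimal", best
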