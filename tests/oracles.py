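"""Independent brute-force oracles used only by the test suite.

The LP oracle enumerates basic feasible solutions (vertices) of the flux
polytope directly from the stoichiometry, with no reliance on the solver
path under test.
"""

from itertools import combinations

import numpy as np

from commassembly.flux import _bounds, stoichiometric_matrix
from commassembly.model import MetabolicModel

_TOL = 1e-8


def _finite_options(lo, hi):
    opts = []
    if lo is not None:
        opts.append(lo)
    if hi is not None and hi != lo:
        opts.append(hi)
    return opts


def enumerate_vertices(A_eq: np.ndarray, b_eq: np.ndarray, bounds) -> list[np.ndarray]:
    """All basic feasible solutions of {A x = b, lb <= x <= ub}.

    Non-basic variables are pinned at a finite bound; the basic block is
    solved exactly and checked for feasibility.
    """
    m, n = A_eq.shape
    r = int(np.linalg.matrix_rank(A_eq))
    lo = [b[0] for b in bounds]
    hi = [b[1] for b in bounds]
    verts = []
    for basic in combinations(range(n), r):
        nonbasic = [j for j in range(n) if j not in basic]
        opts = [_finite_options(lo[j], hi[j]) for j in nonbasic]
        if any(not o for o in opts):
            continue
        B = A_eq[:, basic]
        if np.linalg.matrix_rank(B) < r:
            continue
        stack = [[]]
        for o in opts:
            stack = [s + [v] for s in stack for v in o]
        for fixed in stack:
            x = np.zeros(n)
            x[nonbasic] = fixed
            rhs = b_eq - A_eq[:, nonbasic] @ np.asarray(fixed)
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            x[np.asarray(basic)] = sol
            if np.max(np.abs(A_eq @ x - b_eq)) > _TOL:
                continue
            ok = True
            for j in range(n):
                if lo[j] is not None and x[j] < lo[j] - _TOL:
                    ok = False
                    break
                if hi[j] is not None and x[j] > hi[j] + _TOL:
                    ok = False
                    break
            if ok:
                verts.append(x)
    return verts


def oracle_fba_objective(model: MetabolicModel) -> float:
    """Max biomass flux by exhaustive vertex enumeration."""
    S = stoichiometric_matrix(model)
    verts = enumerate_vertices(S, np.zeros(S.shape[0]), _bounds(model))
    assert verts, "oracle found no feasible vertex"
    j = model.reaction_index[model.objective_id]
    return max(v[j] for v in verts)


def oracle_min_l1_at_optimum(model: MetabolicModel, optimum: float) -> float:
    """Min total absolute flux over {S v = 0, bounds, v_obj = optimum},
    via vertex enumeration in the forward/reverse-split space (where the
    L1 objective is linear, so the optimum sits at a vertex)."""
    S = stoichiometric_matrix(model)
    m, n = S.shape
    A = np.hstack([S, -S])
    obj_row = np.zeros(2 * n)
    j = model.reaction_index[model.objective_id]
    obj_row[j] = 1.0
    obj_row[n + j] = -1.0
    A_eq = np.vstack([A, obj_row])
    b_eq = np.concatenate([np.zeros(m), [optimum]])
    bounds = []
    for lo, hi in _bounds(model):
        bounds.append((0.0, hi if hi is None or hi > 0 else 0.0))
    for lo, hi in _bounds(model):
        bounds.append((0.0, None if lo is None else max(-lo, 0.0)))
    verts = enumerate_vertices(A_eq, b_eq, bounds)
    assert verts, "oracle found no feasible vertex at the optimum"
    return min(float(np.sum(v)) for v in verts)
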