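"""Flux balance analysis and the metabolic-similarity metric.

FBA maximizes biomass flux subject to steady state (S v = 0) and reaction
bounds.  Parsimonious FBA (pFBA) then fixes the biomass optimum and
minimizes total absolute flux by splitting each reaction into forward and
reverse non-negative components, which removes futile cycles and most
degenerate alternate optima.  Metabolic similarity between two growth
environments is the Pearson correlation between their intracellular
(internal-reaction) flux vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import linprog

from .errors import ConfigurationError, SolverError
from .model import (
    BOUND_INF,
    EnvironmentSpec,
    MetabolicModel,
    ReactionKind,
    apply_environment,
)

#: relative tolerance with which pFBA holds the stage-1 optimum
PFBA_OPTIMUM_RTOL = 1e-9
#: minimum biomass flux counted as growth
GROWTH_TOL = 1e-8


class SolverStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


@dataclass
class FluxSolution:
    status: SolverStatus
    objective_value: float
    fluxes: dict[str, float]


@dataclass
class InternalFluxVector:
    environment_label: str
    reaction_ids: list[str]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.reaction_ids, self.values.tolist()))


@dataclass
class MetabolicSimilarityMatrix:
    labels: list[str]
    values: np.ndarray

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


def _solver_bound(b: float) -> float | None:
    """Map the file sentinel (+-1000) onto a true infinity for the LP."""
    if abs(b) >= BOUND_INF:
        return None
    return b


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    met_idx = model.metabolite_index
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry.items():
            S[met_idx[met], j] = coeff
    return S


def _bounds(model: MetabolicModel) -> list[tuple[float | None, float | None]]:
    return [
        (_solver_bound(r.lower_bound), _solver_bound(r.upper_bound))
        for r in model.reactions
    ]


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize biomass flux at steady state; never a silent zero.

    Infeasibility and unboundedness are reported in ``status``, with
    objective 0 and empty fluxes.
    """
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_index[model.objective_id]] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=_bounds(model),
        method="highs",
    )
    if res.status == 2:
        return FluxSolution(SolverStatus.INFEASIBLE, 0.0, {})
    if res.status == 3:
        return FluxSolution(SolverStatus.UNBOUNDED, 0.0, {})
    if not res.success:  # pragma: no cover - defensive
        raise SolverError(f"FBA solver failure: {res.message}")
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(SolverStatus.OPTIMAL, float(-res.fun), fluxes)


def pfba(model: MetabolicModel, optimum_fraction: float = 1.0) -> FluxSolution:
    """Parsimonious FBA: hold the FBA optimum, minimize total absolute flux.

    Each reaction is split as v = v+ - v- with v+, v- >= 0 and the LP
    minimizes sum(v+ + v-) subject to S v = 0, the original bounds, and
    objective >= optimum_fraction * (FBA optimum) (up to a 1e-9 relative
    slack).  Variable ordering is fixed by model order, so the HiGHS
    solution is reproducible.
    """
    stage1 = fba(model)
    if stage1.status is not SolverStatus.OPTIMAL:
        return stage1
    target = optimum_fraction * stage1.objective_value
    S = stoichiometric_matrix(model)
    m, n = S.shape
    # columns: [v+ (n), v- (n)]
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    bounds: list[tuple[float, float | None]] = []
    for lo, hi in _bounds(model):
        bounds.append((0.0, hi if hi is None or hi > 0 else 0.0))
    for lo, hi in _bounds(model):
        neg_cap = None if lo is None else max(-lo, 0.0)
        bounds.append((0.0, neg_cap))
    c = np.ones(2 * n)
    obj_row = np.zeros(2 * n)
    j = model.reaction_index[model.objective_id]
    obj_row[j] = -1.0
    obj_row[n + j] = 1.0
    # -objective <= -target (1 - rtol)
    A_ub = obj_row[None, :]
    b_ub = np.array([-target * (1.0 - PFBA_OPTIMUM_RTOL) if target >= 0 else -target])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return FluxSolution(SolverStatus.INFEASIBLE, 0.0, {})
    if not res.success:  # pragma: no cover - defensive
        raise SolverError(f"pFBA solver failure: {res.message}")
    net = res.x[:n] - res.x[n:]
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, net)}
    return FluxSolution(SolverStatus.OPTIMAL, fluxes[model.objective_id], fluxes)


def internal_flux_vector(solution: FluxSolution, model: MetabolicModel) -> InternalFluxVector:
    """Project a flux solution onto the internal reactions, in model order.

    Transporters, exchanges, the biomass objective and maintenance
    reactions are all excluded, leaving the intracellular metabolic fluxes.
    """
    if solution.status is not SolverStatus.OPTIMAL:
        raise SolverError(
            f"cannot extract internal fluxes from a {solution.status.value} solution"
        )
    ids = [r.id for r in model.reactions if r.kind is ReactionKind.INTERNAL]
    values = np.array([solution.fluxes[i] for i in ids])
    return InternalFluxVector(environment_label="", reaction_ids=ids, values=values)


def environment_flux_vectors(
    model: MetabolicModel,
    environments: list[EnvironmentSpec],
    use_pfba: bool = True,
) -> list[InternalFluxVector]:
    """Solve each environment and return its internal flux vector.

    Raises if any environment fails to grow — the analysis assumes the
    model has been curated to grow on every substrate considered.
    """
    vectors = []
    for env in environments:
        bounded = apply_environment(model, env)
        sol = pfba(bounded) if use_pfba else fba(bounded)
        if sol.status is not SolverStatus.OPTIMAL or sol.objective_value <= GROWTH_TOL:
            raise SolverError(
                f"no growth on substrate {env.label!r} "
                f"(status={sol.status.value}, objective={sol.objective_value:g})"
            )
        vec = internal_flux_vector(sol, model)
        vec.environment_label = env.label
        vectors.append(vec)
    return vectors


def metabolic_similarity(
    model: MetabolicModel,
    environments: list[EnvironmentSpec],
    use_pfba: bool = True,
) -> MetabolicSimilarityMatrix:
    """Environment x environment Pearson correlation of internal flux vectors.

    The correlation is computed over the full internal-reaction vector,
    zero fluxes included.  An environment whose internal vector has zero
    variance yields NaN entries (flagged, not silently dropped).
    """
    vectors = environment_flux_vectors(model, environments, use_pfba=use_pfba)
    labels = [v.environment_label for v in vectors]
    X = np.array([v.values for v in vectors])
    k = len(labels)
    sims = np.full((k, k), np.nan)
    sd = X.std(axis=1)
    for i in range(k):
        for j in range(i, k):
            if sd[i] == 0 or sd[j] == 0:
                continue
            xi = X[i] - X[i].mean()
            xj = X[j] - X[j].mean()
            r = float(xi @ xj / math.sqrt((xi @ xi) * (xj @ xj)))
            sims[i, j] = sims[j, i] = min(1.0, max(-1.0, r))
    return MetabolicSimilarityMatrix(labels=labels, values=sims)


def mixture_environment(
    exchange_ids: list[str],
    total_uptake: float = 1.0,
    convention: str = "equal_split",
    label: str | None = None,
    free_exchanges: set[str] | None = None,
) -> EnvironmentSpec:
    """Environment supplying several carbon sources at once.

    ``equal_split`` divides a fixed total carbon uptake equally among the k
    sources (total carbon concentration held constant across environments).
    ``paper_printed`` reproduces the historically quoted per-source bounds:
    -1 per source for pairs and -0.033 per source for triplets, a
    convention that does not conserve total carbon but is kept available
    for comparison.
    """
    if len(exchange_ids) < 2:
        raise ConfigurationError("a mixture needs at least two carbon sources")
    if len(set(exchange_ids)) != len(exchange_ids):
        raise ConfigurationError(f"duplicate exchange ids in mixture: {exchange_ids}")
    k = len(exchange_ids)
    if convention == "equal_split":
        per_source = -total_uptake / k
    elif convention == "paper_printed":
        if k == 2:
            per_source = -1.0
        elif k == 3:
            per_source = -0.033
        else:
            raise ConfigurationError(
                "printed mixture bounds are only defined for pairs and triplets"
            )
    else:
        raise ConfigurationError(f"unknown mixture convention {convention!r}")
    return EnvironmentSpec(
        label=label or "+".join(exchange_ids),
        carbon_uptakes={ex: per_source for ex in exchange_ids},
        free_exchanges=free_exchanges or set(),
    )
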