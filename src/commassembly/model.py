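"""Constraint-based metabolic models and growth-environment configuration.

A model is a stoichiometric network whose reactions are classed as
``exchange`` (boundary uptake/secretion of a single extracellular
metabolite), ``transport`` (crossing compartments), ``biomass`` (the growth
objective), ``maintenance`` (growth-independent ATP hydrolysis, explicitly
annotated), or ``internal`` (everything else).  Environments are expressed
as carbon-normalized uptake bounds on exchange reactions so that every
substrate is supplied at equal carbon flux.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .errors import ConfigurationError, FormatError, ValidationError

#: File encoding of "unbounded"; the solver layer treats any bound with
#: magnitude >= BOUND_INF as infinite.
BOUND_INF = 1000.0


class ReactionKind(str, Enum):
    INTERNAL = "internal"
    EXCHANGE = "exchange"
    TRANSPORT = "transport"
    BIOMASS = "biomass"
    MAINTENANCE = "maintenance"


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ValidationError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    kind: ReactionKind | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: stoichiometry must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if isinstance(self.kind, str):
            self.kind = ReactionKind(self.kind)


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValidationError("model has an empty reaction list")
        if not self.metabolites:
            raise ValidationError("model has an empty metabolite list")
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ValidationError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise ValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolites: {sorted(unknown)}"
                )
        if self.objective_id not in set(rxn_ids):
            raise ValidationError(f"objective {self.objective_id!r} is not a reaction")
        # classification fills in any kinds left unannotated, then the
        # objective must come out as biomass
        kinds = classify_reactions(self)
        for rxn in self.reactions:
            rxn.kind = kinds[rxn.id]
        if kinds[self.objective_id] is not ReactionKind.BIOMASS:
            raise ValidationError(
                f"objective {self.objective_id!r} is not a biomass reaction"
            )
        for rxn in self.reactions:
            if rxn.kind is ReactionKind.EXCHANGE and len(rxn.stoichiometry) != 1:
                raise ValidationError(
                    f"exchange reaction {rxn.id!r} must touch exactly one metabolite"
                )

    # -- convenience accessors -------------------------------------------------

    def reaction(self, rxn_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rxn_id:
                return rxn
        raise KeyError(rxn_id)

    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def reactions_of_kind(self, kind: ReactionKind) -> list[Reaction]:
        return [r for r in self.reactions if r.kind is kind]

    @property
    def exchanges(self) -> list[Reaction]:
        return self.reactions_of_kind(ReactionKind.EXCHANGE)

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)


@dataclass
class EnvironmentSpec:
    """Growth environment: carbon uptake bounds plus freely available exchanges.

    ``carbon_uptakes`` maps exchange-reaction ids to (negative) uptake
    bounds in carbon-normalized flux units; the default convention supplies
    each single substrate at -1 cmol/gDW/h.  ``free_exchanges`` (trace
    elements, oxygen, ...) are left unbounded below.  The maintenance lower
    bound defaults to 0, i.e. growth-independent maintenance is neglected
    when resources are in excess.
    """

    label: str
    carbon_uptakes: dict[str, float]
    free_exchanges: set[str] = field(default_factory=set)
    maintenance_lower_bound: float = 0.0

    def __post_init__(self) -> None:
        self.free_exchanges = set(self.free_exchanges)
        for rxn_id, bound in self.carbon_uptakes.items():
            if not bound < 0:
                raise ConfigurationError(
                    f"environment {self.label!r}: carbon uptake bound for "
                    f"{rxn_id!r} must be negative, got {bound}"
                )
        overlap = set(self.carbon_uptakes) & self.free_exchanges
        if overlap:
            raise ConfigurationError(
                f"environment {self.label!r}: exchanges {sorted(overlap)} listed "
                "both as carbon uptakes and free exchanges"
            )


def classify_reactions(model: MetabolicModel) -> dict[str, ReactionKind]:
    """Assign every reaction exactly one kind.

    An explicit annotation on the reaction wins.  Otherwise: the objective
    is biomass; a reaction touching exactly one metabolite is an exchange;
    a reaction whose metabolites span >= 2 compartments is a transporter;
    everything else is internal.  Maintenance is never inferred — it must
    be annotated in the file.
    """
    compartments = {m.id: m.compartment for m in model.metabolites}
    kinds: dict[str, ReactionKind] = {}
    for rxn in model.reactions:
        if rxn.id == model.objective_id and rxn.kind is None:
            kinds[rxn.id] = ReactionKind.BIOMASS
        elif rxn.kind is not None:
            kinds[rxn.id] = rxn.kind
        elif len(rxn.stoichiometry) == 1:
            kinds[rxn.id] = ReactionKind.EXCHANGE
        elif len({compartments[m] for m in rxn.stoichiometry}) >= 2:
            kinds[rxn.id] = ReactionKind.TRANSPORT
        else:
            kinds[rxn.id] = ReactionKind.INTERNAL
    return kinds


def apply_environment(model: MetabolicModel, env: EnvironmentSpec) -> MetabolicModel:
    """Return a copy of ``model`` bounded for growth in ``env``.

    Carbon exchanges named in the environment get their uptake bound as the
    exchange lower bound; free exchanges are opened to the unbounded
    sentinel; every other exchange is closed below (no uptake).  Maintenance
    reactions get the environment's maintenance lower bound.  The input
    model is not modified.
    """
    exchange_ids = {r.id for r in model.exchanges}
    named = set(env.carbon_uptakes) | env.free_exchanges
    unknown = named - exchange_ids
    if unknown:
        raise ConfigurationError(
            f"environment {env.label!r} names unknown exchange reactions: {sorted(unknown)}"
        )
    bounded = model.copy()
    for rxn in bounded.reactions:
        if rxn.kind is ReactionKind.EXCHANGE:
            if rxn.id in env.carbon_uptakes:
                rxn.lower_bound = env.carbon_uptakes[rxn.id]
            elif rxn.id in env.free_exchanges:
                rxn.lower_bound = -BOUND_INF
            else:
                rxn.lower_bound = 0.0
        elif rxn.kind is ReactionKind.MAINTENANCE:
            rxn.lower_bound = env.maintenance_lower_bound
    return bounded


# -- serialisation -------------------------------------------------------------


def read_model(path, dialect: str = "json") -> MetabolicModel:
    """Load a metabolic model from a JSON (or SBML L3/FBC) file.

    The JSON layout follows the community constraint-based convention:
    ``metabolites: [{id, compartment}]``, ``reactions: [{id, metabolites,
    lower_bound, upper_bound, kind?}]`` and a top-level ``objective``.
    """
    if dialect == "json":
        try:
            with open(path) as fh:
                raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        return _model_from_dict(raw, source=str(path))
    if dialect == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _model_from_dict(raw: Mapping, source: str = "<dict>") -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(id=m["id"], compartment=m["compartment"])
            for m in raw["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                kind=ReactionKind(r["kind"]) if r.get("kind") else None,
            )
            for r in raw["reactions"]
        ]
        objective = raw["objective"]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{source}: malformed model record ({exc!r})") from exc
    return MetabolicModel(metabolites=metabolites, reactions=reactions, objective_id=objective)


def write_model(model: MetabolicModel, path) -> None:
    raw = {
        "metabolites": [{"id": m.id, "compartment": m.compartment} for m in model.metabolites],
        "reactions": [
            {
                "id": r.id,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "kind": r.kind.value if r.kind else None,
            }
            for r in model.reactions
        ],
        "objective": model.objective_id,
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1, sort_keys=False)
        fh.write("\n")


def _read_sbml(path) -> MetabolicModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise FormatError("SBML import requires the optional cobra dependency") from exc
    cm = cobra.io.read_sbml_model(str(path))
    metabolites = [Metabolite(id=m.id, compartment=m.compartment or "c") for m in cm.metabolites]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coeff for m, coeff in r.metabolites.items()},
            lower_bound=_clip_bound(r.lower_bound),
            upper_bound=_clip_bound(r.upper_bound),
        )
        for r in cm.reactions
    ]
    objective = _sbml_objective_id(cm)
    return MetabolicModel(metabolites=metabolites, reactions=reactions, objective_id=objective)


def _clip_bound(b: float) -> float:
    if math.isinf(b):
        return math.copysign(BOUND_INF, b)
    return float(b)


def _sbml_objective_id(cm) -> str:
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            return rxn.id
    raise FormatError("SBML model declares no objective reaction")
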