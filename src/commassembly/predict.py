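"""Nearest-template prediction of community composition in new environments.

The comparative approach predicts the community assembling on a target
carbon source to be the community observed on the most metabolically
similar *non-identical* template carbon source — a nearest-neighbour
classifier with metabolic similarity as the distance in flux space.
Performance is the Renkonen similarity between the predicted and observed
composition; the null model is the exhaustive distribution of Renkonen
similarities over all non-identical (target, template) substrate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import renkonen
from .errors import AnalysisError, ConfigurationError
from .flux import (
    GROWTH_TOL,
    MetabolicSimilarityMatrix,
    SolverStatus,
    internal_flux_vector,
    pfba,
)
from .model import EnvironmentSpec, MetabolicModel, apply_environment
from .stats import MannWhitneyResult, mann_whitney_one_tailed


@dataclass
class TemplateLibrary:
    """Observed relative-abundance profiles, one per carbon source, for a
    single inoculum at one taxonomic level."""

    inoculum: str
    profiles: pd.DataFrame  # index carbon_source, columns taxa, rows sum to 1
    level: str = "ESV"

    def __post_init__(self) -> None:
        sums = self.profiles.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AnalysisError(
                f"library {self.inoculum!r}: profiles must be normalized to 1"
            )
        if self.profiles.index.duplicated().any():
            raise AnalysisError(
                f"library {self.inoculum!r}: one profile per carbon source required"
            )

    @property
    def substrates(self) -> list[str]:
        return list(self.profiles.index)


@dataclass
class PredictionResult:
    target: str
    template: str
    similarity: float
    predicted: pd.Series
    observed: pd.Series | None
    performance: float | None


@dataclass
class NullDistribution:
    values: np.ndarray
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def _aligned_renkonen(x: pd.Series, y: pd.Series) -> float:
    taxa = sorted(set(x.index) | set(y.index))
    return renkonen(
        x.reindex(taxa, fill_value=0.0).to_numpy(),
        y.reindex(taxa, fill_value=0.0).to_numpy(),
    )


def nearest_template(
    target: str,
    library: TemplateLibrary,
    sim: MetabolicSimilarityMatrix,
    exclude: set[str] | None = None,
) -> tuple[str, float]:
    """Most metabolically similar non-identical template substrate.

    Ties break to the lexicographically smallest label, keeping
    leave-one-out runs deterministic.
    """
    if target not in sim.labels:
        raise AnalysisError(f"target {target!r} absent from the similarity matrix")
    banned = {target} | (exclude or set())
    candidates = [
        s for s in library.substrates if s not in banned and s in sim.labels
    ]
    if not candidates:
        raise AnalysisError(f"no admissible template for target {target!r}")
    best = min(candidates, key=lambda s: (-sim.loc(target, s), s))
    return best, sim.loc(target, best)


def loco_predict(
    targets: TemplateLibrary,
    templates: TemplateLibrary,
    sim: MetabolicSimilarityMatrix,
) -> list[PredictionResult]:
    """Leave-one-carbon-source-out predictions of every target substrate.

    For each substrate in the target library, the composition is predicted
    from the nearest non-identical template (same- or cross-inoculum) and
    scored by Renkonen similarity against the observed composition.
    Targets without a usable template are skipped.
    """
    results = []
    for target in targets.substrates:
        if target not in sim.labels:
            continue
        try:
            template, similarity = nearest_template(target, templates, sim)
        except AnalysisError:
            continue
        predicted = templates.profiles.loc[template]
        observed = targets.profiles.loc[target]
        results.append(
            PredictionResult(
                target=target,
                template=template,
                similarity=similarity,
                predicted=predicted,
                observed=observed,
                performance=_aligned_renkonen(predicted, observed),
            )
        )
    return results


def null_performance(
    targets: TemplateLibrary, templates: TemplateLibrary
) -> NullDistribution:
    """Exhaustive null: Renkonen similarity between every non-identical
    (target, template) substrate pair across the two libraries."""
    values = []
    pairs = []
    for target in targets.substrates:
        observed = targets.profiles.loc[target]
        for template in templates.substrates:
            if template == target:
                continue
            values.append(_aligned_renkonen(templates.profiles.loc[template], observed))
            pairs.append((target, template))
    return NullDistribution(values=np.array(values), pairs=pairs)


def compare_to_null(
    results: list[PredictionResult], null: NullDistribution
) -> dict:
    """One-tailed Mann-Whitney comparison of prediction performances to the
    null distribution (predictions greater)."""
    perf = np.array([r.performance for r in results if r.performance is not None])
    if perf.size == 0 or null.values.size == 0:
        raise AnalysisError("need non-empty prediction and null distributions")
    mw: MannWhitneyResult = mann_whitney_one_tailed(perf, null.values)
    return {
        "median_pred": float(np.median(perf)),
        "median_null": null.median,
        "U": mw.U,
        "p": mw.p,
        "n_pred": int(perf.size),
        "n_null": int(null.values.size),
    }


def predict_mixture(
    mixture: EnvironmentSpec,
    singles: TemplateLibrary,
    model: MetabolicModel,
    single_envs: list[EnvironmentSpec],
    observed: pd.Series | None = None,
    component_substrates: dict[str, str] | None = None,
) -> PredictionResult:
    """Predict composition on a nutrient mixture from single-substrate
    template communities.

    The mixture's internal flux vector (pFBA) is correlated against each
    single-substrate flux vector; the carbon sources contained in the
    mixture are excluded as templates; the nearest remaining template's
    composition is the prediction.  ``component_substrates`` maps the
    mixture's exchange-reaction ids to substrate labels (defaults to the
    environment labels of ``single_envs`` whose uptakes overlap the
    mixture's).  With no observed composition the prediction is returned
    with performance unset.
    """
    if len(mixture.carbon_uptakes) < 2:
        raise ConfigurationError("a mixture environment needs >= 2 carbon sources")
    if component_substrates is None:
        component_substrates = {}
        for env in single_envs:
            if set(env.carbon_uptakes) & set(mixture.carbon_uptakes):
                for ex in env.carbon_uptakes:
                    component_substrates[ex] = env.label
    components = {
        component_substrates[ex]
        for ex in mixture.carbon_uptakes
        if ex in component_substrates
    }

    def flux_vec(env: EnvironmentSpec) -> np.ndarray:
        sol = pfba(apply_environment(model, env))
        if sol.status is not SolverStatus.OPTIMAL or sol.objective_value <= GROWTH_TOL:
            raise AnalysisError(f"no growth in environment {env.label!r}")
        return internal_flux_vector(sol, model).values

    v_mix = flux_vec(mixture)
    sims = {}
    for env in single_envs:
        v = flux_vec(env)
        if v.std() == 0 or v_mix.std() == 0:
            continue
        sims[env.label] = float(np.corrcoef(v_mix, v)[0, 1])
    candidates = [
        s
        for s in singles.substrates
        if s in sims and s not in components
    ]
    if not candidates:
        raise AnalysisError(
            f"no admissible template for mixture {mixture.label!r} after "
            f"excluding components {sorted(components)}"
        )
    template = min(candidates, key=lambda s: (-sims[s], s))
    predicted = singles.profiles.loc[template]
    performance = None if observed is None else _aligned_renkonen(predicted, observed)
    return PredictionResult(
        target=mixture.label,
        template=template,
        similarity=sims[template],
        predicted=predicted,
        observed=observed,
        performance=performance,
    )


def library_from_table(ct, inoculum: str) -> TemplateLibrary:
    """Build a template library from a (rarefied, aggregated) community
    table, keeping one sample per carbon source for the given inoculum."""
    rel = ct.to_relative()
    mask = rel.meta["inoculum"] == inoculum
    sub = rel.counts[mask.to_numpy()]
    sources = rel.meta.loc[mask, "carbon_source"]
    if sources.duplicated().any():
        raise AnalysisError(
            f"inoculum {inoculum!r} has multiple samples per carbon source; "
            "subset to one (e.g. a chosen replicate) first"
        )
    profiles = sub.set_index(sources)
    return TemplateLibrary(inoculum=inoculum, profiles=profiles, level=ct.level)
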