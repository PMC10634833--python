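"""Synthetic inputs with the planted statistical structure the analysis assumes.

Four generators mirror the four input classes of the study design:

* toy constraint-based models (a fixed hand-checkable fixture plus seeded
  branched networks guaranteed to grow on every substrate);
* OD growth curves whose true rates follow a clade-structured gradient
  along metabolic similarity to a reference substrate;
* metabolomics peak tables with block-structured secretions and
  control-contaminated peaks;
* community count tables generated by softmax selection on flux-determined
  fitness, with inoculum dropout/jitter and multinomial read sampling.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import (
    CommunityTable,
    TaxonomyMap,
)
from .errors import ValidationError
from .flux import environment_flux_vectors
from .growth import E_PLUS, P_PLUS, GrowthCurve
from .model import (
    EnvironmentSpec,
    Metabolite,
    MetabolicModel,
    Reaction,
    ReactionKind,
)
from .secretions import PeakTable


@dataclass
class GeneratorConfig:
    """Study-scale knobs for the synthetic generators.

    Defaults mirror the study conditions: 62 strains phenotyped on 19
    carbon sources, 3 inocula, amplicon tables rarefied to 2733 reads,
    5% multiplicative OD noise, and a clade rate gap of 0.3/hr (about the
    spread between fast fermenters and slow respirators on sugars).
    """

    seed: int = 0
    n_strains: int = 62
    n_substrates: int = 19
    n_inocula: int = 3
    n_taxa: int = 48
    clade_effect: float = 0.3
    inoculum_sd: float = 0.3
    noise_sd: float = 0.05
    read_depth: int = 2733

    def __post_init__(self) -> None:
        for name in ("n_strains", "n_substrates", "n_inocula", "n_taxa"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        if self.clade_effect < 0 or self.inoculum_sd < 0 or self.noise_sd < 0:
            raise ValidationError("effect sizes and noise sds must be >= 0")
        if self.read_depth < 100:
            raise ValidationError("read_depth must be >= 100")


# ---------------------------------------------------------------------------
# toy metabolic models
# ---------------------------------------------------------------------------

def make_toy_model(
    variant: str = "T1", k: int = 5, seed: int = 0
) -> tuple[MetabolicModel, list[EnvironmentSpec]]:
    """Toy models with known optima.

    ``T1`` is the fixed fixture: substrates A, C and D, where D enters the
    cytosol at A's node (so A and D have identical internal fluxes) while C
    uses its own entry pathway.  ``T1_futile`` adds a futile cycle that
    plain FBA may carry but pFBA must zero out.  ``branched`` is a seeded
    random network: a linear backbone with ``k`` substrate entry points and
    random shortcut reactions, feasible on every substrate by construction.
    """
    if variant in ("T1", "T1_futile"):
        return _t1_model(futile=variant == "T1_futile")
    if variant == "branched":
        return _branched_model(k=k, seed=seed)
    raise ValidationError(f"unknown toy-model variant {variant!r}")


def _t1_model(futile: bool = False) -> tuple[MetabolicModel, list[EnvironmentSpec]]:
    mets = [
        Metabolite("A_e", "e"),
        Metabolite("C_e", "e"),
        Metabolite("D_e", "e"),
        Metabolite("A_c", "c"),
        Metabolite("C_c", "c"),
        Metabolite("B_c", "c"),
        Metabolite("P_c", "c"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, -1000.0, 1000.0),
        Reaction("EX_C", {"C_e": -1.0}, -1000.0, 1000.0),
        Reaction("EX_D", {"D_e": -1.0}, -1000.0, 1000.0),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
        Reaction("T_C", {"C_e": -1.0, "C_c": 1.0}, 0.0, 1000.0),
        Reaction("T_D", {"D_e": -1.0, "A_c": 1.0}, 0.0, 1000.0),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
        Reaction("R3", {"C_c": -1.0, "B_c": 1.0}, 0.0, 1000.0),
        Reaction("R0", {"B_c": -1.0, "P_c": 1.0}, 0.0, 1000.0),
        Reaction("GROWTH", {"P_c": -1.0}, 0.0, 1000.0),
        Reaction("ATPM", {"P_c": -1.0}, 0.0, 1000.0, kind=ReactionKind.MAINTENANCE),
    ]
    if futile:
        rxns.append(Reaction("R_f", {"B_c": -1.0, "A_c": 1.0}, 0.0, 1000.0))
    model = MetabolicModel(metabolites=mets, reactions=rxns, objective_id="GROWTH")
    envs = [
        EnvironmentSpec(label="A", carbon_uptakes={"EX_A": -1.0}),
        EnvironmentSpec(label="C", carbon_uptakes={"EX_C": -1.0}),
        EnvironmentSpec(label="D", carbon_uptakes={"EX_D": -1.0}),
    ]
    return model, envs


def _branched_model(k: int, seed: int) -> tuple[MetabolicModel, list[EnvironmentSpec]]:
    rng = np.random.default_rng(seed)
    backbone_len = max(6, k // 3 + 4)
    mets = [Metabolite(f"M{i}_c", "c") for i in range(backbone_len)]
    mets.append(Metabolite("BIO_c", "c"))
    rxns = [
        Reaction(f"B{i}", {f"M{i}_c": -1.0, f"M{i+1}_c": 1.0}, 0.0, 1000.0)
        for i in range(backbone_len - 1)
    ]
    rxns.append(
        Reaction(
            f"B{backbone_len - 1}",
            {f"M{backbone_len - 1}_c": -1.0, "BIO_c": 1.0},
            0.0,
            1000.0,
        )
    )
    # a few random forward shortcuts so flux routes differ between entries
    n_short = max(2, backbone_len // 2)
    for s in range(n_short):
        i = int(rng.integers(0, backbone_len - 2))
        j = int(rng.integers(i + 2, backbone_len))
        rxns.append(Reaction(f"S{s}_{i}_{j}", {f"M{i}_c": -1.0, f"M{j}_c": 1.0}, 0.0, 1000.0))
    envs = []
    for s in range(k):
        sub = f"sub{s:02d}"
        entry = int(rng.integers(0, backbone_len - 1))
        mets.append(Metabolite(f"{sub}_e", "e"))
        rxns.append(Reaction(f"EX_{sub}", {f"{sub}_e": -1.0}, -1000.0, 1000.0))
        rxns.append(
            Reaction(f"T_{sub}", {f"{sub}_e": -1.0, f"M{entry}_c": 1.0}, 0.0, 1000.0)
        )
        envs.append(EnvironmentSpec(label=sub, carbon_uptakes={f"EX_{sub}": -1.0}))
    rxns.append(Reaction("GROWTH", {"BIO_c": -1.0}, 0.0, 1000.0))
    model = MetabolicModel(metabolites=mets, reactions=rxns, objective_id="GROWTH")
    return model, envs


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

def _clades_for_strains(n_strains: int) -> list[str]:
    # two-thirds fermenters, one-third respirators, echoing the 40/20 split
    # of the isolate library
    n_e = int(round(n_strains * 2 / 3))
    return [E_PLUS] * n_e + [P_PLUS] * (n_strains - n_e)


def _lagged_logistic(t: np.ndarray, rate: float, lag: float, n0: float, kcap: float) -> np.ndarray:
    out = np.full_like(t, n0, dtype=float)
    grow = t > lag
    out[grow] = kcap / (1.0 + (kcap - n0) / n0 * np.exp(-rate * (t[grow] - lag)))
    return out


def simulate_growth_curves(
    cfg: GeneratorConfig,
    sim_labels: list[str],
    sim_values: np.ndarray,
    reference: str | None = None,
    n_replicates: int = 1,
) -> tuple[list[GrowthCurve], pd.DataFrame, dict[str, dict]]:
    """Clade-structured growth curves along the similarity gradient.

    True rate of strain i on substrate a:

        r_ia = base + sign(clade_i) * clade_effect * sim(a, reference)
               + strain effect + noise,  truncated at 0.01/hr,

    so fermenter-clade strains speed up and respirator-clade strains slow
    down with similarity to the reference substrate.  Curves are lagged
    logistics on a 30-minute grid over 48 h with multiplicative OD noise.
    Returns (curves, true-rate matrix, strain annotations).
    """
    rng = np.random.default_rng(cfg.seed)
    reference = reference or sim_labels[0]
    ref_i = sim_labels.index(reference)
    substrates = list(sim_labels)[: cfg.n_substrates]
    strains = [f"strain{i:03d}" for i in range(cfg.n_strains)]
    clades = _clades_for_strains(cfg.n_strains)
    annotations = {
        s: {"clade": c, "family": "Enterobacteriaceae" if c == E_PLUS else "Pseudomonadaceae"}
        for s, c in zip(strains, clades)
    }
    base = 0.45
    strain_effect = rng.normal(0.0, 0.05, size=cfg.n_strains)
    times = np.arange(0.0, 48.0 + 1e-9, 0.5)
    # preconditioned cultures: lags are short, mostly inside the discarded
    # startup window, so the average-rate estimator can recover the true rate
    curves: list[GrowthCurve] = []
    true = pd.DataFrame(index=strains, columns=substrates, dtype=float)
    for i, strain in enumerate(strains):
        sign = 1.0 if clades[i] == E_PLUS else -1.0
        lag = float(rng.uniform(0.25, 1.25))
        for sub in substrates:
            s = float(sim_values[ref_i, sim_labels.index(sub)])
            rate = base + sign * cfg.clade_effect * s + strain_effect[i]
            rate += float(rng.normal(0.0, cfg.noise_sd * 0.2))
            rate = max(rate, 0.01)
            true.loc[strain, sub] = rate
            for rep in range(1, n_replicates + 1):
                od = _lagged_logistic(times, rate, lag, n0=0.002, kcap=0.8)
                if cfg.noise_sd > 0:
                    od = od * rng.lognormal(0.0, cfg.noise_sd, size=times.size)
                curves.append(
                    GrowthCurve(
                        strain_id=strain,
                        carbon_source=sub,
                        replicate=rep,
                        times=times.copy(),
                        od=od,
                    )
                )
    return curves, true, annotations


# ---------------------------------------------------------------------------
# metabolomics peak tables
# ---------------------------------------------------------------------------

def simulate_peak_table(
    cfg: GeneratorConfig,
    block_structure: dict[str, int] | None = None,
    n_metabolites: int = 69,
    n_contaminated: int = 14,
    n_replicates: int = 3,
    strain: str = "strainK",
) -> PeakTable:
    """Peak table with block-structured secretions and contaminated controls.

    ``n_contaminated`` of the ``n_metabolites`` annotated peaks carry
    significant background signal in the no-carbon-source controls (so the
    default table retains 55 after control filtering).  Substrates are
    grouped into secretion blocks; each block secretes its own
    characteristic subset of the clean metabolites with log-normal heights.
    """
    rng = np.random.default_rng(cfg.seed)
    if block_structure is None:
        subs = [f"source{i:02d}" for i in range(cfg.n_substrates)]
        block_structure = {s: (0 if i < len(subs) // 2 else 1) for i, s in enumerate(subs)}
    if len(set(block_structure.values())) < 2:
        raise ValidationError("need >= 2 secretion blocks")
    if not 0 <= n_contaminated < n_metabolites:
        raise ValidationError("n_contaminated must be in [0, n_metabolites)")
    metabolites = [f"met{i:03d}" for i in range(n_metabolites)]
    contaminated = set(metabolites[:n_contaminated])
    clean = [m for m in metabolites if m not in contaminated]
    blocks = sorted(set(block_structure.values()))
    # partition the clean metabolites into per-block signature sets
    signature: dict[int, set[str]] = {b: set() for b in blocks}
    for i, m in enumerate(clean):
        signature[blocks[i % len(blocks)]].add(m)

    columns, meta_rows, height_cols = [], [], []
    base_height = 1000.0
    for sub, block in block_structure.items():
        for rep in range(1, n_replicates + 1):
            sample = f"{strain}_{sub}_r{rep}"
            heights = np.zeros(n_metabolites)
            for mi, m in enumerate(metabolites):
                if m in signature.get(block, ()):  # block-characteristic secretion
                    heights[mi] = base_height * rng.lognormal(0.0, 0.3)
                elif m in contaminated:
                    heights[mi] = base_height * 0.2 * rng.lognormal(0.0, 0.3)
                else:
                    heights[mi] = 0.0
            columns.append(sample)
            height_cols.append(heights)
            meta_rows.append(
                {"strain": strain, "carbon_source": sub, "replicate": rep,
                 "is_control": False, "od": 0.5}
            )
    for rep in range(1, n_replicates + 1):
        sample = f"{strain}_control_r{rep}"
        heights = np.zeros(n_metabolites)
        for mi, m in enumerate(metabolites):
            if m in contaminated:
                # well above the 5%-of-max control threshold
                heights[mi] = base_height * 0.15 * rng.lognormal(0.0, 0.1)
        columns.append(sample)
        height_cols.append(heights)
        meta_rows.append(
            {"strain": strain, "carbon_source": "none", "replicate": rep,
             "is_control": True, "od": 0.01}
        )
    heights_df = pd.DataFrame(
        np.column_stack(height_cols), index=metabolites, columns=columns
    )
    meta_df = pd.DataFrame(meta_rows, index=columns)
    return PeakTable(heights=heights_df, meta=meta_df)


# ---------------------------------------------------------------------------
# community tables
# ---------------------------------------------------------------------------

_E_FAMILIES = ("Enterobacteriaceae", "Aeromonadaceae", "Erwiniaceae", "Yersiniaceae")
_P_FAMILIES = ("Pseudomonadaceae", "Moraxellaceae")
_OTHER_FAMILIES = ("Comamonadaceae", "Alcaligenaceae", "Rhizobiaceae")


def _make_taxonomy(n_taxa: int, rng: np.random.Generator) -> TaxonomyMap:
    rows = []
    for t in range(n_taxa):
        u = t / n_taxa
        if u < 0.4:
            family = _E_FAMILIES[int(rng.integers(len(_E_FAMILIES)))]
        elif u < 0.8:
            family = _P_FAMILIES[int(rng.integers(len(_P_FAMILIES)))]
        else:
            family = _OTHER_FAMILIES[int(rng.integers(len(_OTHER_FAMILIES)))]
        genus = f"{family[:4]}_genus{int(rng.integers(3))}"
        rows.append({"esv": f"esv{t:03d}", "genus": genus, "family": family})
    return TaxonomyMap(lineage=pd.DataFrame(rows).set_index("esv"))


def simulate_communities(
    cfg: GeneratorConfig,
    model: MetabolicModel,
    envs: list[EnvironmentSpec],
    temperature: float = 0.25,
    dropout: float = 0.15,
) -> tuple[CommunityTable, TaxonomyMap, dict]:
    """Communities assembled by selection on flux-determined traits.

    Each taxon carries a linear functional w over internal-flux space;
    fermenter-clade taxa load on the flux mode of the first (reference)
    environment, respirator-clade taxa on the mode of the environment most
    dissimilar to it, so fitness — and hence composition — varies smoothly
    with the environment's flux vector.  Expected relative abundance is a
    softmax of fitness/temperature modulated by per-inoculum presence
    (random dropout) and log-normal abundance jitter; counts are drawn
    multinomially at the configured read depth.
    """
    rng = np.random.default_rng(cfg.seed)
    vectors = environment_flux_vectors(model, envs, use_pfba=True)
    labels = [v.environment_label for v in vectors]
    V = np.array([v.values for v in vectors], dtype=float)
    norms = np.linalg.norm(V, axis=1)
    Vn = V / norms[:, None]
    # reference mode and its most dissimilar counterpart
    u_e = Vn[0]
    cosines = Vn @ u_e
    u_p = Vn[int(np.argmin(cosines))]
    tax = _make_taxonomy(cfg.n_taxa, rng)
    clade = {
        esv: ("E+" if fam in _E_FAMILIES else "P+" if fam in _P_FAMILIES else "Other")
        for esv, fam in tax.lineage["family"].items()
    }
    taxa = list(tax.lineage.index)
    W = np.zeros((cfg.n_taxa, V.shape[1]))
    for i, esv in enumerate(taxa):
        noise = rng.normal(0.0, 0.15, size=V.shape[1])
        noise /= max(np.linalg.norm(noise), 1e-12)
        if clade[esv] == "E+":
            W[i] = u_e + 0.3 * noise
        elif clade[esv] == "P+":
            W[i] = u_p + 0.3 * noise
        else:
            W[i] = 0.5 * noise
    fitness = W @ Vn.T  # taxa x environments
    inocula = [f"inoc{i}" for i in range(1, cfg.n_inocula + 1)]
    presence = rng.random((cfg.n_inocula, cfg.n_taxa)) >= dropout
    # every inoculum keeps at least one E+ and one P+ taxon
    for k_ino in range(cfg.n_inocula):
        for cl in ("E+", "P+"):
            members = [i for i, esv in enumerate(taxa) if clade[esv] == cl]
            if members and not presence[k_ino, members].any():
                presence[k_ino, members[int(rng.integers(len(members)))]] = True
    jitter = rng.lognormal(0.0, cfg.inoculum_sd, size=(cfg.n_inocula, cfg.n_taxa))
    counts_rows, meta_rows, sample_ids = [], [], []
    for k_ino, ino in enumerate(inocula):
        for j, env_label in enumerate(labels):
            f = fitness[:, j] / temperature
            weights = presence[k_ino] * jitter[k_ino] * np.exp(f - f.max())
            p = weights / weights.sum()
            counts = rng.multinomial(cfg.read_depth, p)
            sample = f"{ino}_{env_label}"
            sample_ids.append(sample)
            counts_rows.append(counts)
            meta_rows.append(
                {"inoculum": ino, "carbon_source": env_label, "replicate": 1}
            )
    ct = CommunityTable(
        counts=pd.DataFrame(counts_rows, index=sample_ids, columns=taxa),
        meta=pd.DataFrame(meta_rows, index=sample_ids),
        level="ESV",
    )
    truth = {"fitness": fitness, "weights": W, "labels": labels, "clade": clade}
    return ct, tax, truth
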