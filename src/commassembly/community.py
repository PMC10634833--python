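"""Community tables, taxonomic coarse-graining, Renkonen similarity and
variance partitioning.

Communities are sample x taxon count tables with (inoculum, carbon_source,
replicate) metadata.  Counts are rarefied to a common depth, aggregated to
the ESV, Genus, Family or Clade level, converted to relative abundances,
and compared by Renkonen similarity

    S(X, Y) = sum_i min(X_i, Y_i)

over relative abundances — mathematically 1 minus the Bray-Curtis
dissimilarity.  The E+ clade comprises the fermenter families
Enterobacteriaceae, Aeromonadaceae, Erwiniaceae and Yersiniaceae; the P+
clade the respirator families Pseudomonadaceae and Moraxellaceae; all
other families map to Other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError

E_PLUS_FAMILIES = frozenset(
    {"Enterobacteriaceae", "Aeromonadaceae", "Erwiniaceae", "Yersiniaceae"}
)
P_PLUS_FAMILIES = frozenset({"Pseudomonadaceae", "Moraxellaceae"})

LEVELS = ("ESV", "Genus", "Family", "Clade")
UNASSIGNED = "unassigned"

NORMALIZATION_TOL = 1e-9


def clade_of_family(family: str) -> str:
    if family in E_PLUS_FAMILIES:
        return "E+"
    if family in P_PLUS_FAMILIES:
        return "P+"
    return "Other"


@dataclass
class TaxonomyMap:
    """ESV -> (genus, family) lineage; the clade is derived from the family."""

    lineage: pd.DataFrame  # index esv, columns genus, family

    def __post_init__(self) -> None:
        missing = {"genus", "family"} - set(self.lineage.columns)
        if missing:
            raise ValidationError(f"taxonomy map missing columns {sorted(missing)}")

    def group_for(self, esv: str, level: str) -> str:
        if level == "ESV":
            return esv
        if esv not in self.lineage.index:
            return "Other" if level == "Clade" else UNASSIGNED
        if level == "Genus":
            return str(self.lineage.loc[esv, "genus"])
        if level == "Family":
            return str(self.lineage.loc[esv, "family"])
        if level == "Clade":
            return clade_of_family(str(self.lineage.loc[esv, "family"]))
        raise AnalysisError(f"unknown taxonomic level {level!r}")


@dataclass
class CommunityTable:
    """Sample x taxon table (integer counts or relative abundances)."""

    counts: pd.DataFrame  # index samples, columns taxa
    meta: pd.DataFrame  # index samples: inoculum, carbon_source, replicate
    level: str = "ESV"
    relative: bool = False

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.meta.index):
            raise ValidationError("community samples and metadata rows disagree")
        if self.level not in LEVELS:
            raise ValidationError(f"unknown taxonomic level {self.level!r}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative abundances")
        if self.relative:
            sums = arr.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=NORMALIZATION_TOL):
                raise ValidationError("relative-abundance rows must sum to 1")
        elif not np.allclose(arr, np.round(arr)):
            raise ValidationError("raw community counts must be integral")

    def to_relative(self) -> "CommunityTable":
        if self.relative:
            return self
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise AnalysisError(f"cannot normalize empty samples: {empty}")
        return CommunityTable(
            counts=self.counts.div(totals, axis=0),
            meta=self.meta.copy(),
            level=self.level,
            relative=True,
        )


def rarefy(ct: CommunityTable, depth: int | None = None, seed: int = 0) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth=None`` uses the highest depth possible, i.e. the minimum
    sample total.  Samples below the requested depth are dropped.  Samples
    are processed in label-sorted order with a single seeded generator, so
    output is bit-reproducible.
    """
    if ct.relative:
        raise AnalysisError("rarefaction needs raw integer counts")
    totals = ct.counts.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise AnalysisError(f"rarefaction depth must be positive, got {depth}")
    keep = sorted(totals.index[totals >= depth])
    rng = np.random.default_rng(seed)
    rows = {}
    for sample in keep:
        counts = ct.counts.loc[sample].to_numpy(dtype=np.int64)
        total = int(counts.sum())
        if total == depth:
            rows[sample] = counts
        else:
            rows[sample] = rng.multivariate_hypergeometric(counts, depth)
    rare = pd.DataFrame.from_dict(rows, orient="index", columns=ct.counts.columns)
    return CommunityTable(
        counts=rare, meta=ct.meta.loc[keep], level=ct.level, relative=False
    )


def aggregate_taxonomy(ct: CommunityTable, tax: TaxonomyMap, level: str) -> CommunityTable:
    """Sum counts within the requested taxonomic groups (row totals conserved)."""
    if level == "ESV":
        return CommunityTable(
            counts=ct.counts.copy(), meta=ct.meta.copy(), level="ESV", relative=ct.relative
        )
    groups = {taxon: tax.group_for(taxon, level) for taxon in ct.counts.columns}
    agg = ct.counts.T.groupby(pd.Series(groups)).sum().T
    agg = agg[sorted(agg.columns)]
    return CommunityTable(counts=agg, meta=ct.meta.copy(), level=level, relative=ct.relative)


def renkonen(x: np.ndarray, y: np.ndarray) -> float:
    """Renkonen similarity sum_i min(X_i, Y_i) of two relative-abundance
    profiles over the same taxon ordering (absent taxon = 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AnalysisError("profiles differ in length")
    for name, v in (("first", x), ("second", y)):
        if not math.isclose(float(v.sum()), 1.0, abs_tol=NORMALIZATION_TOL):
            raise AnalysisError(
                f"{name} profile is not normalized (sum={v.sum():.12g}); "
                "renormalize explicitly before comparing"
            )
    return float(np.minimum(x, y).sum())


def community_similarity_matrix(ct: CommunityTable) -> pd.DataFrame:
    """Sample x sample Renkonen similarity (symmetric, unit diagonal)."""
    rel = ct.to_relative()
    X = rel.counts.to_numpy()
    n = X.shape[0]
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = float(np.minimum(X[i], X[j]).sum())
    return pd.DataFrame(sim, index=rel.counts.index, columns=rel.counts.index)


def per_inoculum_renkonen(ct: CommunityTable, inoculum: str) -> pd.DataFrame:
    """Carbon-source x carbon-source Renkonen matrix for one inoculum
    (one community per substrate required)."""
    mask = (ct.meta["inoculum"] == inoculum).to_numpy()
    if not mask.any():
        raise AnalysisError(f"no samples for inoculum {inoculum!r}")
    sources = ct.meta.loc[mask, "carbon_source"]
    if sources.duplicated().any():
        raise AnalysisError(
            f"inoculum {inoculum!r} has several samples per carbon source"
        )
    sub = CommunityTable(
        counts=ct.counts[mask].set_axis(sources, axis=0),
        meta=ct.meta[mask].set_axis(sources, axis=0),
        level=ct.level,
        relative=ct.relative,
    )
    return community_similarity_matrix(sub)


def similarity_vs_metabolic(
    comm: pd.DataFrame,
    sim_labels: list[str],
    sim_values: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "pearson",
) -> dict:
    """Correlate a community-similarity matrix (indexed by carbon source)
    with the metabolic-similarity matrix over shared substrates, with a
    Mantel permutation p-value."""
    from .stats import mantel_test

    shared = [s for s in comm.index if s in sim_labels]
    if len(shared) < 4:
        raise AnalysisError(f"need >= 4 shared substrates, got {len(shared)}")
    c = comm.loc[shared, shared].to_numpy()
    idx = [sim_labels.index(s) for s in shared]
    m = sim_values[np.ix_(idx, idx)]
    res = mantel_test(m, c, method=method, n_perm=n_perm, seed=seed)
    return {"pearson_r": res.r, "mantel_p": res.p, "n_substrates": len(shared)}


def _adjusted_r2(Y: np.ndarray, dummies: np.ndarray) -> float:
    """Ezekiel-adjusted R^2 of a least-squares redundancy analysis of the
    centered community matrix on the given predictor dummies."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    X = dummies - dummies.mean(axis=0)
    p = np.linalg.matrix_rank(X)
    if n - p - 1 <= 0:
        raise AnalysisError("too few samples for the requested factors")
    beta, *_ = np.linalg.lstsq(X, Yc, rcond=None)
    fitted = X @ beta
    ss_total = float((Yc**2).sum())
    if ss_total == 0:
        raise AnalysisError("community matrix has zero variance")
    r2 = float((fitted**2).sum()) / ss_total
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition(ct: CommunityTable, factors: tuple[str, str] = ("inoculum", "carbon_source")) -> dict:
    """Partition community variation between two design factors.

    Redundancy analysis on relative abundances with dummy-coded factors;
    adjusted R^2 for each factor alone and both together gives the pure
    fractions, the shared fraction and the residual by inclusion-exclusion.
    Fractions may be slightly negative (a property of adjusted R^2).
    """
    f1, f2 = factors
    rel = ct.to_relative()
    meta = rel.meta
    for f in factors:
        if meta[f].nunique() < 2:
            raise AnalysisError(f"factor {f!r} does not vary")
    crossed = meta.groupby(f1)[f2].nunique()
    if (crossed <= 1).all() and meta[f1].nunique() > 1 and meta[f2].nunique() > 1:
        raise AnalysisError(f"factors {f1!r} and {f2!r} are aliased")
    Y = rel.counts.to_numpy()
    d1 = pd.get_dummies(meta[f1], drop_first=True).to_numpy(dtype=float)
    d2 = pd.get_dummies(meta[f2], drop_first=True).to_numpy(dtype=float)
    ab = _adjusted_r2(Y, d1)  # factor 1 alone (a + b)
    bc = _adjusted_r2(Y, d2)  # factor 2 alone (b + c)
    abc = _adjusted_r2(Y, np.hstack([d1, d2]))
    a = abc - bc
    c = abc - ab
    b = ab + bc - abc
    return {
        f"frac_{f1}": a,
        f"frac_{f2}": c,
        "frac_shared": b,
        "frac_residual": 1.0 - abc,
    }


@dataclass
class GenerationArithmetic:
    """Dilution -> generation bookkeeping for serial-passage experiments."""

    dilution_fold: float
    n_transfers: int

    def __post_init__(self) -> None:
        if self.dilution_fold <= 1:
            raise ValidationError("dilution factor must exceed 1")
        if self.n_transfers < 1:
            raise ValidationError("need at least one transfer")

    @property
    def generations_per_transfer(self) -> float:
        return math.log2(self.dilution_fold)

    @property
    def total_generations(self) -> float:
        return self.n_transfers * self.generations_per_transfer


def generations(dilution_fold: float, n_transfers: int) -> float:
    """Total doublings over a serial-passage experiment: each transfer
    regrows the ``dilution_fold`` dilution, i.e. log2(fold) generations."""
    return GenerationArithmetic(dilution_fold, n_transfers).total_generations


def read_community_table(counts_path, meta_path=None) -> CommunityTable:
    """Samples x taxa TSV plus optional sample metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0).loc[counts.index]
    else:
        meta = pd.DataFrame(index=counts.index)
    return CommunityTable(counts=counts, meta=meta)


def read_taxonomy_map(path) -> TaxonomyMap:
    """Taxonomy TSV with columns esv, genus, family."""
    df = pd.read_csv(path, sep="\t")
    if "esv" in df.columns:
        df = df.set_index("esv")
    return TaxonomyMap(lineage=df)
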