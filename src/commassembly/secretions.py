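"""By-product secretion profiles from metabolomics peak tables.

The pipeline starts at an integrated peak table (metabolite x sample
heights with sample metadata).  Metabolites with significant signal in the
no-carbon-source controls are removed, carbon sources without significant
growth in every replicate are gated out, replicate heights are averaged
and z-scored across carbon sources, and substrate pairs are compared by
Pearson correlation of their by-product profiles.  A missing peak is a
zero height (absence of integration), not missing-at-random, and strains
are always analyzed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import AnalysisError, ValidationError

CONTROL_SOURCE = "none"


@dataclass
class PeakTable:
    """Metabolite x sample peak heights plus per-sample metadata.

    ``heights``: DataFrame, rows metabolites, columns sample ids.
    ``meta``: DataFrame indexed by sample id with at least columns
    strain, carbon_source, replicate, od; controls have
    carbon_source == "none".  Extra metadata columns (e.g. time_hr for
    targeted timecourses) are carried along untouched.
    """

    heights: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.heights.columns) != list(self.meta.index):
            raise ValidationError("peak-table samples and metadata rows disagree")
        if (self.heights.to_numpy() < 0).any():
            raise ValidationError("negative peak heights")
        needed = {"strain", "carbon_source", "replicate", "od"}
        missing = needed - set(self.meta.columns)
        if missing:
            raise ValidationError(f"sample metadata missing columns {sorted(missing)}")

    @property
    def is_control(self) -> pd.Series:
        return self.meta["carbon_source"] == CONTROL_SOURCE

    def subset_metabolites(self, keep: list[str]) -> "PeakTable":
        return PeakTable(self.heights.loc[keep], self.meta.copy())

    def subset_samples(self, keep: list[str]) -> "PeakTable":
        return PeakTable(self.heights[keep], self.meta.loc[keep])


@dataclass
class SecretionProfileMatrix:
    """Metabolite x carbon-source matrix of normalized abundances."""

    profiles: pd.DataFrame
    normalization: str
    flagged_constant: list[str] = field(default_factory=list)


def filter_control_peaks(pt: PeakTable, fraction: float = 0.05) -> tuple[PeakTable, list[str]]:
    """Drop metabolites with significant abundance in any control sample.

    "Significant" is relative: a control height exceeding ``fraction`` of
    that metabolite's maximum height across all samples.  Returns the
    filtered table and the list of removed metabolites.
    """
    controls = pt.meta.index[pt.is_control]
    if len(controls) == 0:
        raise AnalysisError("peak table has no control samples")
    removed = []
    for met in pt.heights.index:
        peak_max = pt.heights.loc[met].max()
        if peak_max <= 0:
            continue
        if (pt.heights.loc[met, controls] > fraction * peak_max).any():
            removed.append(met)
    kept = [m for m in pt.heights.index if m not in set(removed)]
    return pt.subset_metabolites(kept), removed


def growth_gate(pt: PeakTable, od_threshold: float = 0.04) -> PeakTable:
    """Drop every carbon source where any replicate failed to grow.

    A source is retained only if all its replicates exceed the OD
    threshold; control samples are always retained.
    """
    bad_sources = set(
        pt.meta.loc[~pt.is_control & (pt.meta["od"] <= od_threshold), "carbon_source"]
    )
    keep = [
        s
        for s in pt.meta.index
        if pt.meta.loc[s, "carbon_source"] == CONTROL_SOURCE
        or pt.meta.loc[s, "carbon_source"] not in bad_sources
    ]
    return pt.subset_samples(keep)


def build_profiles(
    pt: PeakTable,
    strain: str | None = None,
    average_replicates: bool = True,
    normalization: str = "zscore_across_sources",
) -> SecretionProfileMatrix:
    """Per-strain by-product profile matrix.

    Replicate heights are averaged per carbon source, then each metabolite
    row is z-scored across carbon sources (sample sd, n-1).  The
    ``zscore_across_samples`` variant z-scores over all individual
    replicate samples instead.  Constant metabolites become zero rows and
    are flagged.
    """
    strains = sorted(set(pt.meta.loc[~pt.is_control, "strain"]))
    if strain is None:
        if len(strains) != 1:
            raise AnalysisError(
                f"peak table holds strains {strains}; pass `strain` to pick one "
                "(strains are analyzed separately)"
            )
        strain = strains[0]
    samples = pt.meta.index[(pt.meta["strain"] == strain) & ~pt.is_control]
    if len(samples) == 0:
        raise AnalysisError(f"no non-control samples for strain {strain!r}")
    heights = pt.heights[samples]
    if normalization == "zscore_across_sources":
        if average_replicates:
            grouped = heights.T.groupby(pt.meta.loc[samples, "carbon_source"]).mean().T
        else:
            grouped = heights.copy()
            grouped.columns = pt.meta.loc[samples, "carbon_source"]
        data = grouped
    elif normalization == "zscore_across_samples":
        data = heights.copy()
        data.columns = pd.MultiIndex.from_frame(
            pt.meta.loc[samples, ["carbon_source", "replicate"]]
        )
    else:
        raise AnalysisError(f"unknown normalization {normalization!r}")
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=1)
    flagged = list(data.index[sd == 0])
    z = data.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return SecretionProfileMatrix(
        profiles=z, normalization=normalization, flagged_constant=flagged
    )


def byproduct_correlation(profiles: SecretionProfileMatrix) -> pd.DataFrame:
    """Substrate x substrate Pearson correlation of by-product profiles."""
    if profiles.profiles.shape[0] < 3:
        raise AnalysisError("need >= 3 metabolites for by-product correlation")
    corr = profiles.profiles.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_substrates(corr: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage hierarchical clustering of substrates on 1 - r.

    Labels are pre-sorted so equal-height merges resolve deterministically;
    returns the scipy linkage matrix and the leaf order.
    """
    order = sorted(corr.columns)
    corr = corr.loc[order, order]
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [order[i] for i in leaves]


def cut_clusters(linkage: np.ndarray, labels: list[str], k: int) -> dict[str, int]:
    """Flat cluster assignment from a linkage at k clusters (sorted labels)."""
    assignment = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return dict(zip(sorted(labels), (int(a) for a in assignment)))


def targeted_similarity(
    concentrations: PeakTable,
    reference: str,
    timepoint: float,
) -> pd.DataFrame:
    """Pearson r of absolute by-product concentrations against a reference
    substrate, per (strain, replicate, carbon_source) at one timepoint.

    The peak-table metadata must carry a ``time_hr`` column.  All-zero
    concentration vectors yield NaN (flagged undefined, not an error).
    """
    if "time_hr" not in concentrations.meta.columns:
        raise AnalysisError("targeted analysis needs a time_hr metadata column")
    meta = concentrations.meta
    at_t = meta.index[(meta["time_hr"] == timepoint) & (meta["carbon_source"] != CONTROL_SOURCE)]
    if len(at_t) == 0:
        raise AnalysisError(f"no samples at timepoint {timepoint}")
    sub = meta.loc[at_t]
    if not (sub["carbon_source"] == reference).any():
        raise AnalysisError(f"reference substrate {reference!r} absent at t={timepoint}")
    rows = []
    for (strain, rep), grp in sub.groupby(["strain", "replicate"]):
        ref_samples = grp.index[grp["carbon_source"] == reference]
        if len(ref_samples) == 0:
            continue
        ref_vec = concentrations.heights[ref_samples].mean(axis=1).to_numpy()
        for sample in grp.index:
            source = grp.loc[sample, "carbon_source"]
            if source == reference:
                continue
            vec = concentrations.heights[sample].to_numpy()
            if vec.std() == 0 or ref_vec.std() == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(vec, ref_vec)[0, 1])
            rows.append(
                {"strain": strain, "replicate": rep, "carbon_source": source, "r": r}
            )
    return pd.DataFrame(rows, columns=["strain", "replicate", "carbon_source", "r"])


def read_peak_table(heights_path, meta_path) -> PeakTable:
    """Peak matrix CSV (rows metabolites) + sample metadata CSV (rows samples)."""
    heights = pd.read_csv(heights_path, index_col=0)
    meta = pd.read_csv(meta_path, index_col=0)
    meta = meta.loc[heights.columns]
    return PeakTable(heights=heights, meta=meta)
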