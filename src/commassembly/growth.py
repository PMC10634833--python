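"""Growth-rate estimation from OD curves and cross-environment trait analyses.

The headline rate estimate is an average growth rate over the ascending
part of the curve:

    r = ln(N2 / N1) / (t2 - t1)

where t2 is the time of maximum derivative of the smoothed log-OD curve
(clamped to at least ``min_t2`` hours to avoid low-density artifacts), N2
the OD there, and (t1, N1) the third recorded timepoint — the first two
readings are discarded to eliminate bubble artifacts.  This measure folds
lag differences into the rate while excluding the post-peak phase where
growth on secreted by-products would confound the estimate.

The smoother is a penalized cubic smoothing spline on log-OD with the
penalty chosen by generalized cross-validation, a close stand-in for an
adaptive GAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import make_smoothing_spline

from .errors import AnalysisError, ValidationError
from .stats import correlation

#: OD detection floor applied before any logarithm
OD_FLOOR = 1e-3

E_PLUS = "E+"
P_PLUS = "P+"
OTHER = "Other"


@dataclass
class GrowthCurve:
    strain_id: str
    carbon_source: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValidationError("times and od differ in length")
        if self.times.size < 6:
            raise ValidationError("a growth curve needs at least 6 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValidationError("negative OD readings")


@dataclass
class SmoothedCurve:
    times: np.ndarray
    log_od: np.ndarray
    derivative: np.ndarray
    no_growth: bool


@dataclass
class TraitMatrix:
    """Strain x carbon-source matrix of growth metrics (NaN = missing)."""

    rates: pd.DataFrame  # index strains, columns carbon sources
    annotations: dict[str, dict] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.rates.index)

    @property
    def carbon_sources(self) -> list[str]:
        return list(self.rates.columns)

    def clade_of(self, strain: str) -> str:
        return self.annotations.get(strain, {}).get("clade", OTHER)


def smooth_curve(curve: GrowthCurve) -> SmoothedCurve:
    """GCV-penalized cubic smoothing spline of log-OD, with derivative."""
    log_od = np.log(np.maximum(curve.od, OD_FLOOR))
    if np.ptp(log_od) == 0:
        return SmoothedCurve(
            times=curve.times,
            log_od=log_od.copy(),
            derivative=np.zeros_like(log_od),
            no_growth=True,
        )
    spline = make_smoothing_spline(curve.times, log_od)
    smoothed = spline(curve.times)
    deriv = spline.derivative()(curve.times)
    no_growth = bool(np.max(np.abs(deriv)) < 1e-6)
    return SmoothedCurve(curve.times, smoothed, deriv, no_growth)


def _start_point(curve: GrowthCurve) -> tuple[float, float]:
    """(t1, N1): the third timepoint — the first two readings are skipped."""
    return float(curve.times[2]), float(max(curve.od[2], OD_FLOOR))


def average_growth_rate(curve: GrowthCurve, min_t2: float = 5.0) -> float:
    """Average growth rate ln(N2/N1)/(t2-t1) up to the derivative peak.

    t2 is clamped to at least ``min_t2`` hours; N1 and N2 are observed ODs
    floored at the detection limit before the log.
    """
    sm = smooth_curve(curve)
    t1, n1 = _start_point(curve)
    if sm.no_growth:
        return 0.0
    i2 = int(np.argmax(sm.derivative))
    t2 = max(float(curve.times[i2]), min_t2)
    i2 = int(np.argmin(np.abs(curve.times - t2)))
    t2 = float(curve.times[i2])
    n2 = float(max(curve.od[i2], OD_FLOOR))
    if t2 <= t1:
        raise AnalysisError(
            f"{curve.strain_id}/{curve.carbon_source}: derivative peak at or "
            f"before the start of the usable curve (t2={t2}, t1={t1})"
        )
    return float(np.log(n2 / n1) / (t2 - t1))


def alternative_growth_metrics(curve: GrowthCurve) -> dict[str, float]:
    """The four alternative growth quantifications.

    rate_fixed_16h: average rate to the fixed 16 h endpoint;
    max_rate: maximum derivative of the smoothed log-OD curve;
    logistic_rate: rate from a least-squares logistic fit (NaN if the fit
    fails); auc: trapezoidal area under the raw OD curve.
    """
    sm = smooth_curve(curve)
    t1, n1 = _start_point(curve)
    i16 = int(np.argmin(np.abs(curve.times - 16.0)))
    t16 = float(curve.times[i16])
    n16 = float(max(curve.od[i16], OD_FLOOR))
    rate16 = float(np.log(n16 / n1) / (t16 - t1)) if t16 > t1 else float("nan")
    max_rate = float(np.max(sm.derivative)) if not sm.no_growth else 0.0
    auc = float(np.trapezoid(curve.od, curve.times))
    return {
        "rate_fixed_16h": rate16,
        "max_rate": max_rate,
        "logistic_rate": _logistic_rate(curve),
        "auc": auc,
    }


def _logistic(t, k, n0, r):
    return k / (1.0 + (k - n0) / n0 * np.exp(-r * t))


def _logistic_rate(curve: GrowthCurve) -> float:
    od = np.maximum(curve.od, OD_FLOOR)
    k0 = float(od.max())
    n0 = float(od[0])
    if k0 <= n0:
        return float("nan")
    try:
        popt, _ = optimize.curve_fit(
            _logistic,
            curve.times,
            od,
            p0=(k0, n0, 0.3),
            bounds=([OD_FLOOR, OD_FLOOR / 10, 1e-6], [np.inf, k0, 10.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return float("nan")
    return float(popt[2])


_METRICS = {"eq1", "rate_fixed_16h", "max_rate", "logistic_rate", "auc"}


def _metric_value(curve: GrowthCurve, metric: str) -> float:
    if metric == "eq1":
        return average_growth_rate(curve)
    return alternative_growth_metrics(curve)[metric]


def average_replicates(curves: list[GrowthCurve]) -> GrowthCurve:
    """Average replicate OD traces on a shared time grid (one rate per
    strain x substrate is estimated from the averaged curve)."""
    first = curves[0]
    for c in curves[1:]:
        if c.times.size != first.times.size or not np.allclose(c.times, first.times):
            raise AnalysisError(
                f"{first.strain_id}/{first.carbon_source}: replicate time grids differ"
            )
    od = np.mean([c.od for c in curves], axis=0)
    return GrowthCurve(
        strain_id=first.strain_id,
        carbon_source=first.carbon_source,
        replicate=0,
        times=first.times.copy(),
        od=od,
    )


def build_trait_matrix(
    curves: list[GrowthCurve],
    metric: str = "eq1",
    exclusions: list[tuple[str, str]] | None = None,
    annotations: dict[str, dict] | None = None,
) -> TraitMatrix:
    """Strain x substrate matrix of the chosen growth metric.

    Replicates are averaged at the OD level before estimation; excluded
    (strain, substrate) pairs become missing cells.
    """
    if metric not in _METRICS:
        raise AnalysisError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    excluded = set(exclusions or [])
    grouped: dict[tuple[str, str], list[GrowthCurve]] = {}
    for c in curves:
        grouped.setdefault((c.strain_id, c.carbon_source), []).append(c)
    strains = sorted({k[0] for k in grouped})
    sources = sorted({k[1] for k in grouped})
    rates = pd.DataFrame(np.nan, index=strains, columns=sources)
    for (strain, source), reps in grouped.items():
        if (strain, source) in excluded:
            continue
        rates.loc[strain, source] = _metric_value(average_replicates(reps), metric)
    return TraitMatrix(rates=rates, annotations=annotations or {})


def normalize_traits(tm: TraitMatrix, mode: str = "per_substrate_z") -> TraitMatrix:
    """Z-score the trait matrix along substrates (columns) or strains (rows).

    Missing cells are preserved; zero-variance slices become zeros.
    """
    if mode == "per_substrate_z":
        axis = 0
    elif mode == "per_strain_z":
        axis = 1
    else:
        raise AnalysisError(f"unknown normalization mode {mode!r}")
    mean = tm.rates.mean(axis=axis)
    sd = tm.rates.std(axis=axis, ddof=1)
    z = tm.rates.sub(mean, axis=1 - axis).div(sd.replace(0, np.nan), axis=1 - axis)
    z = z.where(~tm.rates.notna() | z.notna(), 0.0)  # zero-variance slices -> 0
    return TraitMatrix(rates=z, annotations=tm.annotations)


def growth_rate_correlation(tm: TraitMatrix, min_pairs: int = 3) -> pd.DataFrame:
    """Substrate x substrate Pearson correlation of rates across strains.

    Pairwise-complete; entries with fewer than ``min_pairs`` shared strains
    are left missing.
    """
    corr = tm.rates.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def clade_contrast(tm: TraitMatrix, substrate: str) -> dict:
    """Welch two-sample t-test of E+ vs P+ growth rates on one substrate."""
    from scipy import stats as sps

    if substrate not in tm.rates.columns:
        raise AnalysisError(f"substrate {substrate!r} not in the trait matrix")
    col = tm.rates[substrate]
    e = col[[s for s in tm.strains if tm.clade_of(s) == E_PLUS]].dropna()
    p = col[[s for s in tm.strains if tm.clade_of(s) == P_PLUS]].dropna()
    if len(e) < 2 or len(p) < 2:
        raise AnalysisError(
            f"substrate {substrate!r}: need >= 2 strains per clade "
            f"(E+={len(e)}, P+={len(p)})"
        )
    if e.var(ddof=1) == 0 and p.var(ddof=1) == 0:
        if e.mean() == p.mean():
            return {"t_statistic": 0.0, "p_value": 1.0, "direction": 0}
        raise AnalysisError("degenerate zero-variance groups with distinct means")
    res = sps.ttest_ind(e, p, equal_var=False)
    diff = float(e.mean() - p.mean())
    return {
        "t_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": int(np.sign(diff)),
    }


def per_strain_similarity_trend(
    tm: TraitMatrix,
    sim_labels: list[str],
    sim_values: np.ndarray,
    reference: str,
    min_substrates: int = 4,
) -> pd.Series:
    """Per-strain Spearman rho between growth rate and metabolic similarity
    of each substrate to a reference substrate (e.g. d-glucose)."""
    if reference not in sim_labels:
        raise AnalysisError(f"reference {reference!r} absent from similarity labels")
    ref_i = sim_labels.index(reference)
    shared = [s for s in tm.carbon_sources if s in sim_labels]
    sim_to_ref = np.array([sim_values[ref_i, sim_labels.index(s)] for s in shared])
    out = {}
    for strain in tm.strains:
        rates = tm.rates.loc[strain, shared].to_numpy(dtype=float)
        keep = ~np.isnan(rates)
        if keep.sum() < min_substrates:
            out[strain] = np.nan
            continue
        out[strain] = correlation(rates[keep], sim_to_ref[keep], method="spearman")
    return pd.Series(out, name=f"spearman_vs_{reference}")


def read_growth_curves(path) -> list[GrowthCurve]:
    """Long-format CSV/TSV (strain, carbon_source, replicate, time_hr, od)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    needed = {"strain", "carbon_source", "replicate", "time_hr", "od"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for (strain, source, rep), grp in df.groupby(
        ["strain", "carbon_source", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_hr")
        curves.append(
            GrowthCurve(
                strain_id=str(strain),
                carbon_source=str(source),
                replicate=int(rep),
                times=grp["time_hr"].to_numpy(),
                od=grp["od"].to_numpy(),
            )
        )
    return curves
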