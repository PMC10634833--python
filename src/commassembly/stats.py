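"""Permutation and rank statistics underpinning the matrix comparisons.

The Mantel test correlates the lower triangles of two square symmetric
matrices and builds its null by simultaneously permuting the rows and
columns of the second matrix.  P-values follow the add-one Monte-Carlo
convention, p = (#{r_perm >= r_obs} + 1) / (n_perm + 1), so the smallest
attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError

SYMMETRY_TOL = 1e-12


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def _check_square_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise AnalysisError(f"{name} is not square")
    if not np.allclose(m, m.T, atol=1e-9, rtol=0):
        raise AnalysisError(f"{name} is not symmetric")
    return m


def mantel_test(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "pearson",
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Permutation test for correlation between two similarity/distance matrices.

    ``a`` and ``b`` are square symmetric matrices over the same label set
    (same ordering).  Permutations are sampled with replacement from the
    permutation group and applied to the second matrix.
    """
    if tail != "greater":
        raise AnalysisError("only the upper-tail Mantel test is provided")
    a = _check_square_symmetric(a, "first matrix")
    b = _check_square_symmetric(b, "second matrix")
    n = a.shape[0]
    if n < 4:
        raise AnalysisError(f"Mantel test needs >= 4 labels, got {n}")
    if a.shape != b.shape:
        raise AnalysisError("matrices differ in size")
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    y = b[iu]
    if x.std() == 0 or y.std() == 0:
        raise AnalysisError("zero variance in a matrix triangle")
    if method == "spearman":
        x = sps.rankdata(x)
    elif method != "pearson":
        raise AnalysisError(f"unknown correlation method {method!r}")

    def corr_rows(Y: np.ndarray) -> np.ndarray:
        if method == "spearman":
            Y = sps.rankdata(Y, axis=-1)
        xc = x - x.mean()
        Yc = Y - Y.mean(axis=-1, keepdims=True)
        num = Yc @ xc
        den = np.sqrt((Yc**2).sum(axis=-1) * (xc**2).sum())
        return num / den

    r_obs = float(corr_rows(y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rows = perms[:, iu[0]]
    cols = perms[:, iu[1]]
    y_perm = b[rows, cols]
    r_perm = corr_rows(y_perm)
    p = (np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str


def mann_whitney_one_tailed(
    x, y, alternative: str = "greater"
) -> MannWhitneyResult:
    """One-tailed Mann-Whitney U test (x tends greater than y).

    Uses exact enumeration when both groups have <= 8 observations and no
    ties straddle the groups; otherwise the normal approximation with
    midranks and tie-corrected variance.
    """
    if alternative != "greater":
        raise AnalysisError("only the 'greater' alternative is provided")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="greater", method="exact")
        return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), method="exact")
    res = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue), method="asymptotic")


def correlation(x, y, method: str = "pearson") -> float:
    """Pairwise-complete correlation; NaN pairs are dropped, >=3 required."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AnalysisError("inputs differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise AnalysisError(f"need >= 3 complete pairs, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise AnalysisError(f"unknown correlation method {method!r}")
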