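"""Association statistics: rank tests, simple regression, and the
Cochran-Armitage trend scan used to screen exome variants against drug
exposure.

Rank tests and the regression delegate to scipy.stats; the Cochran-Armitage
trend test is implemented directly (score test with the exact permutation
variance) since no scipy equivalent exists.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import CATEGORIES

DEFAULT_TREND_WEIGHTS = (0.0, 1.0, 2.0)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class TrendTable:
    """2x3 genotype counts: rows (cases, controls) = (AUC-high, AUC-low),
    columns ordered by variant-allele dose (wild, hetero, variant)."""

    cases: tuple[int, int, int]
    controls: tuple[int, int, int]
    weights: tuple[float, float, float] = DEFAULT_TREND_WEIGHTS

    def __post_init__(self) -> None:
        counts = np.array([self.cases, self.controls], dtype=float)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("trend table is empty")
        if counts.sum(axis=1).min() == 0 or (counts.sum(axis=0) > 0).sum() == 0:
            raise ValueError("trend table needs a nonzero row and column")


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H with tie correction; chi-square p on (g-1) df.

    All values identical across groups degenerates to H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    n = sum(a.size for a in arrays)
    if np.unique(np.concatenate(arrays)).size == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis", df=len(groups) - 1, n=n)
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal-wallis", df=len(groups) - 1, n=n)


def mann_whitney_u(a, b, method: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U.

    Convention: U counts (a, b) pairs with a < b plus half-ties, so a sample
    ``a`` stochastically below ``b`` gives large U.  ``method`` follows
    scipy ("auto" uses the exact distribution for small tie-free samples,
    the tie-corrected normal approximation otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    # scipy's U1 counts a > b pairs (+ half ties); mirror it.
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_less = a.size * b.size - float(res.statistic)
    return TestResult(u_less, float(res.pvalue), "mann-whitney-u", n=a.size + b.size)


def simple_linear_regression(x, y) -> dict:
    """OLS of y on x: slope, intercept, R^2, and two-sided t-test p for slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(x.size),
    }


def cochran_armitage_trend(table: TrendTable) -> TestResult:
    """Cochran-Armitage trend test on a 2x3 genotype table.

    Score test for a dose-ordered case/control difference: the statistic is
    the case-group score sum centred at its hypergeometric expectation,
    standardized by the exact permutation variance
    R1*R2/(N*(N-1)) * sum((s_i - s_bar)^2); two-sided p from the standard
    normal.  Identical genotype proportions in both rows give Z = 0, p = 1.
    """
    r1 = np.asarray(table.cases, dtype=float)
    r2 = np.asarray(table.controls, dtype=float)
    w = np.asarray(table.weights, dtype=float)
    nk = r1 + r2
    n = nk.sum()
    n1, n2 = r1.sum(), r2.sum()
    t = float(w @ r1 - n1 * (w @ nk) / n)
    # sum over subjects of (s_i - s_bar)^2 from column counts
    s_bar = (w @ nk) / n
    ss = float(((w - s_bar) ** 2) @ nk)
    var = n1 * n2 * ss / (n * (n - 1.0)) if n > 1 else 0.0
    if var <= 0:
        return TestResult(0.0, 1.0, "cochran-armitage", n=int(n))
    z = t / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(z), float(min(p, 1.0)), "cochran-armitage", n=int(n))


def _counts_by_category(categories: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    return tuple(int(np.sum(categories[mask] == c)) for c in CATEGORIES)


def trend_scan(
    variants: pd.DataFrame,
    auc: pd.Series,
    split: float = 0.5,
    weights: tuple[float, float, float] = DEFAULT_TREND_WEIGHTS,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Scan variants for trend association with dichotomized exposure.

    Parameters
    ----------
    variants : wide patient x variant frame of categories (wild/hetero/
        variant) or allele counts (0/1/2), indexed by patient_id.
    auc : exposure per patient (ng*hr/ml), same index.
    split : quantile for the high/low dichotomy (default median split).

    Returns a frame sorted by ascending p with per-row genotype counts,
    the trend Z, raw p, and a Bonferroni-adjusted column.
    """
    auc = auc.reindex(variants.index)
    if auc.isna().any():
        raise ValueError("every patient in the variant table needs an AUC value")
    threshold = float(np.quantile(auc.to_numpy(), split))
    high = auc.to_numpy() > threshold
    low = ~high
    if high.sum() == 0 or low.sum() == 0:
        raise ValueError("AUC split puts every patient on one side")

    m = variants.shape[1]
    rows = []
    for name in variants.columns:
        col = variants[name]
        if np.issubdtype(col.dtype, np.number):
            cats = np.asarray(CATEGORIES, dtype=object)[col.to_numpy(dtype=int)]
        else:
            cats = col.to_numpy(dtype=object)
        cases = _counts_by_category(cats, high)
        controls = _counts_by_category(cats, low)
        try:
            res = cochran_armitage_trend(TrendTable(cases, controls, weights))
            z, p = res.statistic, res.p_value
        except ValueError:
            z, p = 0.0, 1.0
        rows.append(
            {
                "rsid": name,
                "n_high_wild": cases[0],
                "n_high_hetero": cases[1],
                "n_high_variant": cases[2],
                "n_low_wild": controls[0],
                "n_low_hetero": controls[1],
                "n_low_variant": controls[2],
                "z": z,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if bonferroni:
        out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    return out.sort_values(["p", "rsid"], kind="stable").reset_index(drop=True)
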