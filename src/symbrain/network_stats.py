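"""Functional degree, the hub disruption index, and the study's statistics.

The hub disruption index (HDI) summarises degree-dependent network
reorganisation: per-region change in functional degree between a perturbed
and a reference condition is regressed on the reference degree, and the
slope is the HDI.  A significantly negative slope means high-degree (hub)
regions lose connectivity preferentially while low-degree regions may gain.

The regression x-axis is always the reference (balanced-model) degree;
swapping the roles of reference and perturbed changes both axes, so the HDI
is not an antisymmetric quantity under that swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .symbolic import ConnectivityMatrix

__all__ = [
    "RegionalProfile",
    "HDIResult",
    "functional_degree",
    "hub_disruption_index",
    "independent_t_test",
    "pearson_r",
    "mann_whitney_u",
    "fdr_bky",
]


@dataclass(frozen=True)
class RegionalProfile:
    """One value per region (PE or functional degree) plus condition tags."""

    values: np.ndarray
    labels: tuple[str, ...] = ()
    condition: dict | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.isfinite(v).all():
            raise ValueError("regional profile contains non-finite values")
        if self.labels and len(self.labels) != len(v):
            raise ValueError("label count does not match value count")


@dataclass(frozen=True)
class HDIResult:
    """Simple-regression summary of degree change vs reference degree."""

    slope: float
    offset: float
    r_squared: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def functional_degree(matrix: ConnectivityMatrix | np.ndarray,
                      labels: tuple[str, ...] = (),
                      condition: dict | None = None) -> RegionalProfile:
    """Per-region mean connectivity to all other regions (diagonal excluded)."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else matrix
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n or n < 2:
        raise ValueError("need a square matrix with at least 2 regions")
    off = values.copy()
    np.fill_diagonal(off, 0.0)
    degree = off.sum(axis=1) / (n - 1)
    return RegionalProfile(degree, labels=labels, condition=condition)


def hub_disruption_index(
    reference: RegionalProfile, perturbed: RegionalProfile
) -> HDIResult:
    """OLS regression of (perturbed - reference) degree on reference degree.

    The slope is the HDI.  F and p are the standard simple-regression test
    with df = (1, N-2); R^2 and F satisfy F = R^2 (N-2) / (1 - R^2).
    """
    x = reference.values
    y = perturbed.values - reference.values
    if len(x) != len(y):
        raise ValueError("reference and perturbed profiles differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 regions for the HDI regression")
    if np.ptp(x) == 0:
        raise ValueError("reference degrees have zero variance")
    fit = _stats.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    df_den = n - 2
    if r2 >= 1.0:
        f = np.inf
    else:
        f = r2 * df_den / (1.0 - r2)
    return HDIResult(
        slope=float(fit.slope),
        offset=float(fit.intercept),
        r_squared=float(r2),
        f_stat=float(f),
        df_num=1,
        df_den=df_den,
        p_value=float(fit.pvalue),
    )


def independent_t_test(
    groupA, groupB, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test with pooled-SD Cohen's d.

    Student's t by default (the study design has equal group sizes); Welch
    via ``equal_var=False``.  Returns (t, p, d).
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = _stats.ttest_ind(a, b, equal_var=equal_var)
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, 0.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    return float(res.statistic), float(res.pvalue), float(d)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = _stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(
    groupA, groupB, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U rank test (U for the A-over-B orientation).

    Exact null distribution for small tie-free samples, normal
    approximation with tie correction otherwise (scipy's 'auto' policy).
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    res = _stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def fdr_bky(p_values, q: float = 0.01) -> np.ndarray:
    """Two-stage linear step-up FDR control (Benjamini-Krieger-Yekutieli).

    Stage one estimates the number of true nulls with a BH pass at level
    q/(1+q); stage two reruns BH at the level scaled by that estimate.
    Returns a boolean rejection flag per hypothesis.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_tsbky")
    return np.asarray(reject, dtype=bool)
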