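"""Site- and population-level statistics for the shoreline-subsidy analysis.

Covers transition-zone slope summaries from transect elevation reliefs,
simple OLS regression with the F statistic on (1, n-2) degrees of freedom,
Kruskal-Wallis tests across habitats with rank-based post hoc comparisons,
the pooled-variance t-test on log-transformed percent marine diet between
sexes, and Pearson correlations of diet with body measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TransectSet",
    "RegressionResult",
    "GroupTestResult",
    "summarize_transects",
    "simple_ols",
    "kruskal_wallis",
    "posthoc_dunn",
    "posthoc_dunnett",
    "sex_ttest_log",
    "correlate",
]


@dataclass(frozen=True)
class TransectSet:
    """Transition-zone hillslope summary for one beach.

    ``reliefs`` are elevation gains (m) along fixed-length shore-perpendicular
    transects; slopes are dimensionless rise/run; SD is the sample (n-1) SD.
    """

    site: str
    reliefs: Tuple[float, ...]
    transect_length: float = 75.0
    slopes: Tuple[float, ...] = field(init=False)
    slope_mean: float = field(init=False)
    slope_sd: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.reliefs) < 2:
            raise ValueError("need >= 2 transects")
        if any(r < 0 for r in self.reliefs):
            raise ValueError("negative elevation relief")
        slopes = tuple(r / self.transect_length for r in self.reliefs)
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "slope_mean", float(np.mean(slopes)))
        object.__setattr__(self, "slope_sd", float(np.std(slopes, ddof=1)))


def summarize_transects(site: str, reliefs: Sequence[float], transect_length: float = 75.0) -> TransectSet:
    """Slope mean and sample SD from per-transect elevation reliefs."""
    return TransectSet(site=site, reliefs=tuple(float(r) for r in reliefs),
                       transect_length=transect_length)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    f_stat: float
    df: Tuple[int, int]
    p_value: float
    n: int


def simple_ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple least-squares regression of y on x with the ANOVA F test.

    For a single predictor F = r^2/(1-r^2) * (n-2) on (1, n-2) degrees of
    freedom, and its upper-tail p equals the two-sided slope t-test p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x/y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x: degenerate design")
    lr = sps.linregress(x, y)
    n = x.size
    # constant y: zero-variance response, r is undefined; report a null fit
    r2 = 0.0 if np.ptp(y) == 0 else float(lr.rvalue**2)
    if r2 >= 1.0:
        f, p = float("inf"), 0.0
    else:
        f = r2 / (1.0 - r2) * (n - 2)
        p = float(sps.f.sf(f, 1, n - 2))
    return RegressionResult(
        slope=float(lr.slope), intercept=float(lr.intercept), r2=r2,
        f_stat=float(f), df=(1, n - 2), p_value=p, n=n,
    )


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: int
    p_value: float
    pairwise: Tuple[Tuple[str, str, float], ...] = ()


def kruskal_wallis(groups: Dict[str, Sequence[float]], posthoc: str = "dunn") -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups with pairwise post hoc.

    ``posthoc`` selects Dunn's rank-based z tests with Holm adjustment
    (default; appropriate after a rank-based omnibus) or Dunnett's
    many-to-one comparisons against the first group (normal-theory; offered
    because the two are often conflated in ecological reporting).
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(data) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if np.ptp(np.concatenate(data)) == 0:
        h, p = 0.0, 1.0  # all observations tied; scipy refuses this edge case
    else:
        h, p = sps.kruskal(*data)
    if posthoc == "dunn":
        pairs = posthoc_dunn(groups)
    elif posthoc == "dunnett":
        pairs = posthoc_dunnett(groups)
    elif posthoc is None or posthoc == "none":
        pairs = ()
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")
    return GroupTestResult(statistic=float(h), df=len(data) - 1, p_value=float(p),
                           pairwise=tuple(pairs))


def posthoc_dunn(groups: Dict[str, Sequence[float]]) -> List[Tuple[str, str, float]]:
    """Dunn's pairwise z tests on pooled ranks, Holm-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))](1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) over tie groups.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    idx = np.cumsum([0] + [d.size for d in data])
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(data))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    labels = []
    for i in range(len(data)):
        for j in range(i + 1, len(data)):
            se = np.sqrt(base_var * (1.0 / data[i].size + 1.0 / data[j].size))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            raw.append(2.0 * sps.norm.sf(abs(z)))
            labels.append((names[i], names[j]))
    adj = multipletests(raw, method="holm")[1] if raw else []
    return [(a, b, float(p)) for (a, b), p in zip(labels, adj)]


def posthoc_dunnett(groups: Dict[str, Sequence[float]]) -> List[Tuple[str, str, float]]:
    """Dunnett's many-to-one comparisons, first group treated as control."""
    names = list(groups)
    control = np.asarray(groups[names[0]], dtype=float)
    treats = [np.asarray(groups[g], dtype=float) for g in names[1:]]
    res = sps.dunnett(*treats, control=control)
    return [(names[0], g, float(p)) for g, p in zip(names[1:], res.pvalue)]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    n_excluded: int = 0


def sex_ttest_log(percent_by_group: Dict[str, Sequence[float]]) -> TTestResult:
    """Pooled-variance two-sample t-test on log percent marine diet.

    Percent values are natural-log transformed to meet normality; nonpositive
    percentages cannot be logged and are excluded with a warning.
    """
    if len(percent_by_group) != 2:
        raise ValueError("need exactly two groups")
    (ga, a), (gb, b) = percent_by_group.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_excl = int((a <= 0).sum() + (b <= 0).sum())
    if n_excl:
        warnings.warn(f"excluding {n_excl} nonpositive percent value(s) before log transform")
    a, b = np.log(a[a > 0]), np.log(b[b > 0])
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 positive values")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), df=a.size + b.size - 2, p_value=float(p), n_excluded=n_excl)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p_value: float


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x/y with n >= 3")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), df=x.size - 2, p_value=float(p))
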