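"""Group-comparison statistics for aMWF observations.

The analysis mirrors the study workflow: a Kolmogorov-Smirnov normality
check per group, a classical one-way ANOVA across the three groups
(normal white matter, normal-appearing white matter, lesions), and a
Games-Howell post hoc test for the pairwise comparisons.  Games-Howell
uses per-pair Welch standard errors and Welch-Satterthwaite degrees of
freedom with p-values from the studentized-range distribution, so it
remains valid when group variances and sizes differ.

Observations are treated as independent: ROIs and lesions pooled across
subjects enter as individual data points, and no mixed-effects correction
for within-subject correlation is applied.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from stairmwi.errors import DegenerateDataError, DomainError

__all__ = [
    "GroupSample",
    "PairwiseComparison",
    "ComparisonReport",
    "ks_normality",
    "one_way_anova",
    "games_howell",
    "summarize_cohort",
]


@dataclass(frozen=True)
class GroupSample:
    """One group's observations (aMWF fractions)."""

    name: str
    values: tuple[float, ...]

    def __init__(self, name: str, values) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    def ci95(self) -> tuple[float, float]:
        """Two-sided 95% t-interval for the group mean."""
        se = self.sd / math.sqrt(self.n)
        tcrit = sps.t.ppf(0.975, self.n - 1)
        return (self.mean - tcrit * se, self.mean + tcrit * se)


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_diff: float
    statistic: float
    welch_df: float
    p_adjusted: float


@dataclass(frozen=True)
class ComparisonReport:
    """Group summaries, ANOVA and Games-Howell table for one cohort."""

    groups: list[GroupSample]
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    pairwise: list[PairwiseComparison]
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)

    def group_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            lo, hi = g.ci95()
            rows.append({
                "group": g.name, "n": g.n,
                "mean_pct": 100 * g.mean, "sd_pct": 100 * g.sd,
                "ci95_lo_pct": 100 * lo, "ci95_hi_pct": 100 * hi,
            })
        return pd.DataFrame(rows)

    def pairwise_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group_a": c.pair[0], "group_b": c.pair[1],
            "mean_diff_pct": 100 * c.mean_diff,
            "t": c.statistic, "welch_df": c.welch_df,
            "p_adjusted": c.p_adjusted,
        } for c in self.pairwise])


def ks_normality(sample: GroupSample, lilliefors_correction: bool = True
                 ) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test of one group.

    The reference normal uses the sample's own mean and SD; with
    ``lilliefors_correction`` (default) the p-value accounts for the
    estimated parameters, otherwise the plain one-sample KS p-value
    against the fitted normal is returned.
    """
    if sample.n < 5:
        raise DomainError("normality test needs n >= 5")
    x = np.asarray(sample.values)
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"group {sample.name!r} is constant")
    if lilliefors_correction:
        stat, p = lilliefors(x, dist="norm")
        return float(stat), float(p)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(stat), float(p)


def one_way_anova(groups: list[GroupSample]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df_between, df_within, p)."""
    if len(groups) < 2:
        raise DomainError("ANOVA needs at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise DomainError(f"group {g.name!r} needs n >= 2")
    arrays = [np.asarray(g.values) for g in groups]
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1 = len(groups) - 1
    df2 = n_total - len(groups)
    if ss_within == 0:
        raise DegenerateDataError("zero within-group variance")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def games_howell(groups: list[GroupSample]) -> list[PairwiseComparison]:
    """Games-Howell pairwise post hoc comparisons.

    For each pair (i, j):
        t  = (mean_i - mean_j) / sqrt(s_i^2/n_i + s_j^2/n_j)
        df = Welch-Satterthwaite
        p  = P(Q_{k, df} > |t| * sqrt(2))        (studentized range, k groups)
    """
    if len(groups) < 2:
        raise DomainError("Games-Howell needs at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise DomainError(f"group {g.name!r} needs n >= 2")
        if g.sd == 0:
            raise DegenerateDataError(
                f"group {g.name!r} has zero variance")
    k = len(groups)
    out = []
    for gi, gj in itertools.combinations(groups, 2):
        vi, vj = gi.sd**2 / gi.n, gj.sd**2 / gj.n
        se = math.sqrt(vi + vj)
        t = (gi.mean - gj.mean) / se
        df = (vi + vj) ** 2 / (vi**2 / (gi.n - 1) + vj**2 / (gj.n - 1))
        q = abs(t) * math.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df))
        out.append(PairwiseComparison(
            pair=(gi.name, gj.name), mean_diff=gi.mean - gj.mean,
            statistic=float(t), welch_df=float(df),
            p_adjusted=min(max(p, 0.0), 1.0),
        ))
    return out


def summarize_cohort(
    observations: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "value",
) -> ComparisonReport:
    """Full comparison report from a tidy observation table.

    ``observations`` needs one row per observation with at least a group
    column and a value column (aMWF as a fraction).  Produces group means,
    SDs and 95% CIs, the one-way ANOVA, the Games-Howell table, and
    KS normality statistics per group.
    """
    names = list(dict.fromkeys(observations[group_col]))
    if len(names) < 2:
        raise DomainError("need at least 2 groups to compare")
    groups = [
        GroupSample(n, observations.loc[observations[group_col] == n,
                                        value_col].to_numpy())
        for n in names
    ]
    f, df1, df2, p = one_way_anova(groups)
    pairwise = games_howell(groups)
    normality = {}
    for g in groups:
        try:
            normality[g.name] = ks_normality(g)
        except (DomainError, DegenerateDataError):
            normality[g.name] = (math.nan, math.nan)
    return ComparisonReport(
        groups=groups, anova_f=f, anova_df=(df1, df2), anova_p=p,
        pairwise=pairwise, normality=normality,
    )
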