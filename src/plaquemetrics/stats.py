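"""Group statistics: hierarchical aggregation, one-way ANOVA with Fisher's
LSD post hoc, Pearson correlation, and the one-tailed Fisher Z test for
independent correlations.

The experimental unit is the animal: per-object measurements are first
averaged (or, for IOD-type metrics, summed) per animal and anatomical region,
then averaged per treatment group, and SEM is always computed over
animal-level values with the n−1 sample standard deviation. Fisher's LSD is
the unadjusted pairwise t-test using the ANOVA pooled mean-square error with
N−k degrees of freedom; pairwise tests are reported regardless of omnibus
significance, with the omnibus p carried alongside. Significance stars follow
the *p<0.05, **p<0.01, ***p<0.001 convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MeasurementError, UsageError


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------


@dataclass
class GroupSummary:
    group: str
    region: str
    metric: str
    animal_values: np.ndarray
    mean: float
    sem: float  # NaN for n = 1 (flagged, not an error)
    n_animals: int


def sem(values) -> float:
    """Standard error of the mean, n−1 denominator; NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def aggregate(
    records: pd.DataFrame,
    value_columns: dict[str, str],
    group_col: str = "group",
    animal_col: str = "animal",
    region_col: str = "region",
) -> tuple[pd.DataFrame, list[GroupSummary]]:
    """Animal-region-then-group aggregation.

    ``value_columns`` maps each metric column to ``"mean"`` (averaged per
    animal-region, e.g. diameters, FD, distances) or ``"sum"`` (cumulated per
    animal-region, e.g. IOD). Returns the per-animal table and the group
    summaries (mean, SEM over animals, n).
    """
    for col in (group_col, animal_col, region_col, *value_columns):
        if col not in records.columns:
            raise UsageError(f"records are missing required column {col!r}")
    per_animal = (
        records.groupby([group_col, region_col, animal_col], sort=True)
        .agg({m: how for m, how in value_columns.items()})
        .reset_index()
    )
    summaries: list[GroupSummary] = []
    for (grp, region), sub in per_animal.groupby([group_col, region_col], sort=True):
        for metric in value_columns:
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            summaries.append(
                GroupSummary(
                    group=str(grp),
                    region=str(region),
                    metric=metric,
                    animal_values=vals,
                    mean=float(vals.mean()),
                    sem=sem(vals),
                    n_animals=int(vals.size),
                )
            )
    return per_animal, summaries


def summaries_to_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                group=s.group,
                region=s.region,
                metric=s.metric,
                mean=s.mean,
                sem=s.sem,
                n_animals=s.n_animals,
            )
            for s in summaries
        ],
        columns=["group", "region", "metric", "mean", "sem", "n_animals"],
    )


# --------------------------------------------------------------------------
# ANOVA + Fisher LSD
# --------------------------------------------------------------------------


@dataclass
class AnovaLsdResult:
    f: float
    df_between: int
    df_within: int
    p_omnibus: float
    mse: float
    group_names: list[str]
    group_means: list[float]
    group_ns: list[int]
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


def stars(p: float) -> str:
    """Significance stars: *p<0.05, **p<0.01, ***p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def one_way_anova(
    groups: list[np.ndarray], names: list[str] | None = None
) -> AnovaLsdResult:
    """Classical one-way ANOVA decomposition (SSB/SSW, F = MSB/MSW)."""
    if len(groups) < 2:
        raise UsageError("one-way ANOVA needs at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise UsageError("each group needs at least 2 observations")
    names = names or [f"group{i + 1}" for i in range(len(groups))]
    k = len(groups)
    ns = [g.size for g in groups]
    n_total = sum(ns)
    grand = np.concatenate(groups).mean()
    means = [float(g.mean()) for g in groups]
    ssb = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ssw = sum(float(((g - m) ** 2).sum()) for g, m in zip(groups, means))
    df_b, df_w = k - 1, n_total - k
    msw = ssw / df_w
    if msw == 0:
        # all values identical within groups: no within-variance
        f = 0.0 if ssb == 0 else float("inf")
        p = 1.0 if ssb == 0 else 0.0
    else:
        f = (ssb / df_b) / msw
        p = float(sps.f.sf(f, df_b, df_w))
    return AnovaLsdResult(
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p_omnibus=p,
        mse=float(msw),
        group_names=list(names),
        group_means=means,
        group_ns=ns,
    )


def fisher_lsd(groups: list[np.ndarray], anova: AnovaLsdResult) -> pd.DataFrame:
    """Unadjusted pairwise t-tests with the pooled MSE and df = N−k.

    t = (m_i − m_j) / sqrt(MSE · (1/n_i + 1/n_j)), two-sided p; no
    multiplicity adjustment (that is the definition of LSD).
    """
    if anova.mse == 0:
        raise MeasurementError("degenerate variance: pooled MSE is zero")
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        mi, mj = anova.group_means[i], anova.group_means[j]
        ni, nj = anova.group_ns[i], anova.group_ns[j]
        se = np.sqrt(anova.mse * (1.0 / ni + 1.0 / nj))
        t = (mi - mj) / se
        p = 2.0 * float(sps.t.sf(abs(t), anova.df_within))
        rows.append(
            dict(
                group_1=anova.group_names[i],
                group_2=anova.group_names[j],
                mean_1=mi,
                mean_2=mj,
                mean_difference=mi - mj,
                t=float(t),
                df=anova.df_within,
                p=p,
                significance=stars(p),
            )
        )
    table = pd.DataFrame(rows)
    anova.pairwise = table
    return table


def anova_lsd(groups: list[np.ndarray], names: list[str] | None = None) -> AnovaLsdResult:
    """Omnibus ANOVA followed by the LSD pairwise table, in one call."""
    res = one_way_anova(groups, names)
    if res.mse > 0:
        fisher_lsd(groups, res)
    return res


# --------------------------------------------------------------------------
# correlations
# --------------------------------------------------------------------------


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the exact-t two-sided p-value.

    p is computed from t = r·sqrt((n−2)/(1−r²)) on n−2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UsageError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise UsageError("Pearson correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise MeasurementError("correlation undefined for a constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, p


@dataclass
class FisherZResult:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float
    tail: str


def fisher_z_independent(
    r1: float, n1: int, r2: float, n2: int, tail: str = "greater"
) -> FisherZResult:
    """Fisher Z test for two independent correlations.

    Z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)). ``tail`` refers to
    the alternative on r1 − r2: "greater", "less", or "two-sided".
    """
    if n1 < 4 or n2 < 4:
        raise UsageError("Fisher Z needs n >= 4 in each sample")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise UsageError("Fisher Z undefined for |r| = 1 (infinite transform)")
    if tail not in ("greater", "less", "two-sided"):
        raise UsageError(f"unknown tail {tail!r}")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if tail == "greater":
        p = float(sps.norm.sf(z))
    elif tail == "less":
        p = float(sps.norm.cdf(z))
    else:
        p = 2.0 * float(sps.norm.sf(abs(z)))
    return FisherZResult(r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p=p, tail=tail)
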