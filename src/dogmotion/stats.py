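"""Group-level comparison machinery: rank tests, effect sizes, power.

The cohorts are small (a dozen subjects per group) and most movement
parameters are far from normal, so location differences are tested with
the Mann-Whitney U test.  Each comparison also reports Cohen's d (pooled
SD) and the post-hoc power of a two-sample test at that effect size;
differences whose power falls below 0.80 are flagged as disregarded
rather than dropped, so the full table remains inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trajectory import SubjectMeta

__all__ = [
    "ComparisonRow",
    "DemographicTestResult",
    "DemographicsSummary",
    "COMPARISON_VARIABLES",
    "POWER_THRESHOLD",
    "mann_whitney_u",
    "cohens_d_pooled",
    "posthoc_power",
    "fisher_exact_2x2",
    "phi_coefficient",
    "summarize_demographics",
    "compare_groups",
]

#: Differences with post-hoc power below this are flagged as disregarded.
POWER_THRESHOLD = 0.80

#: Variables compared between groups, in reporting order.  Normalized
#: distance and speed stand in for their absolute counterparts; turn_total
#: aggregates the four sharpness bins.
COMPARISON_VARIABLES = [
    "n_distance",
    "turn30_60",
    "turn60_90",
    "turn90_120",
    "turn120",
    "iu",
    "number_of_points",
    "n_average_speed",
    "st",
    "msd_rate",
    "si",
    "fd",
    "turn_total",
]


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    n_h: int
    n_c: int
    mean_h: float
    sd_h: float
    mean_c: float
    sd_c: float
    u: float
    p: float
    d: float
    power: float
    disregarded: bool
    untestable: bool = False


@dataclass(frozen=True)
class DemographicTestResult:
    factor: str
    test: str  # "mann_whitney" or "fisher_exact"
    statistic: float  # U, or the odds ratio
    p: float
    phi: float | None = None  # categorical factors only


@dataclass(frozen=True)
class DemographicsSummary:
    tests: list[DemographicTestResult]
    continuous: pd.DataFrame  # per group: median, sd, min, max for age/weight
    counts: pd.DataFrame  # per group: sex and neutered counts


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks.

    Returns ``U = min(U_a, U_b)`` from the midrank sums and the two-tailed
    p-value: exact by enumeration of the rank distribution when the pooled
    sample is small (n1 + n2 <= 12) and untied, otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney_u: both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) == 1:
        # every observation tied: midranks make U exactly n1*n2/2, no evidence
        return a.size * b.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return u, float(min(res.pvalue, 1.0))


def cohens_d_pooled(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized mean difference with root-mean-square pooled SD.

    ``(m1 - m2) / sqrt((sd1^2 + sd2^2) / 2)`` — the equal-n pooling that a
    balanced two-group design reduces to.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("cohens_d_pooled undefined when both SDs are 0")
    return (mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def posthoc_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test at effect size |d|.

    Uses the noncentral-t distribution with noncentrality
    ``d * sqrt(n1 n2 / (n1 + n2))`` on ``n1 + n2 - 2`` degrees of freedom.
    At d = 0 the power equals alpha, and it increases monotonically in |d|
    and in sample size.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    d = abs(float(d))
    if d == 0:
        return alpha
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.isf(alpha / 2.0, df)
    upper = sps.nct.sf(tcrit, df, ncp)
    lower = sps.nct.cdf(-tcrit, df, ncp)
    # the far tail opposite the shift can underflow to NaN; it is negligible
    if not np.isfinite(lower):
        lower = 0.0
    if not np.isfinite(upper):
        upper = 0.0
    return float(min(max(upper + lower, 0.0), 1.0))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 contingency table (two-tailed).

    The two-tailed p sums the hypergeometric probabilities of all tables
    with the observed margins that are no more probable than the observed
    one.  Returns (odds ratio, p).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("fisher_exact_2x2: zero margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def phi_coefficient(table) -> float:
    """Phi association coefficient of a 2x2 table, in [-1, 1].

    ``(ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))`` — equal to the Pearson
    correlation of the two binary indicator variables.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    (a, b), (c, d) = t
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ValueError("phi_coefficient: zero margin")
    return float((a * d - b * c) / np.sqrt(denom))


def summarize_demographics(metas: list[SubjectMeta]) -> DemographicsSummary:
    """Demographic matching checks between the case and control groups.

    Continuous factors (age, weight) get per-group median/SD/min/max and a
    Mann-Whitney test; categorical factors (sex, neutered) get Fisher's
    exact test plus the phi coefficient.
    """
    df = pd.DataFrame(
        {
            "group": [m.group for m in metas],
            "sex": [m.sex for m in metas],
            "age": [m.age for m in metas],
            "weight": [m.weight for m in metas],
            "neutered": [m.neutered for m in metas],
        }
    )
    groups = set(df["group"])
    if groups != {"H", "C"}:
        raise ValueError(f"need both H and C groups, got {sorted(groups)}")
    h = df[df["group"] == "H"]
    c = df[df["group"] == "C"]

    cont_rows = []
    tests: list[DemographicTestResult] = []
    for factor in ("age", "weight"):
        for name, g in (("H", h), ("C", c)):
            cont_rows.append(
                {
                    "factor": factor,
                    "group": name,
                    "median": float(g[factor].median()),
                    "sd": float(g[factor].std(ddof=1)),
                    "min": float(g[factor].min()),
                    "max": float(g[factor].max()),
                }
            )
        u, p = mann_whitney_u(h[factor].to_numpy(), c[factor].to_numpy())
        tests.append(DemographicTestResult(factor, "mann_whitney", u, p))

    count_rows = []
    for factor, positive in (("sex", "m"), ("neutered", True)):
        table = np.array(
            [
                [(h[factor] == positive).sum(), (h[factor] != positive).sum()],
                [(c[factor] == positive).sum(), (c[factor] != positive).sum()],
            ]
        )
        count_rows.append(
            {
                "factor": factor,
                "h_pos": int(table[0, 0]),
                "h_neg": int(table[0, 1]),
                "c_pos": int(table[1, 0]),
                "c_neg": int(table[1, 1]),
            }
        )
        odds, p = fisher_exact_2x2(table)
        tests.append(DemographicTestResult(factor, "fisher_exact", odds, p, phi_coefficient(table)))

    return DemographicsSummary(
        tests=tests,
        continuous=pd.DataFrame(cont_rows),
        counts=pd.DataFrame(count_rows),
    )


def compare_groups(
    metrics: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    power_threshold: float = POWER_THRESHOLD,
) -> list[ComparisonRow]:
    """Per-variable group comparison of a per-subject metrics table.

    ``metrics`` must carry a ``group`` column ('H'/'C') and one column per
    variable.  Missing (NaN) metric values are excluded per variable;
    a variable with fewer than two observations in either group is flagged
    untestable.  Cohen's d is computed from the sample means and (n-1)
    standard deviations; its sign is H minus C.
    """
    if variables is None:
        variables = [v for v in COMPARISON_VARIABLES if v in metrics.columns]
    if not set(metrics["group"]) >= {"H", "C"}:
        raise ValueError("metrics table must contain both H and C groups")
    rows: list[ComparisonRow] = []
    for var in variables:
        hv = metrics.loc[metrics["group"] == "H", var].dropna().to_numpy(dtype=float)
        cv = metrics.loc[metrics["group"] == "C", var].dropna().to_numpy(dtype=float)
        mean_h, mean_c = (float(v.mean()) if len(v) else float("nan") for v in (hv, cv))
        sd_h, sd_c = (float(v.std(ddof=1)) if len(v) > 1 else float("nan") for v in (hv, cv))
        if len(hv) < 2 or len(cv) < 2:
            rows.append(
                ComparisonRow(
                    var, len(hv), len(cv), mean_h, sd_h, mean_c, sd_c,
                    float("nan"), float("nan"), float("nan"), float("nan"),
                    disregarded=True, untestable=True,
                )
            )
            continue
        u, p = mann_whitney_u(hv, cv)
        if sd_h == 0 and sd_c == 0:
            d = 0.0
        else:
            d = float(cohens_d_pooled(mean_h, sd_h, mean_c, sd_c))
        power = posthoc_power(d, len(hv), len(cv), alpha=alpha)
        rows.append(
            ComparisonRow(
                var, len(hv), len(cv), mean_h, sd_h, mean_c, sd_c,
                u, p, d, power, disregarded=power < power_threshold,
            )
        )
    return rows


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a DataFrame in reporting order."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "n_h": r.n_h,
                "n_c": r.n_c,
                "mean_h": r.mean_h,
                "sd_h": r.sd_h,
                "mean_c": r.mean_c,
                "sd_c": r.sd_c,
                "u": r.u,
                "p": r.p,
                "d": r.d,
                "power": r.power,
                "disregarded": r.disregarded,
                "untestable": r.untestable,
            }
            for r in rows
        ]
    )
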