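"""Analysis layer: zone summaries, trend diagnostics, group tests,
factorial ANOVA with Tukey follow-up, and noncentral-F power analysis.

The power computations follow the fixed-effects ANOVA convention for
special/main effects: with Cohen's effect size f = sqrt(SS_effect /
SS_error), the noncentrality parameter is lambda = f^2 * N and the
denominator degrees of freedom are N - k for k design cells, so

    power = P( F'(df_num, N - k, lambda) > F_crit(alpha; df_num, N - k) ).

A-priori sample sizes are found by incrementing N from the smallest
feasible value until the target power is reached.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.outliers_influence import OLSInfluence

from .session import Session, TaskTimeline, Zone, zone_of

ZONES = (Zone.PRE_GRASP, Zone.GRASP, Zone.POST_GRASP)


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


# ---------------------------------------------------------------------------
# Zone failure summaries
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SubjectZoneSummary:
    n_tasks: int
    mean_overall: float
    sd_overall: float
    mean_by_zone: dict[Zone, float]
    sd_by_zone: dict[Zone, float]
    #: zones x bins matrix of mean failure counts on zone-normalized time
    hist: np.ndarray


@dataclasses.dataclass
class ZoneSummary:
    n_bins: int
    per_subject: dict[str, SubjectZoneSummary]


def zone_failure_summary(
    sessions_by_subject: Mapping[str, Sequence[Session]], n_bins: int = 10
) -> ZoneSummary:
    """Per-subject failure statistics by task zone and normalized time.

    Each failure is assigned to the zone of its enclosing task; its
    position within the zone is normalized by the zone duration and binned
    into ``n_bins`` bins, making task durations comparable.  Means and SDs
    are over tasks.
    """
    per_subject: dict[str, SubjectZoneSummary] = {}
    for subject, sessions in sessions_by_subject.items():
        per_task_total: list[int] = []
        per_task_zone: dict[Zone, list[int]] = {z: [] for z in ZONES}
        hist = np.zeros((len(ZONES), n_bins))
        n_tasks = 0
        for session in sessions:
            for task in session.tasks:
                for zone in ZONES:
                    z0, z1 = task.zone_bounds(zone)
                    if z1 - z0 <= 0:
                        raise StatsError("zero-duration zone")
                n_tasks += 1
                counts = {z: 0 for z in ZONES}
                for ev in session.failures:
                    if not task.t_start <= ev.time <= task.t_end:
                        continue
                    zone = zone_of(ev.time, task)
                    counts[zone] += 1
                    z0, z1 = task.zone_bounds(zone)
                    frac = (ev.time - z0) / (z1 - z0)
                    b = min(int(frac * n_bins), n_bins - 1)
                    hist[ZONES.index(zone), b] += 1
                per_task_total.append(sum(counts.values()))
                for z in ZONES:
                    per_task_zone[z].append(counts[z])
        if n_tasks == 0:
            raise StatsError(f"subject {subject} has no tasks")
        per_subject[subject] = SubjectZoneSummary(
            n_tasks=n_tasks,
            mean_overall=float(np.mean(per_task_total)),
            sd_overall=float(np.std(per_task_total, ddof=1)) if n_tasks > 1 else 0.0,
            mean_by_zone={z: float(np.mean(per_task_zone[z])) for z in ZONES},
            sd_by_zone={
                z: float(np.std(per_task_zone[z], ddof=1)) if n_tasks > 1 else 0.0
                for z in ZONES
            },
            hist=hist / n_tasks,
        )
    return ZoneSummary(n_bins=n_bins, per_subject=per_subject)


# ---------------------------------------------------------------------------
# Least-squares trend with Cook's distances
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TrendDiagnostics:
    slope: float
    intercept: float
    cooks_d: np.ndarray
    residuals: np.ndarray


def trend_with_cooks(
    x: Sequence[float], y: Sequence[float]
) -> TrendDiagnostics:
    """Ordinary least-squares line through (x, y) with per-point Cook's
    distances, the standard influence measure for least-squares fits."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise StatsError("at least 3 points required")
    if np.ptp(x) == 0:
        raise StatsError("all x values equal: singular fit")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    if res.ssr <= 1e-12 * max(1.0, float(y @ y)):
        # perfect fit: no point moves the line, influence is zero
        cooks = np.zeros_like(y)
    else:
        cooks = OLSInfluence(res).cooks_distance[0]
    return TrendDiagnostics(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        cooks_d=np.asarray(cooks, dtype=float),
        residuals=np.asarray(res.resid, dtype=float),
    )


# ---------------------------------------------------------------------------
# Group comparison: Shapiro-Wilk + Wilcoxon rank-sum
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GroupComparison:
    shapiro_p_a: float
    shapiro_p_b: float
    wilcoxon_w: float  # rank-sum of the first group
    wilcoxon_p: float


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Normality check per group, then a two-sided Wilcoxon rank-sum test.

    The rank-sum statistic W is reported for the first group; the p-value
    is exact for combined sample sizes up to 25 and uses the
    continuity-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise StatsError("each group needs at least 3 observations")
    method = "exact" if a.size + b.size <= 25 else "asymptotic"
    mwu = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(mwu.statistic) + a.size * (a.size + 1) / 2.0
    return GroupComparison(
        shapiro_p_a=float(sps.shapiro(a).pvalue),
        shapiro_p_b=float(sps.shapiro(b).pvalue),
        wilcoxon_w=w,
        wilcoxon_p=float(mwu.pvalue),
    )


# ---------------------------------------------------------------------------
# Factorial ANOVA on BER tables + Tukey HSD
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AnovaReport:
    #: three-way effects: name -> (F, df_num, df_den, p)
    effects: dict[str, tuple[float, int, int, float]]
    ss: dict[str, float]  # sums of squares incl. "Residual"
    oneway_f: float
    oneway_df: tuple[int, int]
    oneway_p: float
    tukey: pd.DataFrame  # pairwise feature-type comparisons


REQUIRED_COLUMNS = ("subject", "feature_type", "window", "overlap", "ber")


def anova_ber(table: pd.DataFrame) -> AnovaReport:
    """Three-way fixed-effects ANOVA of BER on feature type, window length
    and overlap (all interactions included), plus the one-way reduction to
    feature type with a Tukey HSD follow-up.

    The table must be the balanced full factorial: every subject crossed
    with all 18 feature-set combinations exactly once.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise StatsError(f"BER table missing columns {missing}")
    cells = table.groupby(
        ["subject", "feature_type", "window", "overlap"], observed=True
    ).size()
    n_ft = table["feature_type"].nunique()
    n_w = table["window"].nunique()
    n_ov = table["overlap"].nunique()
    n_subj = table["subject"].nunique()
    if (cells != 1).any() or len(cells) != n_subj * n_ft * n_w * n_ov:
        raise StatsError("BER table is not a balanced full factorial")

    df = table.copy()
    df["window"] = df["window"].astype(str)
    model = smf.ols(
        "ber ~ C(feature_type) * C(window) * C(overlap)", data=df
    ).fit()
    tab = sm.stats.anova_lm(model, typ=2)

    def _clean(name: str) -> str:
        return (
            name.replace("C(feature_type)", "feature_type")
            .replace("C(window)", "window")
            .replace("C(overlap)", "overlap")
        )

    df_resid = int(tab.loc["Residual", "df"])
    # A (near-)constant response makes every SS rounding noise; an effect
    # whose SS vanishes at the response scale explains nothing, so its F is
    # 0 by convention.
    zero_tol = 1e-12 * float((df["ber"] ** 2).sum() + 1.0)
    effects: dict[str, tuple[float, int, int, float]] = {}
    ss: dict[str, float] = {}
    for name, row in tab.iterrows():
        ss[_clean(str(name))] = float(row["sum_sq"])
        if name == "Residual":
            continue
        f_val = float(row["F"])
        p_val = float(row["PR(>F)"])
        if float(row["sum_sq"]) <= zero_tol:
            f_val, p_val = 0.0, 1.0
        effects[_clean(str(name))] = (f_val, int(row["df"]), df_resid, p_val)

    oneway = smf.ols("ber ~ C(feature_type)", data=df).fit()
    otab = sm.stats.anova_lm(oneway, typ=2)
    oneway_f = float(otab.loc["C(feature_type)", "F"])
    oneway_df = (
        int(otab.loc["C(feature_type)", "df"]),
        int(otab.loc["Residual", "df"]),
    )
    oneway_p = float(otab.loc["C(feature_type)", "PR(>F)"])
    if float(otab.loc["C(feature_type)", "sum_sq"]) <= zero_tol:
        oneway_f, oneway_p = 0.0, 1.0

    hsd = pairwise_tukeyhsd(df["ber"], df["feature_type"])
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=hsd.summary().data[0]
    )
    return AnovaReport(
        effects=effects,
        ss=ss,
        oneway_f=oneway_f,
        oneway_df=oneway_df,
        oneway_p=oneway_p,
        tukey=tukey,
    )


# ---------------------------------------------------------------------------
# Noncentral-F power analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PowerQuery:
    f: float  # Cohen's effect size
    alpha: float
    n_total: int
    df_num: int
    n_groups: int

    def __post_init__(self) -> None:
        if self.f < 0:
            raise StatsError("effect size f must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise StatsError("alpha must lie in (0, 1)")
        if self.n_total <= self.n_groups:
            raise StatsError("n_total must exceed the number of groups")


@dataclasses.dataclass(frozen=True)
class PowerResult:
    noncentrality: float  # lambda = f^2 * N
    df_den: int  # N - n_groups
    power: float


def cohens_f_from_ss(ss_effect: float, ss_error: float) -> float:
    """Cohen's f from ANOVA sums of squares: sqrt(SS_effect / SS_error)."""
    if ss_error <= 0:
        raise StatsError("ss_error must be positive")
    if ss_effect < 0:
        raise StatsError("ss_effect must be non-negative")
    return float(np.sqrt(ss_effect / ss_error))


def posthoc_power(q: PowerQuery) -> PowerResult:
    """Achieved power of a fixed-effects (main/special) F test."""
    lam = q.f**2 * q.n_total
    df_den = q.n_total - q.n_groups
    f_crit = sps.f.ppf(1.0 - q.alpha, q.df_num, df_den)
    power = float(1.0 - sps.ncf.cdf(f_crit, q.df_num, df_den, lam))
    return PowerResult(noncentrality=lam, df_den=df_den, power=power)


def required_sample_size(
    f: float,
    alpha: float,
    df_num: int,
    n_groups: int,
    target_power: float = 0.8,
) -> int:
    """Smallest total N whose post-hoc power reaches ``target_power``.

    Plain integer search from the smallest feasible design upward; no
    rounding to group-size multiples.
    """
    if not 0.0 < target_power < 1.0:
        raise StatsError("target power must lie in (0, 1)")
    if f <= 0.0:
        if target_power > alpha:
            raise StatsError(
                "zero effect size: target power above alpha is unattainable"
            )
        return n_groups + df_num + 1
    n = n_groups + df_num + 1
    while True:
        q = PowerQuery(
            f=f, alpha=alpha, n_total=n, df_num=df_num, n_groups=n_groups
        )
        if posthoc_power(q).power >= target_power:
            return n
        n += 1
        if n > 10_000_000:  # pragma: no cover
            raise StatsError("sample-size search did not converge")
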