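"""Two-group statistical battery.

Group comparisons are assumption-gated: Shapiro-Wilk normality in each
group and Levene homogeneity (median-centred) are checked at the gate
alpha; when both hold a pooled-variance Student t-test is used with
Cohen's d = 2t/sqrt(df), otherwise a Mann-Whitney U with tie-corrected
normal approximation Z and effect size r = |Z|/sqrt(n1+n2).

Also provided: the pooled t-test recomputed from printed group
summaries, Pearson correlations, a 2 (group, between) x 2 (task,
within) mixed ANOVA with classical eta squared, and a Bonferroni screen
over many variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import ValidationError


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str  # "student_t" | "mann_whitney"
    statistic: float  # t or U
    p: float
    effect: float  # Cohen's d (t) or r (U)
    df: Optional[int] = None  # t only
    z: Optional[float] = None  # Mann-Whitney only
    group_summaries: tuple[GroupSummary, GroupSummary] = None  # type: ignore[assignment]
    gate_normal: Optional[bool] = None
    gate_homogeneous: Optional[bool] = None


@dataclass(frozen=True)
class SummaryTResult:
    t: float
    df: int
    p: float
    d: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p: float
    n: int


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: int
    df_den: int
    p: float
    eta2: float


@dataclass(frozen=True)
class MixedAnovaResult:
    task: AnovaEffect
    group: AnovaEffect
    interaction: AnovaEffect
    sphericity_ok: bool
    n_complete: int
    posthoc: dict[str, float]  # Bonferroni-adjusted paired task contrasts


def _summary(x: np.ndarray) -> GroupSummary:
    return GroupSummary(float(np.mean(x)), float(np.std(x, ddof=1)), len(x))


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> float:
    """U statistic for the first sample: pairwise wins plus half-ties.

    Computed via the rank-sum identity; equals the brute-force count of
    pairs (i, j) with a_i > b_j plus half the ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def _mw_sigma(a: np.ndarray, b: np.ndarray) -> float:
    """SD of U under H0 with tie correction."""
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(var)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    variable: str = "",
    force: Optional[str] = None,
) -> ComparisonResult:
    """Assumption-gated two-group comparison.

    ``force`` overrides the gate with "student_t" or "mann_whitney"
    (used by the screening and simulation code paths).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each sample needs n >= 3")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValidationError(
            f"variable {variable!r}: degenerate samples (all values identical)"
        )

    gate_normal = gate_homog = None
    if force is None:
        gate_normal = all(
            np.ptp(x) > 0 and sps.shapiro(x).pvalue > alpha for x in (a, b)
        )
        gate_homog = bool(sps.levene(a, b, center="median").pvalue > alpha)
        test = "student_t" if (gate_normal and gate_homog) else "mann_whitney"
    else:
        if force not in ("student_t", "mann_whitney"):
            raise ValidationError(f"unknown forced test {force!r}")
        test = force

    summaries = (_summary(a), _summary(b))
    if test == "student_t":
        res = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
        t = float(res.statistic)
        return ComparisonResult(
            variable=variable,
            test="student_t",
            statistic=t,
            df=df,
            p=float(res.pvalue),
            effect=2 * t / math.sqrt(df),
            group_summaries=summaries,
            gate_normal=gate_normal,
            gate_homogeneous=gate_homog,
        )

    u = mann_whitney_u(a, b)
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    sigma = _mw_sigma(a, b)
    z = (u - mu) / sigma if sigma > 0 else 0.0
    # exact p for small untied samples, normal approximation otherwise
    pooled_ties = len(np.unique(pooled)) < len(pooled)
    if max(n1, n2) <= 8 and not pooled_ties:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return ComparisonResult(
        variable=variable,
        test="mann_whitney",
        statistic=u,
        z=z,
        p=p,
        effect=abs(z) / math.sqrt(n1 + n2),
        group_summaries=summaries,
        gate_normal=gate_normal,
        gate_homogeneous=gate_homog,
    )


def t_from_summaries(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> SummaryTResult:
    """Pooled-variance two-sample t from printed group summaries.

    Cohen's d follows the d = 2t/sqrt(df) convention.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = float(2 * sps.t.sf(abs(t), df))
    return SummaryTResult(t=t, df=df, p=p, d=2 * t / math.sqrt(df))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("samples must have equal length")
    if len(x) < 3:
        raise ValidationError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance sample")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p=float(res.pvalue), n=len(x))


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    group: str = "group",
    task: str = "task",
) -> MixedAnovaResult:
    """2x2 mixed ANOVA (group between, task within) on complete cases.

    Eta squared is classical: SS_effect / SS_total, with SS_total taken
    directly from the complete-case data. With two within-subject levels
    sphericity holds by construction and is reported as satisfied.
    Post-hoc: Bonferroni-adjusted paired t task contrasts, overall and
    within each group.
    """
    df = table[[subject, group, task, dv]].dropna().copy()
    counts = df.groupby(subject)[task].nunique()
    complete = counts[counts == 2].index
    df = df[df[subject].isin(complete)]
    n_complete = df[subject].nunique()
    per_group = df.groupby(group)[subject].nunique()
    if len(per_group) != 2 or (per_group < 2).any():
        raise ValidationError("need >= 2 complete subjects in each of two groups")

    values = df[dv].to_numpy(dtype=float)
    ss_total = float(np.sum((values - values.mean()) ** 2))
    if ss_total == 0:
        # constant response: all effects are exactly zero
        eff = AnovaEffect(F=0.0, df_num=1, df_den=n_complete - 2, p=1.0, eta2=0.0)
        return MixedAnovaResult(
            task=eff, group=eff, interaction=eff, sphericity_ok=True,
            n_complete=n_complete,
            posthoc={"task_overall": 1.0},
        )

    aov = pg.mixed_anova(
        data=df, dv=dv, within=task, between=group, subject=subject
    ).set_index("Source")

    def effect(source: str) -> AnovaEffect:
        row = aov.loc[source]
        return AnovaEffect(
            F=float(row["F"]),
            df_num=int(row["DF1"]),
            df_den=int(row["DF2"]),
            p=float(row["p_unc"]),
            eta2=float(row["SS"]) / ss_total,
        )

    task_name = aov.index[1]  # pingouin labels the within effect by its column
    posthoc: dict[str, float] = {}
    tasks = sorted(df[task].unique())
    wide = df.pivot(index=subject, columns=task, values=dv)
    contrasts: list[tuple[str, pd.DataFrame]] = [("task_overall", wide)]
    groups_of = df.drop_duplicates(subject).set_index(subject)[group]
    for g in sorted(df[group].unique()):
        contrasts.append((f"task_within_{g}", wide[groups_of.reindex(wide.index) == g]))
    m = len(contrasts)
    for name, sub in contrasts:
        diff = sub[tasks[0]] - sub[tasks[1]]
        if np.ptp(diff) == 0:
            p_raw = 1.0
        else:
            p_raw = float(sps.ttest_rel(sub[tasks[0]], sub[tasks[1]]).pvalue)
        posthoc[name] = min(1.0, p_raw * m)

    return MixedAnovaResult(
        task=effect(task_name),
        group=effect(aov.index[0]),
        interaction=effect("Interaction"),
        sphericity_ok=True,
        n_complete=n_complete,
        posthoc=posthoc,
    )


@dataclass(frozen=True)
class ScreenEntry:
    variable: str
    result: Optional[ComparisonResult]
    p_adjusted: Optional[float]
    significant_raw: Optional[bool]
    significant_adjusted: Optional[bool]
    note: str = ""


@dataclass(frozen=True)
class ScreenReport:
    alpha: float
    n_variables: int
    threshold: float  # alpha / m
    entries: list[ScreenEntry] = field(default_factory=list)

    @property
    def survivors(self) -> list[str]:
        return [e.variable for e in self.entries if e.significant_adjusted]


def bonferroni_screen(
    table: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    alpha: float = 0.05,
) -> ScreenReport:
    """Gated two-group comparison per variable with Bonferroni adjustment.

    Adjusted p = min(1, p * m); a raw-significant variable survives iff
    its adjusted p stays below alpha. Degenerate variables (constant in
    both groups) are reported with a note instead of a result.
    """
    if len(variables) < 1:
        raise ValidationError("need at least one variable to screen")
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValidationError(f"screen needs exactly two groups, got {groups}")
    m = len(variables)
    entries: list[ScreenEntry] = []
    for var in variables:
        a = table.loc[table[group_col] == groups[0], var].dropna()
        b = table.loc[table[group_col] == groups[1], var].dropna()
        try:
            res = compare_groups(a, b, alpha=alpha, variable=var)
        except ValidationError as exc:
            entries.append(
                ScreenEntry(var, None, None, None, None, note=str(exc))
            )
            continue
        p_adj = min(1.0, res.p * m)
        entries.append(
            ScreenEntry(
                variable=var,
                result=res,
                p_adjusted=p_adj,
                significant_raw=res.p < alpha,
                significant_adjusted=p_adj < alpha,
            )
        )
    return ScreenReport(alpha=alpha, n_variables=m, threshold=alpha / m, entries=entries)


def two_sample_t_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Closed-form power of the pooled two-sample t-test at effect size d."""
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
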