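"""Age-group analysis: mixed between(group) x within(time) ANOVA with
partial eta-squared, Scheffe post hoc contrasts, Cohen's d, and first-to-
last change-score comparisons.

The response entering the ANOVA is the day-mean score (the average of the
two daily trials) per subject, so the within factor is testing day.  The
design is "split-plot": subjects are nested in age group, and every
retained subject has a complete day-mean vector.  Sums of squares use the
classical cell-count-weighted decomposition (groups may be unbalanced,
22/20/23 in the emulated design; the within factor is complete by
construction):

    SS_between-subjects = SS_group + SS_subjects-within-group
    SS_within-subjects  = SS_time + SS_group-x-time + SS_residual

Partial eta-squared is SS_effect / (SS_effect + SS_error-for-that-effect).
When the within factor has more than two levels, Greenhouse-Geisser
epsilon (from the pooled within-group covariance of the repeated
measures) corrects the time and interaction p-values; epsilon is reported
alongside.

Scheffe's method tests every pairwise group contrast against the criterion
(g - 1) F_{alpha; g-1, df_between-error}, which is coherent with the
omnibus between-group F: no contrast can be significant unless the
omnibus is.  Cohen's d uses the pooled SD of subject-level means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .study_data import LongDataset, day_means


@dataclass(frozen=True)
class EffectRow:
    name: str  # group | time | group_x_time
    ss_effect: float
    ss_error: float
    df_num: int
    df_den: int
    F: float
    p: float
    partial_eta_sq: float


@dataclass
class RMAnovaResult:
    effects: list[EffectRow]
    n_per_group: dict[str, int]
    n_days: int
    gg_epsilon: float | None  # None when the within factor has 2 levels
    sphericity_correction: str  # "none" | "greenhouse-geisser"
    subject_means: pd.DataFrame  # columns: subject, group, mean (across days)
    ms_error_between: float
    df_error_between: int

    def effect(self, name: str) -> EffectRow:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str
    mean_diff: float
    cohens_d: float
    p_scheffe: float
    band: str


def eta_sq_band(eta_p2: float) -> str:
    """Partial eta-squared band: < 0.06 small, [0.06, 0.14) moderate,
    >= 0.14 large."""
    if eta_p2 < 0.06:
        return "small"
    if eta_p2 < 0.14:
        return "moderate"
    return "large"


def cohens_d_band(d: float) -> str:
    """|d| band: < 0.2 trivial, [0.2, 0.5) small, [0.5, 0.8) moderate,
    >= 0.8 large."""
    a = abs(d)
    if a < 0.2:
        return "trivial"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "moderate"
    return "large"


def _complete_day_matrix(ds: LongDataset, test: str) -> pd.DataFrame:
    """Subjects x days matrix of day means, complete cases only, with the
    group label attached."""
    dm = day_means(ds, test)
    wide = dm.pivot_table(index="subject", columns="day", values="score")
    wide = wide.dropna()
    groups = dm.drop_duplicates("subject").set_index("subject")["group"]
    wide.insert(0, "group", groups.reindex(wide.index))
    return wide


def _gg_epsilon(resid: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled covariance of the
    repeated measures (rows: subjects, group-mean-centered)."""
    s = np.cov(resid, rowvar=False, ddof=1)
    k = s.shape[0]
    mean_diag = np.trace(s) / k
    grand = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (
        np.sum(s * s) - 2 * k * np.sum(row_means**2) + k * k * grand * grand
    )
    if den <= 0:
        return 1.0
    eps = num / den
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova(ds: LongDataset, test: str) -> RMAnovaResult:
    """Mixed two-way (group x day) ANOVA on day-mean scores.

    Requires >= 2 groups with >= 2 subjects each and >= 2 days; subjects
    with an incomplete day-mean vector are dropped (complete-case).
    """
    wide = _complete_day_matrix(ds, test)
    day_cols = [c for c in wide.columns if c != "group"]
    k = len(day_cols)
    if k < 2:
        raise InsufficientDataError(f"{test}: need >= 2 days")
    counts = wide["group"].value_counts()
    if len(counts) < 2:
        raise InsufficientDataError(f"{test}: need >= 2 groups")
    if (counts < 2).any():
        small = list(counts[counts < 2].index)
        raise InsufficientDataError(f"{test}: groups with < 2 subjects: {small}")

    y = wide[day_cols].to_numpy(dtype=float)  # N x k
    glabels = wide["group"].to_numpy()
    groups = sorted(counts.index)
    n_tot = y.shape[0]
    grand = y.mean()

    subj_means = y.mean(axis=1)
    day_means_all = y.mean(axis=0)
    ss_total = float(np.sum((y - grand) ** 2))
    ss_between_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_within_subj = ss_total - ss_between_subj

    ss_group = 0.0
    ss_cells = 0.0
    for g in groups:
        mask = glabels == g
        gm = y[mask].mean()
        ss_group += k * mask.sum() * (gm - grand) ** 2
        cell_means = y[mask].mean(axis=0)
        ss_cells += mask.sum() * float(np.sum((cell_means - grand) ** 2))
    ss_err_between = ss_between_subj - ss_group
    ss_time = n_tot * float(np.sum((day_means_all - grand) ** 2))
    ss_interaction = ss_cells - ss_group - ss_time
    ss_err_within = ss_within_subj - ss_time - ss_interaction

    g = len(groups)
    df_group, df_eb = g - 1, n_tot - g
    df_time = k - 1
    df_int = (g - 1) * (k - 1)
    df_ew = (n_tot - g) * (k - 1)

    # Greenhouse-Geisser on group-mean-centered repeated measures
    if k > 2:
        centered = np.empty_like(y)
        for gl in groups:
            mask = glabels == gl
            centered[mask] = y[mask] - y[mask].mean(axis=0)
        eps: float | None = _gg_epsilon(centered)
        correction = "greenhouse-geisser"
    else:
        eps = None
        correction = "none"

    def _row(name, ss_eff, ss_err, dfn, dfd, corrected):
        ms_eff = ss_eff / dfn
        ms_err = ss_err / dfd
        f = ms_eff / ms_err if ms_err > 0 else np.inf
        if corrected and eps is not None:
            p = float(stats.f.sf(f, dfn * eps, dfd * eps))
        else:
            p = float(stats.f.sf(f, dfn, dfd))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return EffectRow(
            name=name,
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
            df_num=dfn,
            df_den=dfd,
            F=float(f),
            p=p,
            partial_eta_sq=float(eta),
        )

    effects = [
        _row("group", ss_group, ss_err_between, df_group, df_eb, False),
        _row("time", ss_time, ss_err_within, df_time, df_ew, True),
        _row("group_x_time", ss_interaction, ss_err_within, df_int, df_ew, True),
    ]
    subject_means = pd.DataFrame(
        {"subject": wide.index, "group": glabels, "mean": subj_means}
    ).reset_index(drop=True)
    return RMAnovaResult(
        effects=effects,
        n_per_group={g_: int(counts[g_]) for g_ in groups},
        n_days=k,
        gg_epsilon=eps,
        sphericity_correction=correction,
        subject_means=subject_means,
        ms_error_between=float(ss_err_between / df_eb),
        df_error_between=df_eb,
    )


def _scheffe_contrasts(values: pd.DataFrame) -> list[Contrast]:
    """All pairwise Scheffe contrasts on subject-level values.

    ``values`` has columns ``group`` and ``value``.  The error term is the
    pooled within-group mean square on the same scale.
    """
    groups = sorted(values["group"].unique())
    g = len(groups)
    if g < 2:
        raise InsufficientDataError("need >= 2 groups for contrasts")
    n_tot = len(values)
    df_err = n_tot - g
    msw = 0.0
    stats_by_group = {}
    for gl in groups:
        v = values.loc[values["group"] == gl, "value"].to_numpy()
        stats_by_group[gl] = (len(v), v.mean(), np.var(v, ddof=1) if len(v) > 1 else 0.0)
        msw += float(np.sum((v - v.mean()) ** 2))
    msw /= df_err
    out = []
    for i in range(g):
        for j in range(i + 1, g):
            na, ma, va = stats_by_group[groups[i]]
            nb, mb, vb = stats_by_group[groups[j]]
            diff = ma - mb
            if msw > 0:
                f_contrast = diff**2 / (msw * (1.0 / na + 1.0 / nb))
                p = float(stats.f.sf(f_contrast / (g - 1), g - 1, df_err))
            else:
                p = 1.0 if diff == 0 else 0.0
            sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
            d = diff / sp if sp > 0 else 0.0
            out.append(
                Contrast(
                    group_a=groups[i],
                    group_b=groups[j],
                    mean_diff=float(diff),
                    cohens_d=float(d),
                    p_scheffe=p,
                    band=cohens_d_band(d),
                )
            )
    return out


def scheffe_posthoc(result: RMAnovaResult) -> list[Contrast]:
    """Pairwise group contrasts on subject means (averaged across days),
    tested against the Scheffe criterion with the between-subject error
    term of the mixed ANOVA."""
    values = result.subject_means.rename(columns={"mean": "value"})
    return _scheffe_contrasts(values[["group", "value"]])


@dataclass
class ChangeScoreResult:
    per_group: pd.DataFrame  # group, n, mean_change, sd_change
    F: float | None
    df_num: int | None
    df_den: int | None
    p: float | None
    contrasts: list[Contrast]


def change_score_comparison(ds: LongDataset, test: str) -> ChangeScoreResult:
    """Per-group first-to-last improvement with a one-way ANOVA across
    groups.

    The change score is oriented so positive = improvement: day-1 mean
    minus last-day mean for lower-is-better tests, the reverse for
    higher-is-better ones.  With a single group the ANOVA is skipped and
    only descriptives are returned.
    """
    wide = _complete_day_matrix(ds, test)
    day_cols = [c for c in wide.columns if c != "group"]
    first, last = min(day_cols), max(day_cols)
    if first == last:
        raise InsufficientDataError(f"{test}: need >= 2 days for change scores")
    sign = -1.0 if ds.higher_is_better.get(test, False) else 1.0
    change = sign * (wide[first] - wide[last])
    values = pd.DataFrame({"group": wide["group"], "value": change})
    per_group = (
        values.groupby("group")["value"]
        .agg(n="size", mean_change="mean", sd_change=lambda v: np.std(v, ddof=1))
        .reset_index()
    )
    groups = sorted(values["group"].unique())
    if len(groups) < 2:
        return ChangeScoreResult(per_group, None, None, None, None, [])
    samples = [values.loc[values["group"] == g, "value"].to_numpy() for g in groups]
    f_res = stats.f_oneway(*samples)
    contrasts = _scheffe_contrasts(values)
    return ChangeScoreResult(
        per_group=per_group,
        F=float(f_res.statistic),
        df_num=len(groups) - 1,
        df_den=len(values) - len(groups),
        p=float(f_res.pvalue),
        contrasts=contrasts,
    )
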