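"""Learning curves and the habituation (stabilization) decision.

Repeated testing without any intervention produces systematic improvement
(a learning effect) that decays over sessions, together with random error
that shrinks as subjects grow familiar with the task.  Testing is treated
as habituated from the first session after which, for every remaining
consecutive-day comparison, (a) the familywise-adjusted bias p-value is
nonsignificant and (b) the consecutive-day MAPE has stopped moving by more
than a configurable tolerance (default 5 percentage points).

Requiring *all* remaining comparisons to pass — not just the first passing
one — guards against non-monotone random-error sequences, which real
reaction-time data do produce.

Statistical nonsignificance is not evidence of irrelevance: each decision
records the bias point estimates next to the MDC so a practically large
but nonsignificant residual learning effect stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement, error_decomp
from .error_decomp import AnalysisConfig
from .exceptions import InsufficientDataError
from .study_data import LongDataset, day_means, make_pairs


@dataclass
class LearningCurve:
    """Day-level summary plus the consecutive-day bias and MAPE series for
    one test and one group (or 'overall')."""

    test: str
    group: str
    day_stats: pd.DataFrame  # columns: day, mean, sd, sem_of_mean, n
    interday_bias: list[tuple[str, float, float]]  # (label, bias, p_adjusted)
    interday_mape: list[tuple[str, float]]  # (label, mape)
    interday_mdc: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class HabituationDecision:
    test: str
    group: str
    stabilization_day: int | None
    criterion_trace: list[dict]
    alpha_used: float
    mape_tolerance: float


def build_learning_curve(
    ds: LongDataset,
    test: str,
    group: str = "overall",
    cfg: AnalysisConfig | None = None,
    icc_variant: str = "standard_A1",
) -> LearningCurve:
    """Day means/SDs and the consecutive-day bias and MAPE series.

    Bias p-values are adjusted within the curve's own family (the D-1
    consecutive comparisons) using ``cfg.multiplicity``.
    """
    cfg = cfg or AnalysisConfig()
    sub = ds.filter_group(group)
    dm = day_means(sub, test)
    stats_rows = []
    for day, g in dm.groupby("day"):
        scores = g["score"].to_numpy()
        stats_rows.append(
            {
                "day": int(day),
                "mean": float(scores.mean()),
                "sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                "sem_of_mean": (
                    float(np.std(scores, ddof=1) / np.sqrt(len(scores)))
                    if len(scores) > 1
                    else 0.0
                ),
                "n": len(scores),
            }
        )
    day_stats = pd.DataFrame(stats_rows).sort_values("day").reset_index(drop=True)
    if len(day_stats) < 2:
        raise InsufficientDataError(f"{test}: need >= 2 days for a learning curve")

    pairs = [
        p for p in make_pairs(sub, test, "interday") if p.kind == "interday"
    ]
    tests = [error_decomp.paired_bias_test(p) for p in pairs]
    p_adj = error_decomp.adjust_pvalues(
        [t.p_raw for t in tests], method=cfg.multiplicity
    )
    bias_series = [
        (pair.label, t.bias, float(pa))
        for pair, t, pa in zip(pairs, tests, p_adj)
    ]
    mape_series = [(p.label, error_decomp.mape(p)) for p in pairs]
    mdc_series = []
    for p in pairs:
        decomp = agreement.ms_decomposition(p)
        icc = agreement.icc_agreement(decomp, variant=icc_variant)
        est = max(icc.estimate, 0.0)  # clamp: SEM undefined for negative ICC
        mdc_series.append((p.label, agreement.sem_mdc(p, est).mdc))
    return LearningCurve(
        test=test,
        group=group,
        day_stats=day_stats,
        interday_bias=bias_series,
        interday_mape=mape_series,
        interday_mdc=mdc_series,
    )


def detect_stabilization(
    curve: LearningCurve,
    cfg: AnalysisConfig | None = None,
    mape_tolerance: float = 5.0,
) -> HabituationDecision:
    """Earliest day d such that every consecutive comparison from (d, d+1)
    onward has a nonsignificant adjusted bias p AND a MAPE change within
    ``mape_tolerance`` percentage points of the previous comparison.

    The first comparison's random-error criterion is vacuously true (there
    is no previous MAPE to compare with).  Returns ``stabilization_day``
    None when the last comparison still fails.
    """
    cfg = cfg or AnalysisConfig()
    if not curve.interday_bias:
        raise InsufficientDataError("curve has no consecutive-day comparisons")
    mdc_by_label = dict(curve.interday_mdc)
    trace: list[dict] = []
    prev_mape: float | None = None
    for (label, bias, p_adj), (_, mp) in zip(
        curve.interday_bias, curve.interday_mape
    ):
        if p_adj is None or np.isnan(p_adj):
            raise InsufficientDataError(f"{label}: missing adjusted p-value")
        bias_ok = p_adj >= cfg.alpha
        random_ok = prev_mape is None or abs(mp - prev_mape) <= mape_tolerance
        trace.append(
            {
                "label": label,
                "bias": bias,
                "p_adjusted": p_adj,
                "mape": mp,
                "bias_ok": bias_ok,
                "random_error_ok": random_ok,
                "mdc": mdc_by_label.get(label),
                "bias_exceeds_mdc": (
                    abs(bias) > mdc_by_label[label]
                    if label in mdc_by_label
                    else None
                ),
            }
        )
        prev_mape = mp

    ok = [t["bias_ok"] and t["random_error_ok"] for t in trace]
    last_fail = max((i for i, v in enumerate(ok) if not v), default=-1)
    if last_fail == len(ok) - 1:
        day: int | None = None  # the final comparison still fails
    else:
        day = last_fail + 2  # comparison i covers days (i+1, i+2)
    return HabituationDecision(
        test=curve.test,
        group=curve.group,
        stabilization_day=day,
        criterion_trace=trace,
        alpha_used=cfg.alpha,
        mape_tolerance=mape_tolerance,
    )


def recommend_sessions(decisions) -> pd.DataFrame:
    """Summary table of familiarization-session recommendations.

    One row per (test, group) with the stabilization day, plus an
    ``overall`` row carrying the maximum across tests; any undetermined
    decision propagates to an undetermined overall recommendation.
    """
    decisions = list(decisions)
    if not decisions:
        raise InsufficientDataError("no habituation decisions to summarize")
    rows = [
        {
            "test": d.test,
            "group": d.group,
            "recommended_sessions": d.stabilization_day,
            "determined": d.stabilization_day is not None,
        }
        for d in decisions
    ]
    days = [d.stabilization_day for d in decisions]
    overall = None if any(v is None for v in days) else max(days)
    rows.append(
        {
            "test": "overall",
            "group": "overall",
            "recommended_sessions": overall,
            "determined": overall is not None,
        }
    )
    return pd.DataFrame(rows)
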