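"""Assemble reliability report tables (one row per test-retest comparison).

A reliability table has one row per test per comparison — days 1..D for
intraday mode, 1_2 .. (D-1)_D then 1_D for interday mode — each carrying
the two occasion means +/- SD, ICC with 95% CI, SEM, MDC, the bias t-test
with family-wise adjusted p, MAE and MAPE.  Multiplicity is applied across
the whole family of one mode (all tests' comparisons), mirroring the
common "alpha / number-of-tests" practice.

Every number in the rendered table comes from the underlying operations;
the formatting layer only rounds for display (2 decimals, "< 0.001" for
tiny p-values) and keeps raw values in the machine-readable output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import agreement, error_decomp
from .agreement import ICCResult
from .error_decomp import AnalysisConfig, BiasTest
from .study_data import LongDataset, PairedComparison, make_pairs


@dataclass
class ReliabilityRow:
    label: str
    kind: str
    test: str
    n: int
    mean_1: float
    sd_1: float
    mean_2: float
    sd_2: float
    icc: ICCResult
    sem: float
    mdc: float
    bias: BiasTest
    mae: float
    mape: float


def _row_for(
    pair: PairedComparison,
    test: str,
    icc_variant: str,
    sem_basis: str,
) -> ReliabilityRow:
    decomp = agreement.ms_decomposition(pair)
    icc = agreement.icc_agreement(decomp, variant=icc_variant)
    est = max(icc.estimate, 0.0)  # SEM needs ICC in [0, 1]
    sm = agreement.sem_mdc(pair, est, basis=sem_basis)
    bias = error_decomp.paired_bias_test(pair)
    return ReliabilityRow(
        label=pair.label,
        kind=pair.kind,
        test=test,
        n=pair.n,
        mean_1=float(pair.x.mean()),
        sd_1=float(np.std(pair.x, ddof=1)),
        mean_2=float(pair.y.mean()),
        sd_2=float(np.std(pair.y, ddof=1)),
        icc=icc,
        sem=sm.sem,
        mdc=sm.mdc,
        bias=bias,
        mae=error_decomp.mae(pair),
        mape=error_decomp.mape(pair),
    )


def reliability_table(
    ds: LongDataset,
    mode: str,
    cfg: AnalysisConfig | None = None,
    icc_variant: str = "standard_A1",
    sem_basis: str = "diff",
) -> list[ReliabilityRow]:
    """One :class:`ReliabilityRow` per test per comparison of the given
    mode, with bias p-values adjusted across the whole family."""
    cfg = cfg or AnalysisConfig()
    rows: list[ReliabilityRow] = []
    for test in ds.tests:
        for pair in make_pairs(ds, test, mode):
            rows.append(_row_for(pair, test, icc_variant, sem_basis))
    if not rows:
        import warnings

        warnings.warn("empty dataset: reliability table has no rows")
        return rows
    p_adj = error_decomp.adjust_pvalues(
        [r.bias.p_raw for r in rows], method=cfg.multiplicity
    )
    for r, pa in zip(rows, p_adj):
        r.bias.p_adjusted = float(pa)
        r.bias.significant = bool(pa < cfg.alpha)
    return rows


def format_p(p: float) -> str:
    """Display convention for table p-values."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def rows_to_frame(rows: list[ReliabilityRow]) -> pd.DataFrame:
    """Machine-readable tidy frame (raw, unrounded values)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "kind": [r.kind for r in rows],
            "test": [r.test for r in rows],
            "n": [r.n for r in rows],
            "mean_1": [r.mean_1 for r in rows],
            "sd_1": [r.sd_1 for r in rows],
            "mean_2": [r.mean_2 for r in rows],
            "sd_2": [r.sd_2 for r in rows],
            "icc": [r.icc.estimate for r in rows],
            "icc_ci_low": [r.icc.ci_low for r in rows],
            "icc_ci_high": [r.icc.ci_high for r in rows],
            "icc_band": [r.icc.band for r in rows],
            "sem": [r.sem for r in rows],
            "mdc": [r.mdc for r in rows],
            "bias": [r.bias.bias for r in rows],
            "t_stat": [r.bias.t_stat for r in rows],
            "p_raw": [r.bias.p_raw for r in rows],
            "p_adjusted": [r.bias.p_adjusted for r in rows],
            "significant": [r.bias.significant for r in rows],
            "mae": [r.mae for r in rows],
            "mape": [r.mape for r in rows],
        }
    )


def render_display(rows: list[ReliabilityRow]) -> pd.DataFrame:
    """Human-readable table rounded to 2 decimals, p shown as '< 0.001'
    below a thousandth (the raw values live in :func:`rows_to_frame`)."""
    recs = []
    for r in rows:
        ci = (
            f"({r.icc.ci_low:.2f}-{r.icc.ci_high:.2f})"
            if r.icc.ci_low is not None
            else ""
        )
        recs.append(
            {
                "Test": r.label,
                "Mean ± SD (Value 1)": f"{r.mean_1:.1f} ± {r.sd_1:.2f}",
                "Mean ± SD (Value 2)": f"{r.mean_2:.1f} ± {r.sd_2:.2f}",
                "ICC (95% CI)": f"{r.icc.estimate:.2f} {ci}".strip(),
                "SEM": round(r.sem, 2),
                "MDC": round(r.mdc, 2),
                "Systematic bias (level of sig.)": (
                    f"{r.bias.bias:.2f} ({format_p(r.bias.p_adjusted if r.bias.p_adjusted is not None else r.bias.p_raw)})"
                ),
                "MAE": round(r.mae, 2),
                "MAPE": round(r.mape, 2),
            }
        )
    return pd.DataFrame(recs)
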