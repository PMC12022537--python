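#!/usr/bin/env python
"""Intraday and interday reliability tables for the simulated cohort.

For every test and comparison: occasion means +/- SD, agreement ICC with
95% CI, SEM, MDC, paired-bias t-test with Holm-adjusted p across the whole
family of one mode, MAE and MAPE.  Also exports per-comparison
Bland-Altman data for plotting.

Reads results/cohort.csv (run 01 first); writes results/intraday.csv,
results/interday.csv (+ _display variants) and results/bland_altman/.
"""

from pathlib import Path

from retestkit import load_long_csv, make_pairs, reliability_table
from retestkit.error_decomp import bland_altman_export
from retestkit.report import render_display, rows_to_frame

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_long_csv(OUT / "cohort.csv")
    for mode in ("intraday", "interday"):
        rows = reliability_table(ds, mode)
        rows_to_frame(rows).to_csv(OUT / f"{mode}.csv", index=False)
        display = render_display(rows)
        display.to_csv(OUT / f"{mode}_display.csv", index=False)
        n_sig = sum(bool(r.bias.significant) for r in rows)
        print(f"{mode}: {len(rows)} comparisons, {n_sig} with significant "
              f"systematic bias after Holm correction")
        print(display.to_string(index=False), "\n")

    ba_dir = OUT / "bland_altman"
    ba_dir.mkdir(exist_ok=True)
    for test in ds.tests:
        for pair in make_pairs(ds, test, "interday"):
            name = pair.label.replace(" ", "_") + ".csv"
            bland_altman_export(pair).to_csv(ba_dir / name, index=False)
    print(f"Bland-Altman exports -> {ba_dir}")


if __name__ == "__main__":
    main()
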