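#!/usr/bin/env python
"""Learning curves and habituation decisions.

Builds per-test day-mean learning curves, tests each consecutive-day bias
(Holm-adjusted within the curve), tracks the consecutive-day MAPE, and
reports the first session after which testing is stable: bias
nonsignificant AND random error no longer moving by more than 5
percentage points, for every remaining comparison.

Reads results/cohort.csv; writes results/learning_curves.csv and
results/habituation_decisions.csv.
"""

from pathlib import Path

import pandas as pd

from retestkit import (
    build_learning_curve,
    detect_stabilization,
    load_long_csv,
    recommend_sessions,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_long_csv(OUT / "cohort.csv")
    curves, decisions = [], []
    for test in ds.tests:
        curve = build_learning_curve(ds, test)
        dec = detect_stabilization(curve)
        curves.append(curve)
        decisions.append(dec)
        day = dec.stabilization_day
        print(f"{test}: stabilization day = "
              f"{day if day is not None else 'undetermined'}")
        for t in dec.criterion_trace:
            print(f"    {t['label']}: bias {t['bias']:+.2f} "
                  f"(p_adj {t['p_adjusted']:.3f}, MDC {t['mdc']:.2f}), "
                  f"MAPE {t['mape']:.1f}% -> "
                  f"{'ok' if t['bias_ok'] and t['random_error_ok'] else 'fail'}")

    frames = []
    for c in curves:
        f = c.day_stats.copy()
        f.insert(0, "test", c.test)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(
        OUT / "learning_curves.csv", index=False
    )
    summary = recommend_sessions(decisions)
    summary.to_csv(OUT / "habituation_decisions.csv", index=False)
    print("\nRecommended familiarization sessions:")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
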