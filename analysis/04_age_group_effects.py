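#!/usr/bin/env python
"""Age-group effects: mixed group x time ANOVA on day means, Scheffe post
hoc contrasts with Cohen's d, and first-to-last change-score comparisons.

Reads results/cohort.csv; writes results/group_anova.csv,
results/group_contrasts.csv and results/change_scores.csv.
"""

from pathlib import Path

import pandas as pd

from retestkit import change_score_comparison, load_long_csv, rm_anova, scheffe_posthoc
from retestkit.group_effects import cohens_d_band, eta_sq_band

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_long_csv(OUT / "cohort.csv")
    anova_rows, contrast_rows, change_rows = [], [], []
    for test in ds.tests:
        res = rm_anova(ds, test)
        print(f"\n{test} (GG epsilon = {res.gg_epsilon:.3f}):")
        for e in res.effects:
            anova_rows.append({"test": test, "effect": e.name,
                               "F": e.F, "df_num": e.df_num, "df_den": e.df_den,
                               "p": e.p, "partial_eta_sq": e.partial_eta_sq,
                               "eta_band": eta_sq_band(e.partial_eta_sq)})
            print(f"  {e.name:13s} F({e.df_num},{e.df_den}) = {e.F:8.2f}, "
                  f"p = {e.p:.2e}, eta_p^2 = {e.partial_eta_sq:.3f} "
                  f"({eta_sq_band(e.partial_eta_sq)})")
        for con in scheffe_posthoc(res):
            contrast_rows.append({"test": test, "a": con.group_a,
                                  "b": con.group_b, "mean_diff": con.mean_diff,
                                  "cohens_d": con.cohens_d,
                                  "p_scheffe": con.p_scheffe, "band": con.band})
        ch = change_score_comparison(ds, test)
        for row in ch.per_group.itertuples():
            change_rows.append({"test": test, "group": row.group, "n": row.n,
                                "mean_change": row.mean_change,
                                "sd_change": row.sd_change,
                                "anova_p": ch.p})
        print(f"  first-to-last change ANOVA: F = {ch.F:.2f}, p = {ch.p:.2e}")
        best = ch.per_group.loc[ch.per_group["mean_change"].idxmax()]
        print(f"  largest improvement: {best['group']} "
              f"({best['mean_change']:.2f} units)")

    pd.DataFrame(anova_rows).to_csv(OUT / "group_anova.csv", index=False)
    pd.DataFrame(contrast_rows).to_csv(OUT / "group_contrasts.csv", index=False)
    pd.DataFrame(change_rows).to_csv(OUT / "change_scores.csv", index=False)
    print(f"\ntables -> {OUT}")


if __name__ == "__main__":
    main()
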