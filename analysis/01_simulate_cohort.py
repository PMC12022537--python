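#!/usr/bin/env python
"""Generate the emulated cohort: 65 subjects in three age groups (22
children, 20 young adults, 23 older adults), five neurocognitive tests,
five days x two trials, with decaying learning effects and shrinking
random error.

Writes results/cohort.csv (long format) and results/cohort_config.yaml.
"""

from pathlib import Path

from retestkit import preset_paper_like, simulate_cohort

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = preset_paper_like(seed=SEED)
    ds = simulate_cohort(cfg)
    ds.to_csv(OUT / "cohort.csv")
    cfg.to_yaml(OUT / "cohort_config.yaml")
    print(f"simulated {len(ds.subjects)} subjects, {len(ds.tests)} tests, "
          f"{len(ds)} observations -> {OUT / 'cohort.csv'}")
    for test, (days, trials) in ds.design.items():
        print(f"  {test}: {days} days x {trials} trials")


if __name__ == "__main__":
    main()
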