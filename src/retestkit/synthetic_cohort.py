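"""Seeded generator of repeated-measures cohorts with decaying learning
effects.

The generative model for the score of subject s (group g) on day d,
trial t is

    score = mu_g + b_s + sign * c_g * [A e^{-lambda_g (d-1)}
                                       + a e^{-lambda_g (d-1)} 1{t=1}] + eps,

with b_s ~ Normal(0, sigma_s,g^2) a stable subject effect,
eps ~ Normal(0, sigma_e(d)^2) per-trial noise whose SD may shrink over
days, A the interday learning amplitude, a an extra trial-1 handicap that
creates within-day (test-vs-retest) improvement, lambda_g a per-group
decay rate and c_g a per-group amplitude scale.  ``sign`` is +1 for
lower-is-better scores (times: early sessions are slower) and -1 for
higher-is-better ones (counts: early sessions score fewer hits), so
"improvement" always moves the score in the right direction.  mu_g is the
post-habituation asymptote.  Floor/ceiling bounds and censoring (e.g. a
dropped 50-cm ruler recorded as 51) are applied last.

All randomness flows from one ``numpy`` generator seeded by the config, so
equal configs produce byte-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .study_data import LongDataset


@dataclass
class GroupSpec:
    label: str
    n: int
    amplitude_scale: float = 1.0  # c_g
    decay_rate: float = 0.8  # lambda_g, per day


@dataclass
class TestSpec:
    """One test's units, direction, per-group baselines and error model.

    ``baseline_mean``/``baseline_sd`` map group label -> asymptotic mean
    mu_g and between-subject SD sigma_s,g.  ``error_sd`` is either a scalar
    or a per-day schedule (nonincreasing when the shrinking-error mode is
    meant); ``censor_value`` replaces scores beyond ``ceiling``.
    """

    name: str
    units: str
    higher_is_better: bool
    baseline_mean: dict[str, float]
    baseline_sd: dict[str, float]
    interday_amplitude: float  # A, score units
    intraday_amplitude: float  # a, score units
    error_sd: tuple[float, ...] | float = 1.0
    floor: float | None = None
    ceiling: float | None = None
    censor_value: float | None = None

    def error_sd_on(self, day: int, n_days: int) -> float:
        if np.isscalar(self.error_sd):
            return float(self.error_sd)
        sched = tuple(self.error_sd)
        if len(sched) != n_days:
            raise ConfigError(
                f"{self.name}: error_sd schedule length {len(sched)} != "
                f"n_days {n_days}"
            )
        return float(sched[day - 1])


@dataclass
class SimulationConfig:
    groups: list[GroupSpec]
    tests: list[TestSpec]
    n_days: int = 5
    n_trials_per_day: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_days < 1 or self.n_trials_per_day < 1:
            raise ConfigError("n_days and n_trials_per_day must be >= 1")
        if not self.groups or not self.tests:
            raise ConfigError("need at least one group and one test")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate group labels")
        for g in self.groups:
            if g.n < 1:
                raise ConfigError(f"group {g.label}: n must be >= 1")
            if g.decay_rate < 0:
                raise ConfigError(f"group {g.label}: decay rate must be >= 0")
        for t in self.tests:
            for g in self.groups:
                if g.label not in t.baseline_mean or g.label not in t.baseline_sd:
                    raise ConfigError(
                        f"test {t.name}: missing baseline for group {g.label}"
                    )
                if t.baseline_sd[g.label] <= 0:
                    raise ConfigError(f"test {t.name}: baseline_sd must be > 0")
            for d in range(1, self.n_days + 1):
                if t.error_sd_on(d, self.n_days) <= 0:
                    raise ConfigError(f"test {t.name}: error_sd must be > 0")
            if t.censor_value is not None and t.ceiling is None:
                raise ConfigError(
                    f"test {t.name}: censor_value requires a ceiling"
                )
            if (
                t.censor_value is not None
                and t.ceiling is not None
                and t.censor_value < t.ceiling
            ):
                raise ConfigError(
                    f"test {t.name}: censor_value must be >= ceiling"
                )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        groups = [GroupSpec(**g) for g in data["groups"]]
        tests = []
        for t in data["tests"]:
            t = dict(t)
            if isinstance(t.get("error_sd"), list):
                t["error_sd"] = tuple(t["error_sd"])
            tests.append(TestSpec(**t))
        return cls(
            groups=groups,
            tests=tests,
            n_days=data.get("n_days", 5),
            n_trials_per_day=data.get("n_trials_per_day", 2),
            seed=data.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _handicap(test: TestSpec, group: GroupSpec, day: int, trial: int) -> float:
    decay = np.exp(-group.decay_rate * (day - 1))
    h = test.interday_amplitude * decay
    if trial == 1:
        h += test.intraday_amplitude * decay
    return group.amplitude_scale * h


def simulate_cohort(cfg: SimulationConfig) -> LongDataset:
    """Draw one cohort; fully reproducible from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for group in cfg.groups:
        subjects = [f"{group.label}_{i + 1:03d}" for i in range(group.n)]
        for test in cfg.tests:
            sign = -1.0 if test.higher_is_better else 1.0
            mu = test.baseline_mean[group.label]
            sigma_s = test.baseline_sd[group.label]
            b = rng.normal(0.0, sigma_s, size=group.n)
            for day in range(1, cfg.n_days + 1):
                sd_e = test.error_sd_on(day, cfg.n_days)
                for trial in range(1, cfg.n_trials_per_day + 1):
                    eps = rng.normal(0.0, sd_e, size=group.n)
                    scores = mu + b + sign * _handicap(test, group, day, trial) + eps
                    if test.floor is not None:
                        scores = np.maximum(scores, test.floor)
                    if test.ceiling is not None:
                        over = scores > test.ceiling
                        if test.censor_value is not None:
                            scores = np.where(over, test.censor_value, scores)
                        else:
                            scores = np.where(over, test.ceiling, scores)
                    frames.append(
                        pd.DataFrame(
                            {
                                "subject": subjects,
                                "group": group.label,
                                "test": test.name,
                                "day": day,
                                "trial": trial,
                                "score": scores,
                            }
                        )
                    )
    frame = pd.concat(frames, ignore_index=True)
    hib = {t.name: t.higher_is_better for t in cfg.tests}
    return LongDataset(frame, higher_is_better=hib)


def preset_paper_like(seed: int = 0) -> SimulationConfig:
    """A qualitative emulation of a 65-subject, 3-age-group cohort tested
    on five neurocognitive measures over 5 days x 2 trials.

    Groups: 22 children (faster/larger learning from a weaker baseline),
    20 young adults (small residual learning), 23 older adults.  Baselines,
    amplitudes and noise schedules are chosen so that day-1 and day-5
    group-pooled means, day-to-day bias decay and shrinking random error
    resemble published magnitudes for these tasks; this is scaffolding for
    tests and demos, not a fit to any dataset.
    """
    c, y, o = "children", "young_adults", "older_adults"
    groups = [
        GroupSpec(label=c, n=22, amplitude_scale=1.35, decay_rate=0.85),
        GroupSpec(label=y, n=20, amplitude_scale=0.75, decay_rate=1.05),
        GroupSpec(label=o, n=23, amplitude_scale=1.0, decay_rate=0.80),
    ]
    tests = [
        TestSpec(
            name="ruler_drop",
            units="cm",
            higher_is_better=False,
            baseline_mean={c: 13.5, y: 7.5, o: 10.5},
            baseline_sd={c: 5.5, y: 4.0, o: 4.5},
            interday_amplitude=7.0,
            intraday_amplitude=2.2,
            error_sd=(4.2, 4.2, 4.3, 4.3, 4.4),
            floor=2.0,
            ceiling=50.0,
            censor_value=51.0,
        ),
        TestSpec(
            name="trail_making",
            units="s",
            higher_is_better=False,
            baseline_mean={c: 22.0, y: 10.5, o: 13.0},
            baseline_sd={c: 7.0, y: 3.5, o: 4.5},
            interday_amplitude=9.0,
            intraday_amplitude=8.5,
            error_sd=(3.2, 2.8, 2.6, 2.4, 2.2),
            floor=5.0,
        ),
        TestSpec(
            name="stroop",
            units="s",
            higher_is_better=False,
            baseline_mean={c: 25.0, y: 14.5, o: 16.5},
            baseline_sd={c: 7.0, y: 3.0, o: 4.0},
            interday_amplitude=4.2,
            intraday_amplitude=2.1,
            error_sd=(1.6, 1.2, 1.0, 0.9, 0.8),
            floor=6.0,
        ),
        TestSpec(
            name="choice_reaction",
            units="hits",
            higher_is_better=True,
            baseline_mean={c: 45.0, y: 56.0, o: 50.0},
            baseline_sd={c: 5.0, y: 4.5, o: 5.0},
            interday_amplitude=6.5,
            intraday_amplitude=2.3,
            error_sd=(2.6, 2.5, 2.4, 2.35, 2.3),
            floor=0.0,
        ),
        TestSpec(
            name="reaction_time",
            units="ms",
            higher_is_better=False,
            baseline_mean={c: 540.0, y: 390.0, o: 480.0},
            baseline_sd={c: 90.0, y: 60.0, o: 70.0},
            interday_amplitude=75.0,
            intraday_amplitude=36.0,
            error_sd=(36.0, 30.0, 26.0, 24.0, 22.0),
            floor=150.0,
        ),
    ]
    return SimulationConfig(groups=groups, tests=tests, n_days=5,
                            n_trials_per_day=2, seed=seed)


def _folded_normal_mean(mu: float, sigma: float) -> float:
    """E|Z| for Z ~ Normal(mu, sigma^2)."""
    from scipy import stats as _st

    if sigma == 0:
        return abs(mu)
    return float(
        sigma * np.sqrt(2.0 / np.pi) * np.exp(-(mu**2) / (2 * sigma**2))
        + mu * (1 - 2 * _st.norm.cdf(-mu / sigma))
    )


def truth_of(cfg: SimulationConfig) -> dict:
    """Analytically implied ground truths of a configuration.

    Per test and group (plus a size-weighted ``overall``):

    ``true_icc_by_day``
        sigma_s^2 / (sigma_s^2 + sigma_e(d)^2), the trial-level reliability
        absent systematic offsets (the overall entry includes the spread of
        group means in the subject variance, as a pooled analysis does);
    ``true_interday_bias``
        expected day-mean difference bias(d, d+1) =
        sign * c_g (A + a/2) [e^{-lambda(d-1)} - e^{-lambda d}];
    ``true_intraday_bias``
        sign * c_g a e^{-lambda(d-1)} per day;
    ``expected_interday_mape``
        folded-normal approximation E|diff| / E[reference] * 100;
    ``first_day_bias_below(threshold)``
        earliest d with |bias(d, d+1)| < threshold, None if never.
    """
    n_total = sum(g.n for g in cfg.groups)
    out: dict = {}
    for test in cfg.tests:
        sign = -1.0 if test.higher_is_better else 1.0
        per_group: dict = {}
        for group in cfg.groups:
            lam, c_g = group.decay_rate, group.amplitude_scale
            amp = c_g * (test.interday_amplitude + test.intraday_amplitude / 2.0)
            s2 = test.baseline_sd[group.label] ** 2
            icc = [
                s2 / (s2 + test.error_sd_on(d, cfg.n_days) ** 2)
                for d in range(1, cfg.n_days + 1)
            ]
            inter = [
                sign * amp * (np.exp(-lam * (d - 1)) - np.exp(-lam * d))
                for d in range(1, cfg.n_days)
            ]
            intra = [
                sign * c_g * test.intraday_amplitude * np.exp(-lam * (d - 1))
                for d in range(1, cfg.n_days + 1)
            ]
            per_group[group.label] = {
                "true_icc_by_day": icc,
                "true_interday_bias": inter,
                "true_intraday_bias": intra,
            }
        # size-weighted overall
        w = np.array([g.n / n_total for g in cfg.groups])
        mus = np.array([test.baseline_mean[g.label] for g in cfg.groups])
        mu_bar = float(w @ mus)
        s2_overall = float(
            w @ np.array([test.baseline_sd[g.label] ** 2 for g in cfg.groups])
            + w @ (mus - mu_bar) ** 2
        )
        icc_overall = [
            s2_overall / (s2_overall + test.error_sd_on(d, cfg.n_days) ** 2)
            for d in range(1, cfg.n_days + 1)
        ]
        inter_overall = [
            float(
                sum(
                    w[i] * per_group[g.label]["true_interday_bias"][d - 1]
                    for i, g in enumerate(cfg.groups)
                )
            )
            for d in range(1, cfg.n_days)
        ]
        # expected day-mean reference value on day d (overall)
        def _day_mean(d: int) -> float:
            total = 0.0
            for i, g in enumerate(cfg.groups):
                h = g.amplitude_scale * (
                    test.interday_amplitude + test.intraday_amplitude / 2.0
                ) * np.exp(-g.decay_rate * (d - 1))
                total += w[i] * (test.baseline_mean[g.label] + sign * h)
            return float(total)

        mape_overall = []
        for d in range(1, cfg.n_days):
            sd_diff = np.sqrt(
                (
                    test.error_sd_on(d, cfg.n_days) ** 2
                    + test.error_sd_on(d + 1, cfg.n_days) ** 2
                )
                / cfg.n_trials_per_day
            )
            e_abs = _folded_normal_mean(inter_overall[d - 1], sd_diff)
            mape_overall.append(100.0 * e_abs / _day_mean(d))

        def _first_below(threshold: float, series=tuple(inter_overall)):
            for d, bias in enumerate(series, start=1):
                if abs(bias) < threshold:
                    return d
            return None

        out[test.name] = {
            "groups": per_group,
            "overall": {
                "true_icc_by_day": icc_overall,
                "true_interday_bias": inter_overall,
                "expected_interday_mape": mape_overall,
                "expected_day_means": [
                    _day_mean(d) for d in range(1, cfg.n_days + 1)
                ],
            },
            "first_day_bias_below": _first_below,
        }
    return out
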