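import numpy as np
import pandas as pd
import pytest

import retestkit as rk
from retestkit.exceptions import InsufficientDataError
from retestkit.group_effects import cohens_d_band, eta_sq_band
from tests.conftest import make_dataset


def two_group_toy():
    """Balanced 2-group x 2-day toy with integer day means (one trial per
    day so the day mean is the trial score)."""
    rows = []
    data = {
        ("a", "s1"): (10, 8), ("a", "s2"): (12, 9), ("a", "s3"): (14, 10),
        ("b", "s4"): (20, 19), ("b", "s5"): (22, 20), ("b", "s6"): (24, 21),
    }
    for (grp, subj), (d1, d2) in data.items():
        rows.append({"subject": subj, "group": grp, "test": "t", "day": 1,
                     "trial": 1, "score": float(d1)})
        rows.append({"subject": subj, "group": grp, "test": "t", "day": 2,
                     "trial": 1, "score": float(d2)})
    return rk.LongDataset(pd.DataFrame(rows))


def brute_force_mixed_ss(y, glabels):
    """Definitional sums of squares via explicit loops over subjects, days
    and group cells (cell-count weighted)."""
    n, k = y.shape
    grand = y.sum() / (n * k)
    groups = sorted(set(glabels))
    subj_mean = [y[i].sum() / k for i in range(n)]
    day_mean = [y[:, j].sum() / n for j in range(k)]
    ss_bs = sum(k * (sm - grand) ** 2 for sm in subj_mean)
    ss_group = 0.0
    ss_cells = 0.0
    for g in groups:
        idx = [i for i in range(n) if glabels[i] == g]
        gmean = sum(y[i, j] for i in idx for j in range(k)) / (len(idx) * k)
        ss_group += k * len(idx) * (gmean - grand) ** 2
        for j in range(k):
            cmean = sum(y[i, j] for i in idx) / len(idx)
            ss_cells += len(idx) * (cmean - grand) ** 2
    ss_time = sum(n * (dm - grand) ** 2 for dm in day_mean)
    ss_total = sum((y[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_int = ss_cells - ss_group - ss_time
    return {
        "group": ss_group,
        "err_between": ss_bs - ss_group,
        "time": ss_time,
        "interaction": ss_int,
        "err_within": ss_total - ss_bs - ss_time - ss_int,
    }


class TestRmAnova:
    def test_toy_matches_brute_force(self):
        ds = two_group_toy()
        res = rk.rm_anova(ds, "t")
        y = np.array([[10, 8], [12, 9], [14, 10], [20, 19], [22, 20], [24, 21]],
                     dtype=float)
        ss = brute_force_mixed_ss(y, ["a", "a", "a", "b", "b", "b"])
        assert res.effect("group").ss_effect == pytest.approx(ss["group"], abs=1e-10)
        assert res.effect("group").ss_error == pytest.approx(ss["err_between"], abs=1e-10)
        assert res.effect("time").ss_effect == pytest.approx(ss["time"], abs=1e-10)
        assert res.effect("group_x_time").ss_effect == pytest.approx(
            ss["interaction"], abs=1e-10)
        assert res.effect("time").ss_error == pytest.approx(ss["err_within"], abs=1e-10)

    def test_random_unbalanced_matches_brute_force(self):
        rng = np.random.default_rng(21)
        rows = []
        sizes = {"a": 5, "b": 7, "c": 4}
        i = 0
        for g, n in sizes.items():
            for _ in range(n):
                i += 1
                for d in range(1, 4):
                    rows.append({"subject": f"s{i}", "group": g, "test": "t",
                                 "day": d, "trial": 1,
                                 "score": rng.normal(10, 3)})
        ds = rk.LongDataset(pd.DataFrame(rows))
        res = rk.rm_anova(ds, "t")
        wide = ds.frame.pivot_table(index="subject", columns="day", values="score")
        glabels = ds.frame.drop_duplicates("subject").set_index("subject")["group"]
        glabels = glabels.reindex(wide.index).tolist()
        ss = brute_force_mixed_ss(wide.to_numpy(), glabels)
        for name, key in [("group", "group"), ("time", "time"),
                          ("group_x_time", "interaction")]:
            assert res.effect(name).ss_effect == pytest.approx(ss[key], abs=1e-10)

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        rows = []
        for gi, g in enumerate(["a", "b"]):
            for s in range(10):
                base = rng.normal(20 + 5 * gi, 3)
                for d in range(1, 5):
                    rows.append({"subject": f"{g}{s}", "group": g, "test": "t",
                                 "day": d, "trial": 1,
                                 "score": base - 0.5 * gi * d + rng.normal(0, 1)})
        ds = rk.LongDataset(pd.DataFrame(rows))
        res = rk.rm_anova(ds, "t")
        long = ds.frame.rename(columns={"day": "time"})
        ref = pg.mixed_anova(data=long, dv="score", within="time",
                             subject="subject", between="group").set_index("Source")
        assert res.effect("group").F == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.effect("time").F == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert res.effect("group_x_time").F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)
        assert res.effect("group").partial_eta_sq == pytest.approx(
            ref.loc["group", "np2"], rel=1e-6)

    def test_partial_eta_sq_definition(self):
        res = rk.rm_anova(two_group_toy(), "t")
        for e in res.effects:
            assert e.partial_eta_sq == pytest.approx(
                e.ss_effect / (e.ss_effect + e.ss_error))
            assert 0.0 <= e.partial_eta_sq <= 1.0
            assert e.F >= 0

    def test_interaction_power_with_group_specific_decay(self):
        # one group learns, the other does not: interaction should be
        # detected in most replicates at the emulated cohort scale
        hits = 0
        for seed in range(15):
            cfg = rk.SimulationConfig(
                groups=[rk.GroupSpec("fast", 22, amplitude_scale=1.5,
                                     decay_rate=0.8),
                        rk.GroupSpec("slow", 20, amplitude_scale=0.2,
                                     decay_rate=0.8)],
                tests=[rk.TestSpec("t", "s", False,
                                   {"fast": 18.0, "slow": 20.0},
                                   {"fast": 4.0, "slow": 4.0},
                                   interday_amplitude=6.0,
                                   intraday_amplitude=2.0, error_sd=1.5)],
                seed=seed,
            )
            res = rk.rm_anova(rk.simulate_cohort(cfg), "t")
            hits += res.effect("group_x_time").p < 0.05
        assert hits >= 12

    def test_null_interaction_rarely_significant(self):
        hits = 0
        for seed in range(20):
            ds = make_dataset(n_subjects=12, n_days=3, seed=seed)
            frame = ds.frame.copy()
            frame.loc[frame.subject.isin(["s1", "s2", "s3", "s4", "s5", "s6"]),
                      "group"] = "g2"
            res = rk.rm_anova(rk.LongDataset(frame), "stroop")
            hits += res.effect("group_x_time").p < 0.05
        assert hits <= 4

    def test_small_group_rejected(self):
        ds = two_group_toy()
        frame = ds.frame[ds.frame.subject != "s4"]
        frame = frame[frame.subject != "s5"]
        with pytest.raises(InsufficientDataError):
            rk.rm_anova(rk.LongDataset(frame), "t")

    def test_gg_epsilon_range(self, preset_cohort):
        res = rk.rm_anova(preset_cohort, "stroop")
        assert res.sphericity_correction == "greenhouse-geisser"
        assert 1.0 / (res.n_days - 1) <= res.gg_epsilon <= 1.0


class TestScheffe:
    def test_identical_groups_null_contrast(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in ("a", "b"):
            for s in range(12):
                base = rng.normal(20, 0.1)
                for d in (1, 2):
                    rows.append({"subject": f"{g}{s}", "group": g, "test": "t",
                                 "day": d, "trial": 1, "score": base})
        res = rk.rm_anova(rk.LongDataset(pd.DataFrame(rows)), "t")
        (con,) = rk.scheffe_posthoc(res)
        assert con.p_scheffe > 0.5
        assert abs(con.cohens_d) < 0.5

    def test_cohens_d_from_pooled_sd(self):
        # means 10 vs 20, both SDs 5 -> |d| = 2.0
        rows = []
        for g, vals in (("a", [5, 10, 15]), ("b", [15, 20, 25])):
            for i, v in enumerate(vals):
                for d in (1, 2):
                    rows.append({"subject": f"{g}{i}", "group": g, "test": "t",
                                 "day": d, "trial": 1, "score": float(v)})
        res = rk.rm_anova(rk.LongDataset(pd.DataFrame(rows)), "t")
        (con,) = rk.scheffe_posthoc(res)
        assert con.mean_diff == pytest.approx(-10.0)
        assert con.cohens_d == pytest.approx(-2.0)
        assert con.band == "large"

    def test_scheffe_conservative_vs_unadjusted_pairwise(self):
        from scipy import stats as st

        rng = np.random.default_rng(14)
        for _ in range(10):
            rows = []
            for g, mu in (("a", 20.0), ("b", 21.0), ("c", 22.0)):
                for s in range(8):
                    base = rng.normal(mu, 2)
                    for d in (1, 2):
                        rows.append({"subject": f"{g}{s}", "group": g,
                                     "test": "t", "day": d, "trial": 1,
                                     "score": base + rng.normal(0, 0.5)})
            res = rk.rm_anova(rk.LongDataset(pd.DataFrame(rows)), "t")
            sm = res.subject_means
            for con in rk.scheffe_posthoc(res):
                va = sm.loc[sm.group == con.group_a, "mean"]
                vb = sm.loc[sm.group == con.group_b, "mean"]
                p_unadj = st.ttest_ind(va, vb).pvalue
                assert con.p_scheffe >= p_unadj - 1e-12


class TestChangeScores:
    def test_faster_learning_group_has_largest_change(self):
        cfg = rk.SimulationConfig(
            groups=[rk.GroupSpec("children", 22, amplitude_scale=1.6,
                                 decay_rate=0.9),
                    rk.GroupSpec("adults", 20, amplitude_scale=0.5,
                                 decay_rate=0.9)],
            tests=[rk.TestSpec("t", "s", False,
                               {"children": 22.0, "adults": 12.0},
                               {"children": 5.0, "adults": 3.0},
                               interday_amplitude=8.0, intraday_amplitude=3.0,
                               error_sd=1.5)],
            seed=6,
        )
        res = rk.change_score_comparison(rk.simulate_cohort(cfg), "t")
        per = res.per_group.set_index("group")["mean_change"]
        assert per["children"] > per["adults"]
        assert res.p < 0.05

    def test_change_direction_respects_score_orientation(self):
        cfg = rk.SimulationConfig(
            groups=[rk.GroupSpec("g", 30), rk.GroupSpec("h", 30)],
            tests=[rk.TestSpec("hits", "n", True, {"g": 40.0, "h": 42.0},
                               {"g": 4.0, "h": 4.0}, interday_amplitude=5.0,
                               intraday_amplitude=1.0, error_sd=1.0)],
            seed=9,
        )
        res = rk.change_score_comparison(rk.simulate_cohort(cfg), "hits")
        # positive = improvement even though raw scores increase
        assert (res.per_group["mean_change"] > 0).all()

    def test_null_rarely_significant(self):
        hits = 0
        for seed in range(20):
            cfg = rk.SimulationConfig(
                groups=[rk.GroupSpec("a", 20), rk.GroupSpec("b", 20)],
                tests=[rk.TestSpec("t", "s", False, {"a": 20.0, "b": 20.0},
                                   {"a": 3.0, "b": 3.0}, interday_amplitude=4.0,
                                   intraday_amplitude=1.0, error_sd=1.0)],
                seed=100 + seed,
            )
            res = rk.change_score_comparison(rk.simulate_cohort(cfg), "t")
            hits += res.p < 0.05
        assert hits <= 4

    def test_single_group_descriptive_only(self):
        cfg = rk.SimulationConfig(
            groups=[rk.GroupSpec("only", 10)],
            tests=[rk.TestSpec("t", "s", False, {"only": 20.0}, {"only": 3.0},
                               interday_amplitude=4.0, intraday_amplitude=1.0)],
            seed=1,
        )
        res = rk.change_score_comparison(rk.simulate_cohort(cfg), "t")
        assert res.F is None and res.p is None and res.contrasts == []


@pytest.mark.parametrize("eta,band", [(0.02, "small"), (0.06, "moderate"),
                                      (0.13, "moderate"), (0.14, "large")])
def test_eta_bands(eta, band):
    assert eta_sq_band(eta) == band


@pytest.mark.parametrize("d,band", [(0.1, "trivial"), (-0.3, "small"),
                                    (0.6, "moderate"), (0.85, "large")])
def test_d_bands(d, band):
    assert cohens_d_band(d) == band
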