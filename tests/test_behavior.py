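"""Task rules, exclusion cascade, and behavioral statistics."""

import numpy as np
import pandas as pd
import pytest

from elneuro.behavior import (
    apply_exclusions,
    bf01_interaction,
    effect_size_r,
    mixed_anova,
    performance_summary,
    rtt_series,
    tradeoff_correlation,
    training_regression,
    validate_trials,
)
from elneuro.simulate import behav_config_age, simulate_behavior_session


class TestRttSeries:
    def test_rule_on_worked_example(self):
        np.testing.assert_allclose(rtt_series([300, 400, 350]), [300, 300, 350])

    def test_constant_rts_constant_threshold(self):
        np.testing.assert_allclose(rtt_series([420] * 6), [420] * 6)

    def test_matches_prefix_median_oracle(self):
        # brute-force oracle: threshold k = median over strictly prior RTs
        for i in range(1000):
            g = np.random.default_rng(i)
            rts = g.uniform(200, 800, size=g.integers(1, 15))
            got = rtt_series(rts)
            exp = [rts[0]] + [float(np.median(rts[:k])) for k in range(1, len(rts))]
            np.testing.assert_allclose(got, exp)

    def test_empty_and_invalid(self):
        assert rtt_series([]).size == 0
        with pytest.raises(ValueError):
            rtt_series([300, -5])


def _trial(participant, session, block, i, stim, responded, rt, rtt, group="g1"):
    if stim == "Go":
        fb = "miss" if not responded else ("fast_hit" if rt < rtt else "late_hit")
    else:
        fb = "fa" if responded else "cr"
    return {
        "participant": participant, "group": group, "session": session,
        "block": block, "trial_index": i, "cue": "green", "stim": stim,
        "responded": responded, "rt_ms": rt if responded else np.nan,
        "rtt_ms": rtt, "feedback": fb,
    }


def _clean_block(participant, session, block, n_fa=3, n_miss=2, rt=400.0):
    rows = []
    i = 0
    for k in range(36):
        i += 1
        responded = k >= n_miss
        rows.append(_trial(participant, session, block, i, "Go", responded,
                           rt + k, rt + 50))
    for k in range(24):
        i += 1
        rows.append(_trial(participant, session, block, i, "NoGo", k < n_fa,
                           rt - 30 if k < n_fa else None, rt + 50))
    return rows


def _session_table(participant, session, n_blocks=6, **kw):
    rows = []
    for b in range(1, n_blocks + 1):
        rows.extend(_clean_block(participant, session, b, **kw))
    return rows


class TestExclusions:
    def test_clean_fixture_nothing_excluded(self):
        t = pd.DataFrame(_session_table("p1", "pre"))
        kept, blocks, excl, rep = apply_exclusions(t)
        assert rep.n_blocks_excluded == 0 and excl == []
        assert rep.n_trials_out == rep.n_trials_in

    def test_high_fa_block_excluded_with_reason(self):
        rows = _session_table("p1", "pre", n_fa=3)
        rows.extend(_clean_block("p1", "pre", 7, n_fa=18))  # 18/24 = 0.75
        kept, blocks, excl, rep = apply_exclusions(pd.DataFrame(rows))
        bad = blocks[blocks["block"] == 7].iloc[0]
        assert bad["excluded"] and "fa_rate>0.7" in bad["exclusion_reason"]
        assert 7 not in kept["block"].unique()

    def test_relative_miss_threshold(self):
        rows = _session_table("p1", "pre", n_blocks=5, n_miss=1)
        rows.extend(_clean_block("p1", "pre", 6, n_miss=6))  # 6/36 vs median ~1/36
        _, blocks, _, _ = apply_exclusions(pd.DataFrame(rows))
        bad = blocks[blocks["block"] == 6].iloc[0]
        assert "miss_rate>median+0.1" in bad["exclusion_reason"]

    def test_session_removed_when_over_half_blocks_bad(self):
        rows = []
        for b in range(1, 7):
            n_fa = 20 if b <= 4 else 3  # 4 of 6 blocks above the FA cap
            rows.extend(_clean_block("p1", "pre", b, n_fa=n_fa))
        kept, _, excl, _ = apply_exclusions(pd.DataFrame(rows))
        assert ("p1", "pre") in excl
        assert kept[(kept["participant"] == "p1") & (kept["session"] == "pre")].empty

    def test_anticipatory_responses_dropped_first(self):
        rows = _session_table("p1", "pre")
        rows.append(_trial("p1", "pre", 1, 99, "Go", True, 50.0, 450.0))
        kept, _, _, rep = apply_exclusions(pd.DataFrame(rows))
        assert rep.n_fast_guesses_dropped == 1
        assert not (kept["rt_ms"] < 100).any()

    def test_rt_outlier_trimming_single_pass(self, rng):
        rows = []
        for b in range(1, 7):
            rows.extend(_clean_block("p1", "pre", b, rt=400.0))
        t = pd.DataFrame(rows)
        # one extreme hit RT
        hit_idx = t.index[t["feedback"].isin(["fast_hit", "late_hit"])][0]
        t.loc[hit_idx, "rt_ms"] = 4000.0
        t.loc[hit_idx, "feedback"] = "late_hit"
        kept, _, _, rep = apply_exclusions(t)
        assert rep.n_rt_outliers_dropped >= 1
        assert 4000.0 not in kept["rt_ms"].values

    def test_malformed_rows_rejected_with_row_numbers(self):
        t = pd.DataFrame(_session_table("p1", "pre"))
        t.loc[3, "feedback"] = "cr"  # inconsistent with a Go trial
        with pytest.raises(ValueError, match="3"):
            validate_trials(t)


class TestPerformanceSummary:
    def test_worked_examples(self):
        rows = [
            _trial("p", "pre", 1, 1, "Go", True, 400.0, 500.0),
            _trial("p", "pre", 1, 2, "Go", True, 420.0, 500.0),
        ]
        rows += [
            _trial("p", "pre", 1, 3 + k, "NoGo", k < 3, 350.0 if k < 3 else None, 500.0)
            for k in range(24)
        ]
        s = performance_summary(pd.DataFrame(rows))
        assert s.loc[0, "mean_rt_hit_ms"] == pytest.approx(410.0)
        assert s.loc[0, "fa_rate"] == pytest.approx(3 / 24)

    def test_matches_bruteforce_on_random_tables(self):
        for i in range(20):
            g = np.random.default_rng(i)
            cfg = behav_config_age(seed=i)
            t = simulate_behavior_session(cfg, "p", "pre", group="young", rng=g)
            s = performance_summary(t).iloc[0]
            hits = t[t["feedback"].isin(["fast_hit", "late_hit"])]
            assert s["mean_rt_hit_ms"] == pytest.approx(hits["rt_ms"].mean())
            assert s["fa_rate"] == pytest.approx(
                (t["feedback"] == "fa").sum() / (t["stim"] == "NoGo").sum()
            )


def _dv(values: dict[str, tuple[float, float]], groups: dict[str, str]) -> pd.DataFrame:
    rows = []
    for p, (pre, post) in values.items():
        rows.append({"participant": p, "group": groups[p], "session": "pre", "value": pre})
        rows.append({"participant": p, "group": groups[p], "session": "post", "value": post})
    return pd.DataFrame(rows)


class TestMixedAnova:
    # hand-computed sum-of-squares oracle for the 4-subject toy table
    # s1:(10,14) s2:(12,18) in g1; s3:(20,21) s4:(22,25) in g2
    TOY = _dv(
        {"s1": (10, 14), "s2": (12, 18), "s3": (20, 21), "s4": (22, 25)},
        {"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"},
    )

    def test_matches_hand_decomposition(self):
        at = mixed_anova(self.TOY)
        e = at.effects.set_index("effect")
        assert e.loc["group", "SS"] == pytest.approx(144.5, abs=1e-10)
        assert e.loc["session", "SS"] == pytest.approx(24.5, abs=1e-10)
        assert e.loc["interaction", "SS"] == pytest.approx(4.5, abs=1e-10)
        assert e.loc["group", "F"] == pytest.approx(144.5 / 9.0, abs=1e-10)
        assert e.loc["session", "F"] == pytest.approx(24.5, abs=1e-10)
        assert e.loc["interaction", "F"] == pytest.approx(4.5, abs=1e-10)
        assert (e["df1"] == 1).all() and (e["df2"] == 2).all()
        assert e.loc["group", "ges"] == pytest.approx(144.5 / 164.5, abs=1e-10)
        assert e.loc["session", "ges"] == pytest.approx(24.5 / 44.5, abs=1e-10)
        assert e.loc["interaction", "ges"] == pytest.approx(4.5 / 24.5, abs=1e-10)

    def test_ss_additivity_and_ges_bounds(self, rng):
        n = 20
        groups = {f"s{i}": ("a" if i < n // 2 else "b") for i in range(n)}
        vals = {f"s{i}": tuple(rng.normal(50, 10, 2)) for i in range(n)}
        at = mixed_anova(_dv(vals, groups))
        # SS terms plus subject terms reconstruct the total SS
        wide = _dv(vals, groups).pivot_table(
            index=["participant", "group"], columns="session", values="value"
        )
        m = wide.mean(axis=1).to_numpy()
        d = (wide["post"] - wide["pre"]).to_numpy()
        grp = np.array([g for _, g in wide.index])
        ss_subj = 2 * sum(
            ((m[grp == g] - m[grp == g].mean()) ** 2).sum() for g in "ab"
        )
        ss_sxs = sum(
            ((d[grp == g] - d[grp == g].mean()) ** 2).sum() for g in "ab"
        ) / 2
        total = at.effects["SS"].sum() + ss_subj + ss_sxs
        assert total == pytest.approx(at.ss_total, abs=1e-8)
        assert ((at.effects["ges"] >= 0) & (at.effects["ges"] <= 1)).all()

    def test_additive_data_zero_interaction(self):
        vals = {"a1": (10, 20), "a2": (10, 20), "b1": (30, 40), "b2": (30, 40)}
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        at = mixed_anova(_dv(vals, groups))
        e = at.effects.set_index("effect")
        assert e.loc["interaction", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert e.loc["interaction", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 12
        groups = {f"s{i}": ("a" if i < 6 else "b") for i in range(n)}
        vals = {f"s{i}": tuple(rng.normal(100, 15, 2)) for i in range(n)}
        dv = _dv(vals, groups)
        ours = mixed_anova(dv).effects.set_index("effect")
        theirs = pg.mixed_anova(
            data=dv, dv="value", within="session", subject="participant",
            between="group",
        ).set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(theirs.loc["group", "F"], rel=1e-9)
        assert ours.loc["session", "F"] == pytest.approx(theirs.loc["session", "F"], rel=1e-9)
        assert ours.loc["interaction", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-9
        )

    def test_followups_and_holm(self):
        at = mixed_anova(self.TOY)
        assert set(at.followups["group"]) == {"g1", "g2"}
        assert (at.followups["p_holm"] >= at.followups["p"] - 1e-15).all()
        assert ((at.followups["r"] >= 0) & (at.followups["r"] <= 1)).all()

    def test_missing_cells_rejected(self):
        dv = self.TOY.drop(index=0)
        with pytest.raises(ValueError):
            mixed_anova(dv)

    def test_effect_size_r_formula(self):
        assert effect_size_r(2.0, 4) == pytest.approx(np.sqrt(4 / 8))


class TestBf01:
    def _noisy_dv(self, n, interaction, seed):
        g = np.random.default_rng(seed)
        vals, groups = {}, {}
        for i in range(2 * n):
            grp = "a" if i < n else "b"
            delta = 10.0 + (interaction if grp == "a" else 0.0)
            pre = g.normal(100, 10)
            vals[f"s{i}"] = (pre, pre + delta + g.normal(0, 5))
            groups[f"s{i}"] = grp
        return _dv(vals, groups)

    def test_strong_interaction_supports_alternative(self):
        assert bf01_interaction(self._noisy_dv(30, interaction=15.0, seed=1)) < 1.0

    def test_additive_data_supports_null_and_grows_with_n(self):
        bfs = [bf01_interaction(self._noisy_dv(n, 0.0, seed=2)) for n in (10, 30, 100)]
        assert all(b > 1.0 for b in bfs)
        assert bfs[0] < bfs[1] < bfs[2]

    def test_degenerate_data_rejected(self):
        vals = {"a1": (1, 2), "a2": (1, 2), "b1": (1, 2), "b2": (1, 2)}
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        with pytest.raises(ValueError):
            bf01_interaction(_dv(vals, groups))


class TestTrainingRegression:
    def test_exact_line_recovered(self):
        days = np.arange(1, 16)
        res = training_regression(days, 640.09 - 4.81 * days)
        assert res["b1"] == pytest.approx(-4.81, abs=1e-10)
        assert res["b0"] == pytest.approx(640.09, abs=1e-9)

    def test_r_equals_pearson_correlation(self, rng):
        days = np.arange(1, 16)
        y = 500 - 3 * days + rng.normal(0, 20, days.size)
        res = training_regression(days, y)
        assert res["r"] == pytest.approx(np.corrcoef(days, y)[0, 1], abs=1e-10)

    def test_null_slope_p_uniform(self):
        ps = []
        for i in range(200):
            g = np.random.default_rng(i)
            ps.append(training_regression(np.arange(1, 16), g.normal(0, 1, 15))["p"])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            training_regression([2, 2, 2], [1, 2, 3])


class TestTradeoff:
    def test_perfect_anticorrelation(self):
        drt = np.array([-60.0, -40.0, -20.0, 0.0])
        r, _ = tradeoff_correlation(drt, -0.001 * drt)
        assert r == pytest.approx(-1.0)

    def test_matches_bruteforce_formula(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, _ = tradeoff_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        exp = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert r == pytest.approx(exp, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tradeoff_correlation([1, 1, 1], [1, 2, 3])


class TestNullCalibrationOfAnova:
    def test_interaction_p_uniform_under_within_permutation(self):
        # permuting each subject's session labels independently kills the
        # within-subject effects; the interaction p should be uniform
        from scipy.stats import kstest

        ps = []
        for i in range(300):
            g = np.random.default_rng(i)
            vals, groups = {}, {}
            for j in range(16):
                pre, post = g.normal(100, 10, 2)
                if g.random() < 0.5:
                    pre, post = post, pre
                vals[f"s{j}"] = (pre, post)
                groups[f"s{j}"] = "a" if j < 8 else "b"
            at = mixed_anova(_dv(vals, groups))
            ps.append(at.effects.set_index("effect").loc["interaction", "p"])
        assert kstest(ps, "uniform").pvalue > 0.01
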