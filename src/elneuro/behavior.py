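"""Go/NoGo behavioral analysis: task-rule computations, the trial/block/
participant exclusion cascade, and the statistical toolkit (2x2 mixed ANOVA
with generalized eta squared, follow-up paired t-tests with Holm correction
and effect size r, a BIC-approximated Bayes factor for the interaction,
training-day regressions, and the speed-accuracy trade-off correlation).

Trial tables are plain pandas DataFrames with the column set of
:data:`TRIAL_COLUMNS`; feedback categories follow the task rule:

* ``fast_hit`` — response to Go with RT below the adaptive threshold (RTT),
* ``late_hit`` — response to Go with RT at/above the RTT,
* ``miss`` — no response to Go,
* ``fa`` — response to NoGo (false alarm, a failed inhibition),
* ``cr`` — no response to NoGo (correct rejection).

The RTT is the running median of the block's previous correct-Go RTs, which
keeps time pressure constant across participants and blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TRIAL_COLUMNS",
    "validate_trials",
    "rtt_series",
    "feedback_for",
    "apply_exclusions",
    "performance_summary",
    "mixed_anova",
    "bf01_interaction",
    "training_regression",
    "tradeoff_correlation",
    "AnovaTable",
    "ExclusionReport",
]

TRIAL_COLUMNS = [
    "participant",
    "group",
    "session",
    "block",
    "trial_index",
    "cue",
    "stim",
    "responded",
    "rt_ms",
    "rtt_ms",
    "feedback",
]

_FEEDBACKS = {"fast_hit", "late_hit", "miss", "fa", "cr"}
_HIT = ("fast_hit", "late_hit")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table contract; raise with offending row numbers."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    t = trials
    bad_rt = t.index[t["responded"].astype(bool) != t["rt_ms"].notna()]
    if len(bad_rt):
        raise ValueError(f"rt_ms must be present iff responded; rows {list(bad_rt[:10])}")
    bad_fb = t.index[~t["feedback"].isin(_FEEDBACKS)]
    if len(bad_fb):
        raise ValueError(f"unknown feedback values at rows {list(bad_fb[:10])}")
    exp = _expected_feedback(t)
    bad = t.index[exp != t["feedback"]]
    if len(bad):
        raise ValueError(f"feedback inconsistent with stim/response at rows {list(bad[:10])}")
    return t


def _expected_feedback(t: pd.DataFrame) -> pd.Series:
    responded = t["responded"].astype(bool)
    is_go = t["stim"] == "Go"
    out = pd.Series("cr", index=t.index)
    out[is_go & ~responded] = "miss"
    out[~is_go & responded] = "fa"
    fast = is_go & responded & (t["rt_ms"] < t["rtt_ms"])
    late = is_go & responded & (t["rt_ms"] >= t["rtt_ms"])
    out[fast] = "fast_hit"
    out[late] = "late_hit"
    return out


def feedback_for(stim: str, responded: bool, rt_ms: float | None, rtt_ms: float | None) -> str:
    """Feedback category for a single trial under the task rule."""
    if stim == "Go":
        if not responded:
            return "miss"
        return "fast_hit" if rt_ms < rtt_ms else "late_hit"
    return "fa" if responded else "cr"


def rtt_series(go_rts) -> np.ndarray:
    """Adaptive response-time thresholds for a block's correct-Go RTs.

    The threshold in force at correct-Go trial k is the median of the
    previous correct-Go RTs (trials 1..k-1 of the block); for the very first
    correct Go it is that trial's own RT. Any responded Go trial (fast or
    late) counts as a correct Go. Resets every block.
    """
    rts = np.asarray(list(go_rts), dtype=float)
    if rts.size == 0:
        return rts
    if np.any(rts <= 0):
        raise ValueError("RTs must be positive")
    out = np.empty_like(rts)
    out[0] = rts[0]
    for k in range(1, rts.size):
        out[k] = np.median(rts[:k])
    return out


# ---------------------------------------------------------------------------
# exclusion cascade

@dataclass
class ExclusionReport:
    n_trials_in: int
    n_fast_guesses_dropped: int
    n_blocks_in: int
    n_blocks_excluded: int
    excluded_sessions: list[tuple[str, str]]
    n_rt_outliers_dropped: int
    n_trials_out: int


def _block_rates(t: pd.DataFrame) -> pd.DataFrame:
    def rates(g: pd.DataFrame) -> pd.Series:
        n_go = int((g["stim"] == "Go").sum())
        n_nogo = int((g["stim"] == "NoGo").sum())
        fa = int((g["feedback"] == "fa").sum())
        miss = int((g["feedback"] == "miss").sum())
        hit_rts = g.loc[g["feedback"].isin(_HIT), "rt_ms"]
        return pd.Series(
            {
                "n_go": n_go,
                "n_nogo": n_nogo,
                "fa_rate": fa / n_nogo if n_nogo else 0.0,
                "miss_rate": miss / n_go if n_go else 0.0,
                "mean_rt_hit_ms": hit_rts.mean() if len(hit_rts) else np.nan,
            }
        )

    out = (
        t.groupby(["participant", "session", "block"])
        .apply(rates, include_groups=False)
        .reset_index()
    )
    return out


def apply_exclusions(
    trials: pd.DataFrame,
    fa_abs: float = 0.7,
    miss_abs: float = 0.2,
    fa_rel: float = 0.2,
    miss_rel: float = 0.1,
    sd_mult: float = 2.5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]], ExclusionReport]:
    """Run the fixed-order exclusion cascade on a trial table.

    1. Drop responded (hit and false-alarm) trials with RT < 100 ms: such
       responses cannot be stimulus-driven.
    2. Exclude blocks with FA rate > ``fa_abs``, miss rate > ``miss_abs``,
       FA rate above the participant-session median + ``fa_rel``, or miss
       rate above the median + ``miss_rel``. The medians are over all of that
       participant-session's blocks, computed before any block exclusion.
    3. Exclude a participant's session when more than half its blocks are
       excluded.
    4. Per participant x session, drop hit trials with RT outside mean
       +/- ``sd_mult`` * SD (sample SD, single pass).

    Returns the retained trials, per-block summaries with exclusion flags,
    the list of excluded (participant, session) pairs, and a stage report.
    """
    t = validate_trials(trials).copy()
    n_in = len(t)

    # stage 1: anticipatory responses
    fast_guess = t["responded"].astype(bool) & (t["rt_ms"] < 100.0)
    t = t[~fast_guess]

    # stage 2: block outliers
    blocks = _block_rates(t)
    med = (
        blocks.groupby(["participant", "session"])[["fa_rate", "miss_rate"]]
        .median()
        .rename(columns=lambda c: f"med_{c}")
        .reset_index()
    )
    blocks = blocks.merge(med, on=["participant", "session"])
    reasons = []
    for _, row in blocks.iterrows():
        why = []
        if row["fa_rate"] > fa_abs:
            why.append(f"fa_rate>{fa_abs}")
        if row["miss_rate"] > miss_abs:
            why.append(f"miss_rate>{miss_abs}")
        if row["fa_rate"] > row["med_fa_rate"] + fa_rel:
            why.append(f"fa_rate>median+{fa_rel}")
        if row["miss_rate"] > row["med_miss_rate"] + miss_rel:
            why.append(f"miss_rate>median+{miss_rel}")
        reasons.append(";".join(why))
    blocks["excluded"] = [bool(r) for r in reasons]
    blocks["exclusion_reason"] = reasons

    # stage 3: disengaged sessions
    excl_sessions: list[tuple[str, str]] = []
    for (p, s), grp in blocks.groupby(["participant", "session"]):
        if grp["excluded"].sum() > len(grp) / 2:
            excl_sessions.append((p, s))
    sess_set = set(excl_sessions)

    bad_blocks = {
        (r["participant"], r["session"], r["block"])
        for _, r in blocks.iterrows()
        if r["excluded"] or (r["participant"], r["session"]) in sess_set
    }
    keep_mask = ~t.apply(
        lambda r: (r["participant"], r["session"], r["block"]) in bad_blocks, axis=1
    )
    t = t[keep_mask] if len(t) else t

    # stage 4: RT outlier trimming on hits, per participant-session
    n_outliers = 0
    keep_idx = []
    for (p, s), grp in t.groupby(["participant", "session"]):
        hits = grp[grp["feedback"].isin(_HIT)]
        if len(hits) >= 2:
            m, sd = hits["rt_ms"].mean(), hits["rt_ms"].std(ddof=1)
            out_of_band = hits.index[(hits["rt_ms"] - m).abs() > sd_mult * sd]
            n_outliers += len(out_of_band)
            keep_idx.extend(set(grp.index) - set(out_of_band))
        else:
            keep_idx.extend(grp.index)
    t = t.loc[sorted(keep_idx)]

    report = ExclusionReport(
        n_trials_in=n_in,
        n_fast_guesses_dropped=int(fast_guess.sum()),
        n_blocks_in=len(blocks),
        n_blocks_excluded=int(blocks["excluded"].sum()),
        excluded_sessions=excl_sessions,
        n_rt_outliers_dropped=n_outliers,
        n_trials_out=len(t),
    )
    return t, blocks, excl_sessions, report


def performance_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x session mean hit RT (ms) and FA rate.

    The FA rate divides false alarms by NoGo trials over the retained
    blocks. Cells with no retained hits or no NoGo trials come back with NaN
    and ``missing=True``.
    """
    rows = []
    for (p, s), grp in trials.groupby(["participant", "session"]):
        hits = grp.loc[grp["feedback"].isin(_HIT), "rt_ms"]
        n_nogo = int((grp["stim"] == "NoGo").sum())
        n_fa = int((grp["feedback"] == "fa").sum())
        group = grp["group"].iloc[0]
        rows.append(
            {
                "participant": p,
                "group": group,
                "session": s,
                "mean_rt_hit_ms": hits.mean() if len(hits) else np.nan,
                "fa_rate": n_fa / n_nogo if n_nogo else np.nan,
                "missing": len(hits) == 0 or n_nogo == 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics

@dataclass
class AnovaTable:
    effects: pd.DataFrame      # effect, SS, df1, df2, F, p, ges
    followups: pd.DataFrame    # group, t, df, p, p_holm, r
    bf01: float | None = None
    ss_total: float = np.nan


def _check_design(dv: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Pivot a long (participant, group, session, value) table to wide and
    return (wide, pre, post, group codes)."""
    sessions = sorted(dv["session"].unique())
    if len(sessions) != 2:
        raise ValueError(f"need exactly 2 sessions, got {sessions}")
    order = ["pre", "post"] if set(sessions) == {"pre", "post"} else sessions
    wide = dv.pivot_table(
        index=["participant", "group"], columns="session", values="value"
    ).reset_index()
    if wide[order].isna().any().any():
        bad = wide.loc[wide[order].isna().any(axis=1), "participant"].tolist()
        raise ValueError(f"missing cells for participants {bad}")
    groups = sorted(wide["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    for g in groups:
        if (wide["group"] == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 participants")
    return wide, wide[order[0]].to_numpy(), wide[order[1]].to_numpy(), wide["group"].to_numpy()


def mixed_anova(dv: pd.DataFrame) -> AnovaTable:
    """Classical sum-of-squares 2x2 mixed ANOVA (group between, session
    within) with generalized eta squared and Holm-corrected follow-ups.

    The decomposition is exact and additive: with subject sums m_i (between
    part) and differences d_i (within part),

        SS_group       = 2 * sum_g n_g (mbar_g - mbar)^2
        SS_subj(group) = 2 * sum_i (m_i - mbar_g(i))^2
        SS_session     = N * dbar^2 / 2
        SS_interaction = sum_g n_g (dbar_g - dbar)^2 / 2
        SS_sess x subj = sum_i (d_i - dbar_g(i))^2 / 2

    and ges(effect) = SS_effect / (SS_effect + SS_subj(group) + SS_sxs).
    Follow-ups are paired pre/post t-tests per group with
    r = sqrt(t^2 / (t^2 + df)) and Holm adjustment across the family.
    """
    wide, pre, post, grp = _check_design(dv)
    groups = sorted(set(grp))
    m = (pre + post) / 2.0
    d = post - pre
    n = len(m)
    n_g = {g: int((grp == g).sum()) for g in groups}
    mbar, dbar = m.mean(), d.mean()
    mbar_g = {g: m[grp == g].mean() for g in groups}
    dbar_g = {g: d[grp == g].mean() for g in groups}

    ss_group = 2.0 * sum(n_g[g] * (mbar_g[g] - mbar) ** 2 for g in groups)
    ss_subj = 2.0 * sum((m[grp == g] - mbar_g[g]).dot(m[grp == g] - mbar_g[g]) for g in groups)
    ss_session = n * dbar**2 / 2.0
    ss_inter = sum(n_g[g] * (dbar_g[g] - dbar) ** 2 for g in groups) / 2.0
    ss_sxs = sum(
        (d[grp == g] - dbar_g[g]).dot(d[grp == g] - dbar_g[g]) for g in groups
    ) / 2.0
    y = np.concatenate([pre, post])
    ss_total = float(((y - y.mean()) ** 2).sum())

    df_between, df_within = n - 2, n - 2
    rows = []
    for name, ss, df1, df_err, ms_err in [
        ("group", ss_group, 1, df_between, ss_subj / df_between),
        ("session", ss_session, 1, df_within, ss_sxs / df_within),
        ("interaction", ss_inter, 1, df_within, ss_sxs / df_within),
    ]:
        f = (ss / df1) / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
        p = float(stats.f.sf(f, df1, df_err)) if np.isfinite(f) else 0.0
        ges = ss / (ss + ss_subj + ss_sxs) if (ss + ss_subj + ss_sxs) > 0 else 0.0
        rows.append(
            {"effect": name, "SS": ss, "df1": df1, "df2": df_err, "F": f, "p": p, "ges": ges}
        )
    effects = pd.DataFrame(rows)

    fu_rows = []
    for g in groups:
        res = stats.ttest_rel(post[grp == g], pre[grp == g])
        df = n_g[g] - 1
        tval = float(res.statistic)
        fu_rows.append(
            {
                "group": g,
                "t": tval,
                "df": df,
                "p": float(res.pvalue),
                "r": float(np.sqrt(tval**2 / (tval**2 + df))),
            }
        )
    followups = pd.DataFrame(fu_rows)
    followups["p_holm"] = multipletests(followups["p"], method="holm")[1]

    return AnovaTable(effects=effects, followups=followups, ss_total=ss_total)


def effect_size_r(t: float, df: int) -> float:
    """r = sqrt(t^2 / (t^2 + df)), the t-to-r effect-size conversion."""
    return float(np.sqrt(t**2 / (t**2 + df)))


def bf01_interaction(dv: pd.DataFrame) -> float:
    """Bayes factor for the *absence* of the group x session interaction.

    Compares the additive model (subject + session) against the full model
    (subject + session + group:session) through the BIC approximation
    BF01 = exp((BIC_full - BIC_additive) / 2). With subject effects absorbing
    the between-subject variance, the two models differ only in the
    within-subject part, giving the closed form

        BF01 = sqrt(n_obs) * (RSS_full / RSS_additive)^(n_obs / 2),

    with RSS_additive = sum_i (d_i - dbar)^2 / 2 and
    RSS_full = sum_i (d_i - dbar_g(i))^2 / 2. BF01 > 1 favors no interaction
    and grows with sample size under additivity; BF01 < 1 favors the
    interaction. This is a large-sample approximation, not a prior-based
    integration, so only its direction and ordering are interpretable.
    """
    _, pre, post, grp = _check_design(dv)
    d = post - pre
    n_obs = 2 * len(d)
    groups = sorted(set(grp))
    rss_add = float(((d - d.mean()) ** 2).sum()) / 2.0
    rss_full = float(
        sum(((d[grp == g] - d[grp == g].mean()) ** 2).sum() for g in groups)
    ) / 2.0
    if rss_full <= 0 or rss_add <= 0:
        raise ValueError("zero residual variance: Bayes factor undefined")
    # exp((BIC_full - BIC_add)/2) with BIC = n ln(RSS/n) + k ln(n); dk = 1
    log_bf01 = 0.5 * (n_obs * np.log(rss_full / rss_add) + np.log(n_obs))
    return float(np.exp(log_bf01))


def training_regression(days, values) -> dict:
    """OLS of a daily performance mean on training day (1..n_days).

    Returns intercept b0, slope b1, the slope's t and p, and the signed
    effect size r = sign(b1) * sqrt(t^2/(t^2+df)) — identical to the Pearson
    correlation of value with day for a simple regression.
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 days")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    df = x.size - 2
    if res.stderr > 0:
        t = res.slope / res.stderr
    else:
        t = np.inf if res.slope != 0 else 0.0
    r = np.sign(res.slope) * np.sqrt(t**2 / (t**2 + df)) if np.isfinite(t) else np.sign(res.slope)
    return {
        "b0": float(res.intercept),
        "b1": float(res.slope),
        "t": float(t),
        "df": int(df),
        "p": float(res.pvalue),
        "r": float(r),
    }


def tradeoff_correlation(delta_rt, delta_fa) -> tuple[float, float]:
    """Pearson correlation between per-participant post-pre RT change and
    post-pre FA-rate change (negative under a speed-accuracy trade-off)."""
    x = np.asarray(delta_rt, dtype=float)
    y = np.asarray(delta_fa, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired deltas")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in deltas")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
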