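"""Synthetic data generators for every pipeline stage.

Two families of generators are provided, both pure functions of
(config, seed):

* **ERP simulator** — 64-channel average-reference-free scalp potentials
  built from quasi-stable component topographies (an early visual
  positivity, a fronto-central N2-like negativity, a centro-parietal
  P3-like positivity) with Gaussian temporal envelopes, multiplicative
  subject gains, and spatially correlated AR(1) noise. Group x session
  effects can be injected either as a pure response-gain change (scales GFP,
  leaves the normalized topography untouched) or as a pure topographic
  rotation at fixed GFP (changes the map configuration, leaves GFP
  untouched to machine precision), plus an age-like group latency shift of
  the late components. The construction makes strength-only and
  topography-only injections exact, which is what lets the test suite ask
  the GFP and topographic randomization tests to each detect their own kind
  of effect and not the other.

* **Go/NoGo simulator** — trial streams with the task's exact block
  composition (36 Go / 24 NoGo), probabilistic cues (Go follows a green cue
  with probability 0.70 and a red cue with probability 0.30), ex-Gaussian
  response times with group x session location shifts, an adaptive
  running-median response deadline (RTT) driving trial feedback, a logistic
  false-alarm model modulated by time pressure, per-day training drifts,
  and a negative coupling between individual RT change and FA-rate change
  (a speed-accuracy trade-off).

Behavioral defaults reproduce the condition means and between-subject
spreads of the emulated study population (older adults ~467 ms / 12.5% FA
before training, young adults ~389 ms / 14.8% FA; training slopes around
-4 to -5 ms/day with FA growing ~0.75 points/day).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import TRIAL_COLUMNS, feedback_for
from .field_core import Montage, average_reference
from .preprocess import EpochSet, Erp
from .randomization import GroupDesign

__all__ = [
    "default_montage",
    "TemplateSpec",
    "EffectSpec",
    "ErpSimConfig",
    "simulate_erp_dataset",
    "simulate_epoch_set",
    "BehavSimConfig",
    "behav_config_training",
    "behav_config_age",
    "simulate_behavior_session",
    "simulate_behavior_dataset",
    "simulate_training_log",
]


def default_montage() -> Montage:
    """The standard 64-channel 10-10 cap (Biosemi layout), positions
    normalized to the unit sphere."""
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    pos = std.get_positions()["ch_pos"]
    labels = list(pos)
    arr = np.array([pos[k] for k in labels], dtype=float)
    arr = arr / np.linalg.norm(arr, axis=1, keepdims=True)
    return Montage(tuple(labels), arr)


# ---------------------------------------------------------------------------
# ERP simulation

@dataclass(frozen=True)
class TemplateSpec:
    """One quasi-stable component: spatial focus + Gaussian time course."""

    name: str
    focus_channel: str          # electrode at the spatial peak
    center_ms: float
    width_ms: float             # Gaussian SD of the envelope
    amplitude_uv: float         # signed peak amplitude at the focus
    spatial_fwhm: float = 0.9   # spread of the map over chord distance


@dataclass(frozen=True)
class EffectSpec:
    """A group x session x window manipulation.

    kind="gain": multiply the whole signal inside the window by ``gain``
    (pure GFP change). kind="topo": rotate each map inside the window by
    ``angle_deg`` toward a fixed orthogonal pattern at unchanged GFP (pure
    topography change).
    """

    kind: str                   # "gain" | "topo"
    window_ms: tuple[float, float]
    group: str | None = None    # None: both groups
    session: str | None = "post"
    gain: float = 1.0
    angle_deg: float = 0.0


_DEFAULT_TEMPLATES = (
    TemplateSpec("P1", "Oz", 120.0, 25.0, 3.0),
    TemplateSpec("N2", "FCz", 250.0, 35.0, -4.0),
    TemplateSpec("P3", "CPz", 420.0, 55.0, 5.0),
)


@dataclass(frozen=True)
class ErpSimConfig:
    montage: Montage = field(default_factory=default_montage)
    srate: float = 256.0
    window_ms: tuple[float, float] = (-100.0, 700.0)
    templates: tuple[TemplateSpec, ...] = _DEFAULT_TEMPLATES
    n_per_group: int = 16
    group_names: tuple[str, str] = ("A", "B")
    subject_gain_sd: float = 0.1
    snr: float = 5.0            # signal RMS / noise RMS at the ERP level; 0 = noise off
    noise_spatial_fwhm: float = 0.6   # chord-distance FWHM of noise smoothing
    noise_ar1: float = 0.95
    effects: tuple[EffectSpec, ...] = ()
    latency_shift_ms: dict[str, float] = field(default_factory=dict)  # group -> ms
    shift_components: tuple[str, ...] | None = None  # None: delay all components
    seed: int = 0

    def times_ms(self) -> np.ndarray:
        n = int(np.floor((self.window_ms[1] - self.window_ms[0]) / 1000.0 * self.srate))
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.srate

    def validate(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        t0, t1 = self.window_ms
        for e in self.effects:
            if e.kind not in ("gain", "topo"):
                raise ValueError(f"unknown effect kind {e.kind!r}")
            if not (0.0 <= e.angle_deg <= 90.0):
                raise ValueError("mixing angle must be in [0, 90] degrees")
            if e.window_ms[0] < t0 or e.window_ms[1] > t1:
                raise ValueError(f"effect window {e.window_ms} outside epoch")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 subjects per group")


def _component_map(montage: Montage, spec: TemplateSpec) -> np.ndarray:
    """Signed, average-referenced spatial pattern peaking at the focus."""
    center = montage.positions[montage.index(spec.focus_channel)]
    d = np.linalg.norm(montage.positions - center, axis=1)
    sigma = spec.spatial_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    raw = np.exp(-(d**2) / (2.0 * sigma**2))
    return average_reference(raw, axis=0)


def _orthogonal_pattern(montage: Montage, against: np.ndarray) -> np.ndarray:
    """A fixed unit-GFP map orthogonal (zero spatial covariance) to
    ``against``; used as the rotation target of topographic effects."""
    alt = _component_map(montage, TemplateSpec("alt", "C3", 0, 1, 1.0)) - _component_map(
        montage, TemplateSpec("alt2", "C4", 0, 1, 1.0)
    )
    a = against / max(np.linalg.norm(against), 1e-30)
    b = alt - (alt @ a) * a
    b = average_reference(b, axis=0)
    return b / b.std()


def _noise(
    rng: np.random.Generator,
    montage: Montage,
    n_tf: int,
    spatial_fwhm: float,
    ar1: float,
) -> np.ndarray:
    """Unit-RMS spatially smoothed, temporally AR(1)-correlated noise."""
    c = montage.n_channels
    w = rng.standard_normal((c, n_tf))
    if ar1 > 0:
        x = np.empty_like(w)
        x[:, 0] = w[:, 0]
        scale = np.sqrt(1.0 - ar1**2)
        for t in range(1, n_tf):
            x[:, t] = ar1 * x[:, t - 1] + scale * w[:, t]
    else:
        x = w
    if spatial_fwhm > 0:
        d = np.linalg.norm(
            montage.positions[:, None, :] - montage.positions[None, :, :], axis=2
        )
        sigma = spatial_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        kern = np.exp(-(d**2) / (2.0 * sigma**2))
        kern /= np.sqrt((kern**2).sum(axis=1, keepdims=True))
        x = kern @ x
    return x / np.sqrt(np.mean(x**2))


def _clean_signal(cfg: ErpSimConfig, group: str, session: str) -> np.ndarray:
    """Noise-free channels x timeframes signal for one design cell."""
    t = cfg.times_ms()
    shift = cfg.latency_shift_ms.get(group, 0.0)
    sig = np.zeros((cfg.montage.n_channels, t.size))
    shifted = (
        tuple(s.name for s in cfg.templates)
        if cfg.shift_components is None
        else cfg.shift_components
    )
    for spec in cfg.templates:
        center = spec.center_ms + (shift if spec.name in shifted else 0.0)
        env = np.exp(-((t - center) ** 2) / (2.0 * spec.width_ms**2))
        sig += spec.amplitude_uv * np.outer(_component_map(cfg.montage, spec), env)
    for eff in cfg.effects:
        if eff.group is not None and eff.group != group:
            continue
        if eff.session is not None and eff.session != session:
            continue
        win = (t >= eff.window_ms[0]) & (t <= eff.window_ms[1])
        if eff.kind == "gain":
            sig[:, win] *= eff.gain
        else:
            sig[:, win] = _rotate_maps(
                sig[:, win], cfg.montage, np.deg2rad(eff.angle_deg)
            )
    return sig


def _rotate_maps(maps: np.ndarray, montage: Montage, theta: float) -> np.ndarray:
    """Rotate each column map toward a fixed orthogonal pattern, preserving
    its GFP exactly: u -> cos(theta) u + sin(theta) gfp(u) b_perp(u)."""
    out = maps.copy()
    base = _orthogonal_pattern(montage, average_reference(maps.mean(axis=1), axis=0))
    c = maps.shape[0]
    for j in range(maps.shape[1]):
        u = average_reference(maps[:, j], axis=0)
        g = u.std()
        if g == 0:
            continue
        a = u / (g * np.sqrt(c))           # unit vector norm
        b = base - (base @ a) * a          # orthogonalize against this map
        b = average_reference(b, axis=0)
        gb = b.std()
        if gb == 0:
            continue
        out[:, j] = np.cos(theta) * u + np.sin(theta) * g * (b / gb)
    return out


def simulate_erp_dataset(cfg: ErpSimConfig) -> GroupDesign:
    """Generate a full 2x2 design of per-subject ERPs plus a ground-truth
    sidecar (``design.ground_truth``) recording injected effects.

    subject ERP = subject_gain x cell signal + noise, with noise RMS =
    signal RMS / snr (snr=0 switches noise off). Seed-deterministic.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times_ms()
    subjects, group_of, erp_of = [], {}, {}
    cell_sig = {
        (g, s): _clean_signal(cfg, g, s)
        for g in cfg.group_names
        for s in ("pre", "post")
    }
    sig_rms = np.sqrt(np.mean(np.stack(list(cell_sig.values())) ** 2))
    noise_rms = sig_rms / cfg.snr if cfg.snr > 0 else 0.0
    for g in cfg.group_names:
        for i in range(cfg.n_per_group):
            sid = f"{g}{i:02d}"
            subjects.append(sid)
            group_of[sid] = g
            gain = 1.0 + cfg.subject_gain_sd * rng.standard_normal()
            for sess in ("pre", "post"):
                data = gain * cell_sig[(g, sess)]
                if noise_rms > 0:
                    data = data + noise_rms * _noise(
                        rng, cfg.montage, t.size, cfg.noise_spatial_fwhm, cfg.noise_ar1
                    )
                erp_of[(sid, sess)] = Erp(
                    data=average_reference(data, axis=0),
                    srate=cfg.srate,
                    window_ms=cfg.window_ms,
                    condition=sess,
                    participant=sid,
                    group=g,
                    avg_referenced=True,
                    n_epochs_used=1,
                )
    gt = {
        "effects": [
            {
                "kind": e.kind,
                "window_ms": list(e.window_ms),
                "group": e.group,
                "session": e.session,
                "gain": e.gain,
                "angle_deg": e.angle_deg,
            }
            for e in cfg.effects
        ],
        "latency_shift_ms": dict(cfg.latency_shift_ms),
        "component_centers_ms": {s.name: s.center_ms for s in cfg.templates},
    }
    return GroupDesign(subjects, group_of, erp_of, ground_truth=gt)


def simulate_epoch_set(
    cfg: ErpSimConfig,
    participant: str,
    group: str,
    session: str,
    n_trials: int = 40,
    trial_noise_uv: float = 8.0,
    seed: int | None = None,
) -> EpochSet:
    """Single-trial epochs for one subject cell: shared clean signal plus
    independent per-trial noise of the given RMS amplitude (uV)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sig = _clean_signal(cfg, group, session)
    trials = np.stack(
        [
            sig
            + trial_noise_uv
            * _noise(rng, cfg.montage, sig.shape[1], cfg.noise_spatial_fwhm, cfg.noise_ar1)
            for _ in range(n_trials)
        ]
    )
    trials -= trials.mean(axis=2, keepdims=True)  # whole-epoch baseline
    return EpochSet(
        trials, cfg.srate, cfg.window_ms, session, participant, group
    )


# ---------------------------------------------------------------------------
# Go/NoGo behavioral simulation

@dataclass(frozen=True)
class CellParams:
    """Trial-generating parameters of one group x session cell."""

    mean_rt_ms: float
    between_sd_ms: float
    fa_rate: float
    fa_between_sd: float


@dataclass(frozen=True)
class BehavSimConfig:
    """Parameters of the Go/NoGo trial-stream generator.

    Cue contingencies: the probability that a trial is Go given a green or
    red cue. The marginal Go probability is fixed by the block composition
    (36/60), which pins the green-cue frequency at
    (p_go - p_go_red) / (p_go_green - p_go_red) = 0.75.
    """

    blocks_per_session: int = 6
    n_go: int = 36
    n_nogo: int = 24
    p_go_given_green: float = 0.70
    p_go_given_red: float = 0.30
    # trial-level ex-Gaussian RT dispersion (location comes from the cell)
    rt_sigma_ms: float = 45.0
    rt_tau_ms: float = 75.0
    miss_prob: float = 0.03
    # false alarms: logistic in standardized time pressure (rtt - rt_mean)
    fa_slope: float = 1.0
    fa_scale_ms: float = 100.0
    cells: dict[tuple[str, str], CellParams] = field(default_factory=dict)
    # speed-accuracy trade-off: corr of individual (delta RT, delta FA)
    delta_coupling: float = -0.45
    delta_rt_sd_ms: float = 30.0
    delta_fa_sd: float = 0.06
    # training drifts per group: (rt_b0, rt_b1_ms_per_day, fa_b0_pct, fa_b1_pct_per_day)
    training_drift: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "young": (453.4, -3.69, 15.14, 0.75),
            "older": (640.09, -4.81, 7.58, 0.73),
        }
    )
    training_blocks_per_day: int = 12   # 4 app sessions of 3 blocks
    include_orange_cue: bool = False    # training-app-only 50% cue level
    p_go_given_orange: float = 0.50
    seed: int = 0

    @property
    def p_green(self) -> float:
        p_go = self.n_go / (self.n_go + self.n_nogo)
        return (p_go - self.p_go_given_red) / (
            self.p_go_given_green - self.p_go_given_red
        )

    def validate(self) -> None:
        for p in (self.p_go_given_green, self.p_go_given_red, self.miss_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_go <= 0 or self.n_nogo <= 0:
            raise ValueError("trial counts must be positive")
        if not (0.0 < self.p_green < 1.0):
            raise ValueError("cue contingencies incompatible with composition")


def behav_config_training(**kw) -> BehavSimConfig:
    """Older adults, inhibition training vs active control: the training
    group trades more speed for more false alarms after the intervention."""
    cells = {
        ("training", "pre"): CellParams(467.3, 42.2, 0.125, 0.072),
        ("training", "post"): CellParams(410.6, 50.8, 0.222, 0.125),
        ("control", "pre"): CellParams(486.9, 55.0, 0.121, 0.081),
        ("control", "post"): CellParams(432.7, 49.6, 0.165, 0.097),
    }
    return BehavSimConfig(cells=cells, **kw)


def behav_config_age(**kw) -> BehavSimConfig:
    """Young vs older adults, both with inhibition training."""
    cells = {
        ("young", "pre"): CellParams(388.9, 29.0, 0.148, 0.077),
        ("young", "post"): CellParams(345.1, 32.4, 0.258, 0.117),
        ("older", "pre"): CellParams(467.3, 42.2, 0.125, 0.072),
        ("older", "post"): CellParams(410.6, 50.8, 0.222, 0.125),
    }
    return BehavSimConfig(cells=cells, **kw)


def _exgauss_median_offset(sigma: float, tau: float) -> float:
    """Median minus mean of a centered ex-Gaussian (negative: right skew).

    The adaptive RTT tracks the running *median* of the RTs, which for a
    right-skewed distribution sits below the mean; the FA model's
    time-pressure term is centered on the median so that the average
    pressure is ~0 and the subject's FA rate matches its target.
    """
    if sigma <= 0 or tau <= 0:
        return 0.0
    from scipy.stats import exponnorm

    return float(exponnorm.median(tau / sigma, loc=-tau, scale=sigma))


def _sample_rt(
    rng: np.random.Generator, mean_ms: float, sigma: float, tau: float
) -> float:
    """Centered ex-Gaussian draw: normal + exponential, shifted so the
    expectation equals ``mean_ms`` (degenerates to the mean when both
    dispersion parameters are 0)."""
    rt = mean_ms + sigma * rng.standard_normal()
    if tau > 0:
        rt += rng.exponential(tau) - tau
    return max(rt, 1.0)


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1.0 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def simulate_behavior_session(
    cfg: BehavSimConfig,
    participant: str,
    session: str,
    group: str = "",
    mean_rt_ms: float | None = None,
    fa_rate: float | None = None,
    rng: np.random.Generator | None = None,
    n_blocks: int | None = None,
) -> pd.DataFrame:
    """Generate one session of Go/NoGo blocks for one participant.

    Each block holds exactly ``n_go`` Go and ``n_nogo`` NoGo trials in random
    order; cues are assigned per trial so that the Go|cue contingencies hold
    (Bayes inversion of the configured conditional probabilities). The RTT
    follows the running-median rule and determines fast/late hit feedback;
    the per-trial false-alarm probability is a logistic function of the
    standardized time pressure (rtt - subject mean RT) / fa_scale, centered
    on the subject's FA rate. Deterministic given the rng state.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if mean_rt_ms is None or fa_rate is None:
        if (group, session) not in cfg.cells:
            raise KeyError(f"no cell parameters for {(group, session)}")
        cell = cfg.cells[(group, session)]
        mean_rt_ms = cell.mean_rt_ms if mean_rt_ms is None else mean_rt_ms
        fa_rate = cell.fa_rate if fa_rate is None else fa_rate
    n_blocks = cfg.blocks_per_session if n_blocks is None else n_blocks

    p_go = cfg.n_go / (cfg.n_go + cfg.n_nogo)
    if cfg.include_orange_cue:
        # fix P(orange)=0.2 and solve the green/red marginals so that all
        # three Go|cue contingencies hold jointly with the block composition
        p_orange = 0.2
        p_grn = (
            p_go
            - cfg.p_go_given_red
            - (cfg.p_go_given_orange - cfg.p_go_given_red) * p_orange
        ) / (cfg.p_go_given_green - cfg.p_go_given_red)
        marginals = {"green": p_grn, "orange": p_orange, "red": 1.0 - p_grn - p_orange}
        conds = {
            "green": cfg.p_go_given_green,
            "orange": cfg.p_go_given_orange,
            "red": cfg.p_go_given_red,
        }
    else:
        marginals = {"green": cfg.p_green, "red": 1.0 - cfg.p_green}
        conds = {"green": cfg.p_go_given_green, "red": cfg.p_go_given_red}
    cues = list(marginals)
    p_cue_given_go = np.array([conds[c] * marginals[c] / p_go for c in cues])
    p_cue_given_nogo = np.array(
        [(1.0 - conds[c]) * marginals[c] / (1.0 - p_go) for c in cues]
    )
    base_logit = _logit(fa_rate)
    rt_median = mean_rt_ms + _exgauss_median_offset(cfg.rt_sigma_ms, cfg.rt_tau_ms)
    rows = []
    for block in range(1, n_blocks + 1):
        stims = np.array(["Go"] * cfg.n_go + ["NoGo"] * cfg.n_nogo)
        rng.shuffle(stims)
        rtt = np.nan
        go_rts: list[float] = []
        for idx, stim in enumerate(stims):
            p_cue = p_cue_given_go if stim == "Go" else p_cue_given_nogo
            cue = cues[int(rng.choice(len(cues), p=p_cue))]
            rtt_now = rtt if np.isfinite(rtt) else np.nan
            if stim == "Go":
                responded = rng.random() >= cfg.miss_prob
                rt = (
                    _sample_rt(rng, mean_rt_ms, cfg.rt_sigma_ms, cfg.rt_tau_ms)
                    if responded
                    else np.nan
                )
                if responded:
                    thresh = rt if not go_rts else float(np.median(go_rts))
                    rtt_now = thresh
                    go_rts.append(rt)
                    rtt = float(np.median(go_rts))
            else:
                pressure = (
                    ((rtt_now if np.isfinite(rtt_now) else rt_median) - rt_median)
                    / cfg.fa_scale_ms
                )
                p_fa = _expit(base_logit - cfg.fa_slope * pressure)
                responded = rng.random() < p_fa
                rt = (
                    _sample_rt(rng, mean_rt_ms * 0.9, cfg.rt_sigma_ms, cfg.rt_tau_ms)
                    if responded
                    else np.nan
                )
            fb = feedback_for(
                stim,
                responded,
                rt if responded else None,
                rtt_now if np.isfinite(rtt_now) else None,
            )
            rows.append(
                {
                    "participant": participant,
                    "group": group,
                    "session": session,
                    "block": block,
                    "trial_index": idx + 1,
                    "cue": cue,
                    "stim": stim,
                    "responded": bool(responded),
                    "rt_ms": rt if responded else np.nan,
                    "rtt_ms": rtt_now,
                    "feedback": fb,
                }
            )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_behavior_dataset(
    cfg: BehavSimConfig, n_per_group: dict[str, int] | int = 29, seed: int | None = None
) -> pd.DataFrame:
    """Full pre/post trial tables for two groups with coupled individual
    session effects.

    Each subject draws a baseline offset (between-subject spread of the pre
    cell) and a (delta RT, delta FA) pair from a bivariate normal whose
    correlation is the configured speed-accuracy coupling; post-session
    parameters are pre + delta, recentered on the configured post-cell
    means.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    groups = sorted({g for g, _ in cfg.cells})
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in groups}
    rho = cfg.delta_coupling
    cov = np.array(
        [
            [cfg.delta_rt_sd_ms**2, rho * cfg.delta_rt_sd_ms * cfg.delta_fa_sd],
            [rho * cfg.delta_rt_sd_ms * cfg.delta_fa_sd, cfg.delta_fa_sd**2],
        ]
    )
    tables = []
    for g in groups:
        pre, post = cfg.cells[(g, "pre")], cfg.cells[(g, "post")]
        for i in range(n_per_group[g]):
            pid = f"{g}{i:02d}"
            rt_pre = pre.mean_rt_ms + pre.between_sd_ms * rng.standard_normal()
            fa_pre = float(
                np.clip(pre.fa_rate + pre.fa_between_sd * rng.standard_normal(), 0.01, 0.95)
            )
            d_rt, d_fa = rng.multivariate_normal(
                [post.mean_rt_ms - pre.mean_rt_ms, post.fa_rate - pre.fa_rate], cov
            )
            rt_post = max(rt_pre + d_rt, 150.0)
            fa_post = float(np.clip(fa_pre + d_fa, 0.01, 0.95))
            for sess, rt_m, fa_m in [("pre", rt_pre, fa_pre), ("post", rt_post, fa_post)]:
                tables.append(
                    simulate_behavior_session(
                        cfg, pid, sess, group=g, mean_rt_ms=rt_m, fa_rate=fa_m, rng=rng
                    )
                )
    return pd.concat(tables, ignore_index=True)


def simulate_training_log(
    cfg: BehavSimConfig,
    group: str = "older",
    n_days: int = 15,
    noise: bool = True,
    seed: int | None = None,
) -> pd.DataFrame:
    """Daily in-app Go/NoGo trial tables over the intervention.

    Day d draws trials with RT location b0 + b1*d and FA probability
    (fa_b0 + fa_b1*d)/100, per the group's configured drift. With
    ``noise=False`` all dispersion is switched off, so the daily mean RT
    equals the configured line exactly and a training-day regression
    recovers the slope to machine precision. Tables carry a ``day`` column
    and session labels ``day01``..``dayNN``.
    """
    if n_days < 3:
        raise ValueError("n_days must be >= 3")
    cfg.validate()
    if group not in cfg.training_drift:
        raise KeyError(f"no training drift configured for group {group!r}")
    rt_b0, rt_b1, fa_b0, fa_b1 = cfg.training_drift[group]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    run_cfg = cfg
    if not noise:
        run_cfg = replace(cfg, rt_sigma_ms=0.0, rt_tau_ms=0.0, miss_prob=0.0, fa_slope=0.0)
    days = []
    for d in range(1, n_days + 1):
        tab = simulate_behavior_session(
            run_cfg,
            participant=f"{group}_trainee",
            session=f"day{d:02d}",
            group=group,
            mean_rt_ms=rt_b0 + rt_b1 * d,
            fa_rate=float(np.clip((fa_b0 + fa_b1 * d) / 100.0, 0.001, 0.999)),
            rng=rng,
            n_blocks=cfg.training_blocks_per_day,
        )
        tab["day"] = d
        days.append(tab)
    return pd.concat(days, ignore_index=True)


def training_schedule_sessions(
    sessions_per_day: int = 4, days_per_week: int = 5, weeks: int = 3
) -> int:
    """Total training sessions implied by the default intervention schedule
    (four 3-block sessions a day, five days a week, for three weeks)."""
    return sessions_per_day * days_per_week * weeks
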