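"""Time-frame-wise randomization statistics for 2x2 mixed designs on
multichannel ERPs, with duration-threshold multiple-comparison correction,
plus a generic Monte-Carlo cluster-extent calibrator for node graphs.

Two orthogonal sensor-level metrics are tested at every timeframe:

* ``gfp`` — response *strength*: the effect contrast of scalar global field
  power values.
* ``topo`` — field *configuration*: subject-condition maps are
  average-referenced and scaled to unit GFP, and the statistic is the GFP of
  the effect's contrast map (a TANOVA-style topographic consistency
  statistic). Rescaling any cell's maps leaves this metric unchanged.

The null distribution comes from re-randomization respecting the mixed
design: the within factor (session) is randomized by swapping each subject's
pre/post labels independently with probability 1/2; the between factor
(group) by shuffling group membership across subjects; the interaction by
both. These schemes give approximate exchangeability under the respective
nulls. All statistics are magnitudes, so the tests are inherently two-sided.

Correction for multiple comparisons over timeframes uses a duration
threshold: the minimal run length of consecutive pointwise-significant
timeframes whose occurrence probability under the permutation null is at
most alpha. The permutation p-value series needed for this is obtained by
the rank trick (each permutation's statistic ranked within the pooled
permutation distribution per timeframe), which costs O(n_perm) rather than
nested permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .preprocess import Erp

__all__ = [
    "GroupDesign",
    "TfTestResult",
    "tf_randomization_test",
    "perm_p_matrix",
    "duration_threshold",
    "longest_run",
    "cluster_extent_threshold",
    "write_result",
]

_METRICS = ("gfp", "topo")
_EFFECTS = ("session", "group", "interaction")
_SESSIONS = ("pre", "post")


@dataclass
class GroupDesign:
    """A 2x2 mixed design: between factor group (A/B), within factor session.

    Every subject must have an ERP for both sessions, all on the same montage
    and time base.
    """

    subjects: list[str]
    group_of: dict[str, str]
    erp_of: dict[tuple[str, str], Erp]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = sorted(set(self.group_of.values()))
        if len(groups) != 2:
            raise ValueError(f"need exactly 2 groups, got {groups}")
        for g in groups:
            if sum(self.group_of[s] == g for s in self.subjects) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 subjects")
        shapes = set()
        for s in self.subjects:
            for sess in _SESSIONS:
                if (s, sess) not in self.erp_of:
                    raise ValueError(f"missing session {sess!r} for subject {s!r}")
                e = self.erp_of[(s, sess)]
                shapes.add((e.data.shape, e.srate, tuple(e.window_ms)))
        if len(shapes) != 1:
            raise ValueError("all ERPs must share montage, srate and window")

    @property
    def group_labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.group_of.values())))

    def data_array(self) -> np.ndarray:
        """Stack to subjects x sessions x channels x timeframes."""
        return np.stack(
            [
                np.stack([self.erp_of[(s, sess)].data for sess in _SESSIONS])
                for s in self.subjects
            ]
        )

    def group_mask(self) -> np.ndarray:
        """Boolean mask, True where the subject is in the first group."""
        a = self.group_labels[0]
        return np.array([self.group_of[s] == a for s in self.subjects])


@dataclass
class TfTestResult:
    metric: str
    effect: str
    stat: np.ndarray          # observed statistic per timeframe
    p: np.ndarray             # pointwise permutation p-values
    n_perm: int
    alpha: float
    duration_threshold_tf: int
    pois: list[tuple[int, int]]  # inclusive (start_tf, end_tf) runs
    times_ms: np.ndarray | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha


# ---------------------------------------------------------------------------
# feature extraction and the vectorized permutation engine

def _features(data: np.ndarray, metric: str) -> np.ndarray:
    """Per-subject, per-session feature arrays.

    gfp  -> (S, 2, T) scalar GFP series.
    topo -> (S, 2, C, T) average-referenced unit-GFP maps (zero maps where
            GFP is exactly 0, reported as no topographic information).
    """
    if metric == "gfp":
        return data.std(axis=2)
    if metric == "topo":
        ref = data - data.mean(axis=2, keepdims=True)
        g = ref.std(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(g > 0, ref / np.where(g > 0, g, 1.0), 0.0)
        return out
    raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def _effect_feature(f: np.ndarray, effect: str) -> np.ndarray:
    """Collapse the session axis per the effect: the within-subject
    difference (post - pre) for session/interaction, the subject mean for the
    group main effect."""
    if effect in ("session", "interaction"):
        return f[:, 1] - f[:, 0]
    if effect == "group":
        return f.mean(axis=1)
    raise ValueError(f"unknown effect {effect!r}; expected one of {_EFFECTS}")


def _perm_weights(
    effect: str, in_a: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed (S,) and permutation (n_perm, S) subject weight vectors.

    The statistic is |w @ feature| (gfp) or the GFP of w @ maps (topo); the
    weights encode both the effect contrast and the randomization scheme.
    """
    s = in_a.size
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())

    def group_w(mask: np.ndarray) -> np.ndarray:
        return np.where(mask, 1.0 / n_a, -1.0 / n_b)

    if effect == "session":
        w_obs = np.full(s, 1.0 / s)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, s))
        return w_obs, flips / s
    # group or interaction: contrast of group means, group labels shuffled
    masks = np.empty((n_perm, s), dtype=bool)
    for b in range(n_perm):
        masks[b] = in_a[rng.permutation(s)]
    w_perm = np.where(masks, 1.0 / n_a, -1.0 / n_b)
    if effect == "interaction":
        w_perm = w_perm * rng.choice([-1.0, 1.0], size=(n_perm, s))
    return group_w(in_a), w_perm


def _stat_from_weights(w: np.ndarray, feat: np.ndarray) -> np.ndarray:
    """Statistic per timeframe for a batch of weight vectors.

    feat is (S, T) for gfp — statistic |w @ feat| — or (S, C, T) for topo —
    statistic = GFP of the contrast map. Contrast maps are combinations of
    average-referenced maps, hence themselves zero-mean over channels, so
    their GFP is the RMS over channels.
    """
    w2 = np.atleast_2d(w)
    if feat.ndim == 2:
        out = np.abs(w2 @ feat)
    else:
        s_, c, t = feat.shape
        contrast = (w2 @ feat.reshape(s_, c * t)).reshape(len(w2), c, t)
        out = np.sqrt(np.mean(contrast**2, axis=1))
    return out[0] if w.ndim == 1 else out


def _observed_and_perm_stats(
    design: GroupDesign,
    metric: str,
    effect: str,
    n_perm: int,
    seed: int | np.random.Generator,
    chunk: int = 250,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    feat = _effect_feature(_features(design.data_array(), metric), effect)
    w_obs, w_perm = _perm_weights(effect, design.group_mask(), n_perm, rng)
    obs = _stat_from_weights(w_obs, feat)
    parts = [
        _stat_from_weights(w_perm[i : i + chunk], feat)
        for i in range(0, n_perm, chunk)
    ]
    perm = np.concatenate(parts, axis=0)
    # clamp numerical dust to an exact zero so that degenerate inputs
    # (identical cells) produce exact ties and hence p = 1
    tol = 1e-12 * max(float(np.abs(feat).max()), 1e-300)
    obs[obs < tol] = 0.0
    perm[perm < tol] = 0.0
    return obs, perm


def perm_p_matrix(
    design: GroupDesign,
    metric: str,
    effect: str,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Rank-based pseudo p-value series, one row per permutation.

    Each permutation's statistic at timeframe t is ranked within the pooled
    permutation distribution at t (mid-rank for ties) and converted to a
    right-tail pseudo p in (0, 1]. Used to calibrate the duration threshold
    without nested permutations.
    """
    _, perm = _observed_and_perm_stats(design, metric, effect, n_perm, seed)
    return _pseudo_p(perm)


def _pseudo_p(perm_stats: np.ndarray) -> np.ndarray:
    n = perm_stats.shape[0]
    ranks = stats.rankdata(perm_stats, axis=0, method="average")
    return (n - ranks + 1.0) / n


def longest_run(mask: np.ndarray) -> np.ndarray:
    """Length of the longest run of True along the last axis."""
    m = np.atleast_2d(mask).astype(bool)
    best = np.zeros(m.shape[0], dtype=int)
    cur = np.zeros(m.shape[0], dtype=int)
    for t in range(m.shape[1]):
        cur = (cur + 1) * m[:, t]
        best = np.maximum(best, cur)
    return best if mask.ndim > 1 else best[0]


def duration_threshold(perm_p: np.ndarray, alpha: float = 0.05) -> int:
    """Minimal significant-run duration calibrated from the permutation null.

    For each permutation's p-value series, take the longest run of p < alpha;
    return the smallest integer L such that P(longest run >= L) <= alpha
    under that distribution. Runs touching the epoch edges count like any
    other run. Returns T+1 when no finite run length is rare enough.
    """
    perm_p = np.atleast_2d(np.asarray(perm_p, dtype=float))
    if perm_p.size == 0:
        raise ValueError("empty permutation p matrix")
    runs = np.sort(longest_run(perm_p < alpha))
    n = runs.size
    for ell in range(1, perm_p.shape[1] + 2):
        exceed = n - np.searchsorted(runs, ell, side="left")
        if exceed / n <= alpha:
            return ell
    raise AssertionError("unreachable")


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) indices of True runs in a 1-D mask."""
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return [(int(a), int(b - 1)) for a, b in zip(idx[::2], idx[1::2])]


def tf_randomization_test(
    design: GroupDesign,
    metric: str,
    effect: str,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> TfTestResult:
    """Pointwise randomization test with duration-threshold correction.

    p(t) = (1 + #{permutation stat >= observed}) / (n_perm + 1), so p is
    never exactly 0 and degenerate (zero-variance) data give p = 1. Periods
    of interest (POIs) are runs of p < alpha at least as long as the
    calibrated duration threshold.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if effect not in _EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs, perm = _observed_and_perm_stats(design, metric, effect, n_perm, seed)
    p = (1.0 + (perm >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    dur = duration_threshold(_pseudo_p(perm), alpha)
    pois = [(a, b) for a, b in _runs_of(p < alpha) if b - a + 1 >= dur]
    any_erp = design.erp_of[(design.subjects[0], "pre")]
    return TfTestResult(
        metric=metric,
        effect=effect,
        stat=obs,
        p=p,
        n_perm=n_perm,
        alpha=alpha,
        duration_threshold_tf=dur,
        pois=pois,
        times_ms=any_erp.times_ms(),
    )


# ---------------------------------------------------------------------------
# generic cluster-extent calibration on node graphs

def cluster_extent_threshold(
    adjacency,
    smoothing_fwhm: float = 0.0,
    alpha_node: float = 0.05,
    fwer: float = 0.05,
    n_mc: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> int:
    """Monte-Carlo minimal cluster extent Ke on an arbitrary node graph.

    Simulates iid standard-normal node fields, optionally smooths them with a
    Gaussian kernel of the given FWHM over graph (shortest-path) distance —
    renormalized to unit node variance so the two-sided alpha_node threshold
    stays calibrated — thresholds two-sided, and records the maximal
    connected supra-threshold cluster size per draw. Returns the smallest Ke
    with P(max cluster >= Ke) <= fwer.

    ``adjacency`` is a networkx graph or a square (sparse or dense)
    adjacency matrix; the graph must be connected.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    adj = _as_sparse_adjacency(adjacency)
    n = adj.shape[0]
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError("adjacency graph is disconnected")
    rng = np.random.default_rng(seed)
    if smoothing_fwhm > 0:
        from scipy.sparse.csgraph import shortest_path

        d = shortest_path(adj, directed=False, unweighted=True)
        sigma = smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        kern = np.exp(-(d**2) / (2.0 * sigma**2))
        kern /= np.sqrt((kern**2).sum(axis=1, keepdims=True))  # unit variance
    else:
        kern = None
    z_crit = stats.norm.ppf(1.0 - alpha_node / 2.0)
    max_sizes = np.empty(n_mc, dtype=int)
    chunk = max(1, int(2_000_000 // max(n, 1)))
    done = 0
    while done < n_mc:
        b = min(chunk, n_mc - done)
        z = rng.standard_normal((b, n))
        if kern is not None:
            z = z @ kern.T
        supra = np.abs(z) > z_crit
        for i in range(b):
            max_sizes[done + i] = _max_cluster(adj, supra[i])
        done += b
    max_sizes.sort()
    for ke in range(1, n + 2):
        exceed = n_mc - np.searchsorted(max_sizes, ke, side="left")
        if exceed / n_mc <= fwer:
            return ke
    raise AssertionError("unreachable")


def _as_sparse_adjacency(adjacency) -> sparse.csr_matrix:
    if hasattr(adjacency, "nodes"):  # networkx graph
        import networkx as nx

        return nx.to_scipy_sparse_array(adjacency, format="csr")
    a = sparse.csr_matrix(adjacency)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a


def _max_cluster(adj: sparse.csr_matrix, supra: np.ndarray) -> int:
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return 0
    sub = adj[idx][:, idx]
    ncomp, labels = connected_components(sub, directed=False)
    return int(np.bincount(labels, minlength=ncomp).max())


# ---------------------------------------------------------------------------
# on-disk results

def write_result(result: TfTestResult, out_dir, stem: str | None = None) -> Path:
    """Write the per-timeframe TSV plus a JSON summary; returns the TSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{result.metric}_{result.effect}"
    t = (
        result.times_ms
        if result.times_ms is not None
        else np.arange(result.stat.size, dtype=float)
    )
    pd.DataFrame(
        {
            "timeframe": np.arange(result.stat.size),
            "time_ms": t[: result.stat.size],
            "stat": result.stat,
            "p": result.p,
            "significant": result.significant.astype(int),
        }
    ).to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False, float_format="%.10g")
    step = float(t[1] - t[0]) if len(t) > 1 else 1.0
    summary = {
        "metric": result.metric,
        "effect": result.effect,
        "n_perm": result.n_perm,
        "alpha": result.alpha,
        "duration_threshold_tf": result.duration_threshold_tf,
        "pois_tf": [list(p) for p in result.pois],
        "pois_ms": [
            [float(t[a]), float(t[b] + step)] for a, b in result.pois
        ],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(summary, indent=1))
    return out_dir / f"{stem}.tsv"
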