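"""Topographic temporal segmentation of grand-average ERPs.

ERP map topographies do not vary randomly over time: they stay quasi-stable
for tens of milliseconds (functional microstates corresponding to ERP
components such as the N2 and P3) before switching to another stable
configuration. This module segments one or more condition grand-averages
into K template topographies with an atomize-and-agglomerate hierarchical
clustering (AAHC), selects the number of templates by combining a
cross-validation criterion with the Krzanowski-Lai criterion, and locates
component onsets (first sufficiently long assignment run of the component's
template) for latency locking across groups.

Clustering is polarity-sensitive by default: unlike spontaneous-EEG
microstate analysis, ERP segmentation treats a map and its inverse as
different states, because component polarity is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
import json
import logging
from pathlib import Path

import numpy as np

from .field_core import average_reference
from .preprocess import Erp

__all__ = [
    "Segmentation",
    "aahc_segment",
    "select_k",
    "component_onset",
    "ComponentNotFound",
    "FRONTO_CENTRAL",
    "CENTRO_PARIETAL",
]

logger = logging.getLogger(__name__)

# default electrode neighborhoods for component identification (10-10 names)
FRONTO_CENTRAL = ("FCz", "Fz", "Cz", "FC1", "FC2")
CENTRO_PARIETAL = ("CPz", "Pz", "CP1", "CP2")

_COMPONENT_SIGN = {"N2": -1.0, "P3": +1.0}
_COMPONENT_SITES = {"N2": FRONTO_CENTRAL, "P3": CENTRO_PARIETAL}


class ComponentNotFound(RuntimeError):
    pass


@dataclass
class Segmentation:
    """AAHC solutions over a range of K, on a set of condition averages.

    ``labels[k]`` maps each concatenated timeframe to a template index in
    [0, K); ``slices`` recovers each condition's stretch. Criterion curves
    are filled by :func:`select_k`.
    """

    conditions: list[str]
    slices: dict[str, slice]
    maps: np.ndarray                     # (T_total, C) average-referenced
    gfp_t: np.ndarray                    # (T_total,)
    times_ms: dict[str, np.ndarray]
    ch_names: list[str] | None
    k_values: list[int]
    templates: dict[int, np.ndarray]     # K -> (K, C) unit-GFP templates
    labels: dict[int, np.ndarray]        # K -> (T_total,) template indices
    gev: dict[int, float]
    polarity_sensitive: bool
    cv_curve: dict[int, float] = dc_field(default_factory=dict)
    kl_curve: dict[int, float] = dc_field(default_factory=dict)
    k_selected: int | None = None

    def labels_for(self, condition: str, k: int | None = None) -> np.ndarray:
        k = self.k_selected if k is None else k
        return self.labels[k][self.slices[condition]]


def _spatial_corr(maps: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Signed spatial Pearson correlation of avg-referenced rows of ``maps``
    with an avg-referenced ``template`` (zero-GFP rows give 0)."""
    num = maps @ template
    den = np.linalg.norm(maps, axis=-1) * np.linalg.norm(template)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def _unit_gfp(m: np.ndarray) -> np.ndarray:
    g = m.std()
    return m / g if g > 0 else m


def aahc_segment(
    erps: list[Erp] | dict[str, np.ndarray],
    k_range: range | list[int],
    polarity_sensitive: bool = True,
    ch_names: list[str] | None = None,
    times_ms: dict[str, np.ndarray] | None = None,
) -> Segmentation:
    """Atomize-and-agglomerate hierarchical clustering of ERP topographies.

    Every timeframe of every condition grand-average starts as its own
    cluster. At each step the cluster contributing least to the global
    explained variance (GEV) is dissolved ("atomized") and its member maps
    reassigned to whichever remaining cluster correlates best spatially
    (signed correlation if ``polarity_sensitive``). The solution at each K in
    ``k_range`` is recorded; templates are the unit-GFP cluster mean maps.

    GEV(K) = sum_t (gfp_t * r(u_t, template_label(t)))^2 / sum_t gfp_t^2 —
    non-decreasing in K because the solutions are nested refinements.
    """
    if isinstance(erps, dict):
        arrays = dict(erps)
        if times_ms is not None:
            times = {c: np.asarray(times_ms[c], dtype=float) for c in arrays}
        else:
            times = {c: np.arange(a.shape[1], dtype=float) for c, a in arrays.items()}
    else:
        arrays = {e.condition: e.data for e in erps}
        times = {e.condition: e.times_ms() for e in erps}
        if ch_names is None and len({e.data.shape[0] for e in erps}) != 1:
            raise ValueError("conditions must share the channel count")
    conditions = list(arrays)
    slices, start, maps_list, times_kept = {}, 0, [], {}
    for c in conditions:
        m = average_reference(np.asarray(arrays[c], dtype=float).T, axis=1)
        g = m.std(axis=1)
        keep = g > 0
        if not keep.all():
            logger.warning("condition %s: excluding %d zero-GFP timeframes",
                           c, int((~keep).sum()))
        m = m[keep]
        slices[c] = slice(start, start + m.shape[0])
        start += m.shape[0]
        maps_list.append(m)
        times_kept[c] = times[c][keep]
    maps = np.concatenate(maps_list, axis=0)
    t_total, n_ch = maps.shape
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values or k_values[0] < 1 or k_values[-1] > t_total:
        raise ValueError(f"k_range must lie within [1, {t_total}]")
    if t_total < 2:
        raise ValueError("need at least 2 timeframes to segment")

    gfp_t = maps.std(axis=1)
    denom = float((gfp_t**2).sum())
    label = np.arange(t_total)
    active = list(range(t_total))
    centroids = {t: maps[t].copy() for t in range(t_total)}
    members: dict[int, list[int]] = {t: [t] for t in range(t_total)}
    map_norm = np.linalg.norm(maps, axis=1)

    def member_corr(cid: int) -> np.ndarray:
        rows = np.array(members[cid])
        r = _spatial_corr(maps[rows], centroids[cid])
        return r if polarity_sensitive else np.abs(r)

    def contribution(cid: int) -> float:
        rows = np.array(members[cid])
        r = member_corr(cid)
        return float(((gfp_t[rows] * r) ** 2).sum()) / denom

    def recompute_centroid(cid: int) -> None:
        rows = np.array(members[cid])
        m = maps[rows]
        if not polarity_sensitive and len(rows) > 1:
            # sign-align members to the current centroid before averaging
            s = np.sign(_spatial_corr(m, centroids[cid]))
            m = m * np.where(s == 0, 1.0, s)[:, None]
        centroids[cid] = m.mean(axis=0)

    contrib = {cid: contribution(cid) for cid in active}

    templates_out: dict[int, np.ndarray] = {}
    labels_out: dict[int, np.ndarray] = {}
    gev_out: dict[int, float] = {}

    def record(k: int) -> None:
        order = sorted(active)
        remap = {cid: i for i, cid in enumerate(order)}
        lab = np.array([remap[label[t]] for t in range(t_total)])
        tmpl = np.stack([_unit_gfp(centroids[cid]) for cid in order])
        labels_out[k] = lab
        templates_out[k] = tmpl
        gev_out[k] = float(sum(contrib[cid] for cid in order))

    while True:
        k_now = len(active)
        if k_now in k_values:
            record(k_now)
        if k_now <= k_values[0]:
            break
        worst = min(active, key=lambda cid: contrib[cid])
        active.remove(worst)
        orphan_rows = members.pop(worst)
        centroids.pop(worst)
        contrib.pop(worst)
        # vectorized reassignment: correlate every orphan with every centroid
        cen = np.stack([centroids[cid] for cid in active])
        cen_norm = np.linalg.norm(cen, axis=1)
        num = maps[orphan_rows] @ cen.T
        den = np.outer(map_norm[orphan_rows], cen_norm)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if not polarity_sensitive:
            r = np.abs(r)
        choice = np.argmax(r, axis=1)
        touched = set()
        for t, j in zip(orphan_rows, choice):
            new = active[int(j)]
            label[t] = new
            members[new].append(t)
            touched.add(new)
        for cid in touched:
            recompute_centroid(cid)
            contrib[cid] = contribution(cid)

    return Segmentation(
        conditions=conditions,
        slices=slices,
        maps=maps,
        gfp_t=gfp_t,
        times_ms=times_kept,
        ch_names=list(ch_names) if ch_names is not None else None,
        k_values=k_values,
        templates=templates_out,
        labels=labels_out,
        gev=gev_out,
        polarity_sensitive=polarity_sensitive,
    )


def select_k(seg: Segmentation, cv_tolerance: float = 0.05) -> int:
    """Choose K by combining cross-validation and Krzanowski-Lai criteria.

    CV(K) = residual variance x ((C-1)/(C-1-K))^2, minimized; the residual
    variance is the mean squared part of each map orthogonal to its assigned
    template. KL(K) = |DIFF(K) / DIFF(K+1)| with
    DIFF(K) = (K-1)^(2/C) W(K-1) - K^(2/C) W(K), maximized, where W(K) is the
    within-cluster dispersion (sum of squared distances of unit-GFP maps to
    their cluster mean). The selected K maximizes KL among the K whose CV is
    within ``cv_tolerance`` (relative) of the CV optimum; ties break toward
    the smaller K. Fills ``seg.cv_curve``, ``seg.kl_curve``,
    ``seg.k_selected``.
    """
    ks = seg.k_values
    if len(ks) < 3:
        raise ValueError("need at least 3 evaluated K values")
    n_ch = seg.maps.shape[1]
    unit_maps = seg.maps / np.where(seg.gfp_t > 0, seg.gfp_t, 1.0)[:, None]

    cv, w = {}, {}
    for k in ks:
        lab = seg.labels[k]
        tmpl = seg.templates[k]
        # residual variance: squared norm minus squared projection onto the
        # (unit-vector-normalized) assigned template
        a = tmpl / np.linalg.norm(tmpl, axis=1, keepdims=True)
        proj = np.einsum("tc,tc->t", seg.maps, a[lab])
        resid = np.maximum((seg.maps**2).sum(axis=1) - proj**2, 0.0)
        sigma2 = float(resid.sum()) / (seg.maps.shape[0] * (n_ch - 1))
        denom_k = n_ch - 1 - k
        cv[k] = sigma2 * ((n_ch - 1) / denom_k) ** 2 if denom_k > 0 else np.inf
        # within-cluster dispersion on unit-GFP maps
        tot = 0.0
        for j in range(k):
            rows = unit_maps[lab == j]
            if seg.polarity_sensitive or len(rows) < 2:
                cen = rows.mean(axis=0)
            else:
                s = np.sign(_spatial_corr(rows, rows[0]))
                rows = rows * np.where(s == 0, 1.0, s)[:, None]
                cen = rows.mean(axis=0)
            tot += float(((rows - cen) ** 2).sum())
        w[k] = tot

    expo = 2.0 / n_ch

    def diff(k: int) -> float | None:
        if (k - 1) not in w or k not in w:
            return None
        return (k - 1) ** expo * w[k - 1] - k**expo * w[k]

    kl = {}
    for k in ks:
        d1, d2 = diff(k), diff(k + 1)
        if d1 is None or d2 is None:
            kl[k] = np.nan
        elif d2 == 0.0:
            kl[k] = np.inf if d1 != 0.0 else np.nan
        else:
            kl[k] = abs(d1 / d2)

    seg.cv_curve, seg.kl_curve = cv, kl
    cv_min = min(cv.values())
    slack = 1e-12 * max(1.0, max(v for v in cv.values() if np.isfinite(v)))
    band = [k for k in ks if cv[k] <= cv_min * (1.0 + cv_tolerance) + slack]
    scored = [(k, kl[k]) for k in band if np.isfinite(kl[k]) or np.isinf(kl[k])]
    scored = [(k, v) for k, v in scored if not np.isnan(v)]
    if scored:
        best = max(v for _, v in scored)
        seg.k_selected = min(k for k, v in scored if v == best)
    else:  # no interior KL value available: fall back to the CV optimum
        seg.k_selected = min(band)
    return seg.k_selected


def component_onset(
    seg: Segmentation,
    component: str,
    search_window_ms: tuple[float, float],
    condition: str | None = None,
    min_dur_ms: float = 20.0,
    electrodes: tuple[str, ...] | None = None,
    k: int | None = None,
) -> dict[str, int]:
    """Onset timeframe of an ERP component in each condition's label track.

    The component's template is the one whose assigned timeframes inside the
    search window have the most negative (N2, fronto-central sites) or most
    positive (P3, centro-parietal sites) mean potential. The onset is the
    first timeframe (index within the condition) of its first assignment run
    lasting at least ``min_dur_ms``. Raises :class:`ComponentNotFound` if no
    such run exists.
    """
    if component not in _COMPONENT_SIGN:
        raise ValueError(f"unknown component {component!r}; expected N2 or P3")
    k = seg.k_selected if k is None else k
    if k is None:
        raise ValueError("run select_k first or pass k explicitly")
    sites = _COMPONENT_SITES[component] if electrodes is None else tuple(electrodes)
    if seg.ch_names is not None:
        idx = [seg.ch_names.index(s) for s in sites if s in seg.ch_names]
        if not idx:
            raise ValueError(f"none of {sites} found in channel names")
    else:
        idx = None  # unlabeled montage: use the whole map
    sign = _COMPONENT_SIGN[component]
    conds = [condition] if condition is not None else seg.conditions
    out: dict[str, int] = {}
    for c in conds:
        lab = seg.labels_for(c, k)
        t_ms = seg.times_ms[c]
        dt = float(np.median(np.diff(t_ms))) if len(t_ms) > 1 else 1.0
        min_run = max(1, int(np.ceil(min_dur_ms / dt)))
        in_win = (t_ms >= search_window_ms[0]) & (t_ms <= search_window_ms[1])
        cond_maps = seg.maps[seg.slices[c]]
        score = np.full(k, np.nan)
        for j in range(k):
            sel = in_win & (lab == j)
            if not sel.any():
                continue
            vals = cond_maps[sel][:, idx] if idx is not None else cond_maps[sel]
            score[j] = sign * float(vals.mean())
        if np.all(np.isnan(score)):
            raise ComponentNotFound(
                f"{component}: no template assigned inside the search window "
                f"for condition {c!r}"
            )
        target = int(np.nanargmax(score))
        # first run of >= min_run consecutive assignments within the window
        onset = None
        run_start, run_len = None, 0
        for t in range(len(lab)):
            if in_win[t] and lab[t] == target:
                if run_len == 0:
                    run_start = t
                run_len += 1
                if run_len >= min_run:
                    onset = run_start
                    break
            else:
                run_len = 0
        if onset is None:
            raise ComponentNotFound(
                f"{component}: no assignment run of >= {min_dur_ms} ms in the "
                f"search window for condition {c!r}"
            )
        out[c] = int(onset)
    return out


def write_segmentation(seg: Segmentation, out_dir) -> Path:
    """JSON dump of templates/criteria plus one TSV label track per condition."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "conditions": seg.conditions,
        "k_values": seg.k_values,
        "k_selected": seg.k_selected,
        "gev": {str(k): v for k, v in seg.gev.items()},
        "cv_curve": {str(k): v for k, v in seg.cv_curve.items()},
        "kl_curve": {
            str(k): (None if np.isnan(v) else v) for k, v in seg.kl_curve.items()
        },
        "templates": {
            str(k): t.tolist() for k, t in seg.templates.items()
            if seg.k_selected in (None, k)
        },
    }
    (out_dir / "segmentation.json").write_text(json.dumps(payload, indent=1))
    for c in seg.conditions:
        k = seg.k_selected or seg.k_values[-1]
        lab = seg.labels_for(c, k)
        lines = ["timeframe\ttime_ms\tlabel"]
        for i, (t, l) in enumerate(zip(seg.times_ms[c], lab)):
            lines.append(f"{i}\t{t:.6f}\t{int(l)}")
        (out_dir / f"labels_{c.replace('/', '_')}.tsv").write_text(
            "\n".join(lines) + "\n"
        )
    return out_dir / "segmentation.json"
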