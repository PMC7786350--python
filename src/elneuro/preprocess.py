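"""ERP preprocessing: band-pass filtering, epoching with whole-epoch
baseline, amplitude/jump artifact rejection, averaging with common average
reference, and component-onset alignment of averaged ERPs.

The chain mirrors a standard event-related potential pipeline: 0.5-40 Hz
zero-phase band-pass, epochs from 100 ms before to 700 ms after stimulus
onset, baseline correction by subtracting each epoch's own per-channel mean,
rejection of epochs with >30 uV sample-to-sample jumps or >80 uV absolute
voltage on any electrode, per-subject averaging, and re-referencing of the
average to the common average reference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .field_core import average_reference

__all__ = [
    "EpochSet",
    "Erp",
    "RejectionReport",
    "bandpass_filter",
    "make_epochs",
    "reject_epochs",
    "average_erp",
    "align_to_component",
    "read_erp",
    "write_erp",
]

logger = logging.getLogger(__name__)


def _n_timeframes(window_ms: tuple[float, float], srate: float) -> int:
    """Timeframe count for a half-open window [start, end) at srate."""
    start, end = window_ms
    return int(np.floor((end - start) / 1000.0 * srate))


@dataclass
class EpochSet:
    """Single-trial epochs: trials x channels x timeframes, in microvolts.

    ``window_ms`` is relative to stimulus onset and half-open, [start, end);
    the timeframe count is floor((end-start)/1000*srate) so shapes are
    reproducible from the metadata alone.
    """

    data: np.ndarray
    srate: float
    window_ms: tuple[float, float]
    condition: str
    participant: str
    group: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x timeframes")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        start, end = self.window_ms
        if not (start < 0 <= end):
            raise ValueError("window must start before 0 and end at/after 0")
        expect = _n_timeframes(self.window_ms, self.srate)
        if self.data.shape[0] > 0 and self.data.shape[2] != expect:
            raise ValueError(
                f"window/srate imply {expect} timeframes, data has {self.data.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def times_ms(self) -> np.ndarray:
        n = _n_timeframes(self.window_ms, self.srate)
        return self.window_ms[0] + np.arange(n) * 1000.0 / self.srate


@dataclass
class Erp:
    """Averaged ERP: channels x timeframes, with provenance metadata."""

    data: np.ndarray
    srate: float
    window_ms: tuple[float, float]
    condition: str
    participant: str
    group: str
    avg_referenced: bool = False
    n_epochs_used: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ERP data must be channels x timeframes")
        if self.n_epochs_used < 1:
            raise ValueError("n_epochs_used must be >= 1")
        if self.avg_referenced:
            scale = max(np.abs(self.data).max(), 1.0)
            if np.abs(self.data.mean(axis=0)).max() > 1e-9 * scale:
                raise ValueError("avg_referenced flag set but channel mean is not 0")

    def times_ms(self) -> np.ndarray:
        return self.window_ms[0] + np.arange(self.data.shape[1]) * 1000.0 / self.srate


def bandpass_filter(
    data: np.ndarray,
    srate: float,
    lo_hz: float = 0.5,
    hi_hz: float = 40.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    ``order`` is the one-pass filter order; forward-backward application
    doubles the effective roll-off and cancels the group delay, so filtered
    components keep their latency.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if not (0 < lo_hz < hi_hz < srate / 2):
        raise ValueError("need 0 < lo_hz < hi_hz < srate/2")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=srate, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than filter warm-up ({padlen + 1})"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def make_epochs(
    continuous: np.ndarray,
    events: np.ndarray,
    srate: float,
    window_ms: tuple[float, float] = (-100.0, 700.0),
    condition: str = "",
    participant: str = "",
    group: str = "",
) -> EpochSet:
    """Cut stimulus-locked epochs and baseline-correct on the whole epoch.

    ``events`` are onset sample indices into ``continuous``. Each epoch's
    per-channel mean over the full window is subtracted (whole-epoch
    baseline), so every epoch has per-channel mean 0. Events whose window
    falls outside the recording are skipped and logged, not fatal.
    """
    x = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_tf = _n_timeframes(window_ms, srate)
    offset = int(np.round(window_ms[0] / 1000.0 * srate))
    epochs, skipped = [], []
    for ev in np.asarray(events, dtype=int):
        lo = ev + offset
        hi = lo + n_tf
        if lo < 0 or hi > x.shape[1]:
            skipped.append(int(ev))
            continue
        seg = x[:, lo:hi]
        epochs.append(seg - seg.mean(axis=1, keepdims=True))
    if skipped:
        logger.info("make_epochs: skipped %d events at recording edge: %s",
                    len(skipped), skipped)
    data = np.stack(epochs) if epochs else np.empty((0, x.shape[0], n_tf))
    return EpochSet(data, srate, window_ms, condition, participant, group)


@dataclass
class RejectionReport:
    n_input: int
    n_rejected_jump: int
    n_rejected_amplitude: int
    n_kept: int


def reject_epochs(
    epochs: EpochSet, jump_uv: float = 30.0, abs_uv: float = 80.0
) -> tuple[EpochSet, RejectionReport]:
    """Drop epochs with large sample-to-sample jumps or absolute voltages.

    An epoch is rejected if any electrode shows |v(t+1) - v(t)| > jump_uv, or
    |v| > abs_uv at any timeframe. Pure set semantics: order-independent and
    idempotent. An epoch failing both criteria counts toward both tallies.
    """
    if jump_uv <= 0 or abs_uv <= 0:
        raise ValueError("thresholds must be positive")
    d = epochs.data
    if d.shape[0] == 0:
        return epochs, RejectionReport(0, 0, 0, 0)
    jump_bad = np.abs(np.diff(d, axis=2)).max(axis=(1, 2)) > jump_uv
    amp_bad = np.abs(d).max(axis=(1, 2)) > abs_uv
    keep = ~(jump_bad | amp_bad)
    kept = replace(epochs, data=d[keep])
    report = RejectionReport(
        n_input=d.shape[0],
        n_rejected_jump=int(jump_bad.sum()),
        n_rejected_amplitude=int(amp_bad.sum()),
        n_kept=int(keep.sum()),
    )
    return kept, report


def average_erp(epochs: EpochSet) -> Erp:
    """Average surviving epochs and apply the common average reference."""
    if epochs.n_epochs < 1:
        raise ValueError(
            f"no epochs to average for participant={epochs.participant!r} "
            f"condition={epochs.condition!r}"
        )
    mean = epochs.data.mean(axis=0)
    return Erp(
        data=average_reference(mean, axis=0),
        srate=epochs.srate,
        window_ms=epochs.window_ms,
        condition=epochs.condition,
        participant=epochs.participant,
        group=epochs.group,
        avg_referenced=True,
        n_epochs_used=epochs.n_epochs,
    )


def align_to_component(
    erps: list[Erp],
    onsets_tf: dict[tuple[str, str], int],
) -> tuple[list[Erp], dict]:
    """Shift each ERP so its (group, condition) component onset lands on a
    common reference timeframe, truncating to the shared overlap window.

    ``onsets_tf`` maps (group, condition) to the onset timeframe index of the
    component (e.g. the N2) in that cell's grand average. The latest onset is
    used as the common lock point; ERPs with earlier onsets are shifted right
    and all outputs are cut to the intersection window, so no samples are
    fabricated at the edges. Returns the aligned ERPs plus a log of shifts
    (in timeframes and ms) and the retained window.
    """
    if not erps:
        return [], {"shifts_tf": {}, "kept_window_ms": None}
    srate = erps[0].srate
    n_tf = erps[0].data.shape[1]
    for e in erps:
        if e.srate != srate or e.data.shape != erps[0].data.shape:
            raise ValueError("all ERPs must share srate and shape")
        if (e.group, e.condition) not in onsets_tf:
            raise KeyError(f"onset missing for cell {(e.group, e.condition)}")
    for cell, tf in onsets_tf.items():
        if not (0 <= tf < n_tf):
            raise ValueError(f"onset {tf} outside epoch for cell {cell}")
    lock = max(onsets_tf[(e.group, e.condition)] for e in erps)
    shifts = {
        cell: lock - tf for cell, tf in onsets_tf.items()
    }  # >= 0: shift right by delaying the read start
    max_shift = max(shifts[(e.group, e.condition)] for e in erps)
    if max_shift >= n_tf:
        raise ValueError("alignment shift exceeds epoch length")
    kept = n_tf - max_shift
    t0 = erps[0].times_ms()
    new_window = (float(t0[max_shift]), float(t0[max_shift] + kept * 1000.0 / srate))
    aligned = []
    for e in erps:
        s = shifts[(e.group, e.condition)]
        # take the slice whose onset index becomes (lock - max_shift)
        start = max_shift - s
        aligned.append(
            replace(e, data=e.data[:, start : start + kept], window_ms=new_window)
        )
    log = {
        "lock_tf": int(lock),
        "shifts_tf": {f"{g}/{c}": int(s) for (g, c), s in shifts.items()},
        "shifts_ms": {
            f"{g}/{c}": float(s * 1000.0 / srate) for (g, c), s in shifts.items()
        },
        "kept_window_ms": (float(t0[max_shift]), float(t0[n_tf - 1])),
        "kept_timeframes": int(kept),
    }
    return aligned, log


# ---------------------------------------------------------------------------
# On-disk layout: one TSV (rows=channels, columns=timeframes, header=time in
# ms) plus a JSON manifest per participant x condition.

def write_erp(erp: Erp, tsv_path, labels: list[str] | None = None) -> None:
    tsv_path = Path(tsv_path)
    times = [f"{t:.6f}" for t in erp.times_ms()]
    index = labels if labels is not None else [f"ch{i}" for i in range(erp.data.shape[0])]
    pd.DataFrame(erp.data, index=index, columns=times).to_csv(
        tsv_path, sep="\t", index_label="channel", float_format="%.10g"
    )
    manifest = {
        "srate": erp.srate,
        "window_ms": list(erp.window_ms),
        "condition": erp.condition,
        "participant": erp.participant,
        "group": erp.group,
        "avg_referenced": erp.avg_referenced,
        "n_epochs_used": erp.n_epochs_used,
        "n_channels": int(erp.data.shape[0]),
        "n_timeframes": int(erp.data.shape[1]),
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_erp(tsv_path) -> Erp:
    tsv_path = Path(tsv_path)
    manifest = json.loads(tsv_path.with_suffix(".json").read_text())
    df = pd.read_csv(tsv_path, sep="\t", index_col="channel")
    data = df.to_numpy(dtype=float)
    if data.shape != (manifest["n_channels"], manifest["n_timeframes"]):
        raise ValueError(
            f"{tsv_path}: matrix shape {data.shape} does not match manifest "
            f"({manifest['n_channels']}, {manifest['n_timeframes']})"
        )
    return Erp(
        data=data,
        srate=manifest["srate"],
        window_ms=tuple(manifest["window_ms"]),
        condition=manifest["condition"],
        participant=manifest["participant"],
        group=manifest["group"],
        avg_referenced=manifest["avg_referenced"],
        n_epochs_used=manifest["n_epochs_used"],
    )
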