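"""Scalp-field primitives: montages, global field power, map dissimilarity,
average referencing and bad-channel interpolation.

The two scalar descriptors defined here carry the whole sensor-level
statistical strategy of the package:

* **GFP** (global field power) is the spatial standard deviation of the
  potential map at one instant — a reference-free index of overall response
  strength.
* **GMD** (global map dissimilarity) is the RMS difference between two
  average-referenced, GFP-normalized maps — an index of field *configuration*
  that is orthogonal to strength by construction.

Both use the population (1/C) normalization so that GMD is exactly bounded in
[0, 2] and satisfies ``gmd**2 == 2 * (1 - r_spatial)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial.distance import pdist

__all__ = [
    "Montage",
    "read_montage",
    "write_montage",
    "gfp",
    "gmd",
    "average_reference",
    "interpolate_channels",
]


@dataclass(frozen=True)
class Montage:
    """Electrode labels with 3-D positions on/near the unit sphere.

    Positions are unitless; only relative geometry matters (inter-electrode
    distances drive interpolation and simulated spatial noise correlation).
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (C, 3)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)
        if len(labels) < 2:
            raise ValueError("montage needs at least 2 channels")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate channel labels")
        if pos.shape != (len(labels), 3):
            raise ValueError(f"positions must be ({len(labels)}, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite electrode positions")
        if pdist(pos).min() <= 0:
            raise ValueError("two channels share identical coordinates")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def median_distance(self) -> float:
        """Median pairwise inter-electrode distance (default RBF shape)."""
        return float(np.median(pdist(self.positions)))


def read_montage(path) -> Montage:
    """Read an sfp-style whitespace-delimited ``label x y z`` file."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"malformed montage row: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return Montage(tuple(labels), np.array(rows))


def write_montage(montage: Montage, path) -> None:
    """Write sfp-style rows with full float precision (round-trip exact)."""
    with open(path, "w") as fh:
        for lab, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{lab} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def gfp(values: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Global field power: population spatial SD across channels.

    ``sqrt(mean((u - mean(u))**2))`` along ``axis`` (the channel axis).
    Invariant to adding a constant to all channels; scales linearly with the
    map. Works on a single map or any array with a channel axis.
    """
    u = np.asarray(values, dtype=float)
    if u.shape == () or u.shape[axis] == 0:
        raise ValueError("empty map")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite map values")
    out = u.std(axis=axis)  # numpy std is the population SD
    return float(out) if out.ndim == 0 else out


def average_reference(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Subtract the instantaneous mean across channels (common average ref).

    Idempotent; preserves GFP.
    """
    u = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite map values")
    return u - u.mean(axis=axis, keepdims=True)


def gmd(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Global map dissimilarity between two maps on the same montage.

    Each map is average-referenced and scaled to unit GFP ("instantaneous"
    normalization), then the population RMS of their difference is returned.
    Bounded in [0, 2]: 0 for proportional maps, 2 for antiphase maps, and
    sqrt(2) for spatially uncorrelated maps.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D with equal length")
    ga, gb = gfp(a), gfp(b)
    if ga == 0.0 or gb == 0.0:
        raise ValueError("zero-GFP map: dissimilarity undefined")
    ah = average_reference(a) / ga
    bh = average_reference(b) / gb
    return float(np.sqrt(np.mean((ah - bh) ** 2)))


def multiquadric_interpolator(
    positions: np.ndarray, values: np.ndarray, shape_param: float
) -> RBFInterpolator:
    """Multiquadric RBF interpolant phi(r) = sqrt(r**2 + c**2) on 3-D points.

    scipy parametrizes the kernel as sqrt(1 + (eps*r)**2); this differs from
    the classical form only by a constant factor, which the solved weights
    absorb, so the interpolant is identical.
    """
    if shape_param <= 0:
        raise ValueError("shape_param must be > 0")
    return RBFInterpolator(
        positions, values, kernel="multiquadric", epsilon=1.0 / shape_param
    )


def interpolate_channels(
    data: np.ndarray,
    bad_labels: list[str],
    montage: Montage,
    shape_param: float | None = None,
) -> np.ndarray:
    """Replace bad channels of a channels x timeframes array by multiquadric
    RBF interpolation over the good channels' 3-D positions, per timeframe.

    Good channels are returned unchanged. ``shape_param`` defaults to the
    montage's median inter-electrode distance. Distances are 3-D Euclidean
    (chord), not geodesic.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] != montage.n_channels:
        raise ValueError(
            f"data has {x.shape[0]} channels, montage has {montage.n_channels}"
        )
    bad_idx = sorted({montage.index(lab) for lab in bad_labels})
    if not bad_idx:
        return x.copy()
    good_idx = [i for i in range(montage.n_channels) if i not in set(bad_idx)]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels to interpolate")
    c = montage.median_distance() if shape_param is None else float(shape_param)
    # one linear solve for all timeframes: RBFInterpolator accepts (n, T) values
    interp = multiquadric_interpolator(montage.positions[good_idx], x[good_idx], c)
    out = x.copy()
    out[bad_idx] = interp(montage.positions[bad_idx])
    return out
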