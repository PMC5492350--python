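"""Inter-atomic distance time series and their summaries.

The headline application is the heme-iron-to-ligand-C30 distance: the
distance between the heme Fe and the C30 methyl carbon of lanosterol is a
proxy for catalytically competent substrate positioning, so its level and
stability over a trajectory discriminate well-seated from displaced ligands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import AtomSelection, SelectionError, Trajectory

__all__ = ["DistanceSeries", "SeriesSummary", "distance_series", "series_summary", "running_average"]


@dataclass(frozen=True)
class DistanceSeries:
    structure_label: str
    times_ps: np.ndarray
    distances_angstrom: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ps, dtype=float)
        d = np.asarray(self.distances_angstrom, dtype=float)
        if t.shape != d.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "times_ps", t)
        object.__setattr__(self, "distances_angstrom", d)

    def __len__(self) -> int:
        return len(self.distances_angstrom)


@dataclass(frozen=True)
class SeriesSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int


def _single_index(sel: AtomSelection) -> int:
    if len(sel) != 1:
        raise SelectionError(
            f"selection {sel.spec!r} must resolve exactly one atom, got {len(sel)}"
        )
    return sel.indices[0]


def distance_series(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    structure_label: str = "",
) -> DistanceSeries:
    """Per-frame Euclidean distance between two single-atom selections.

    Computed over the full trajectory; windowing is applied downstream by
    :func:`series_summary`.
    """
    ia, ib = _single_index(sel_a), _single_index(sel_b)
    coords = np.stack([f.coords for f in traj.frames])  # (n_frames, n_atoms, 3)
    diff = coords[:, ia, :] - coords[:, ib, :]
    dists = np.sqrt(np.sum(diff * diff, axis=1))
    times = np.array([f.time_ps for f in traj.frames], dtype=float)
    return DistanceSeries(structure_label=structure_label, times_ps=times,
                          distances_angstrom=dists)


def series_summary(series: DistanceSeries, window: tuple[int, int] | None = None) -> SeriesSummary:
    """Sample statistics (mean, n-1 sd, min, max) of a windowed series."""
    d = series.distances_angstrom
    if window is not None:
        start, end = window
        d = d[start:end]
    if d.size == 0:
        raise ValueError("summary window is empty")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return SeriesSummary(
        mean=float(np.mean(d)), sd=sd, min=float(np.min(d)), max=float(np.max(d)),
        n=int(d.size),
    )


def running_average(values: np.ndarray, window: int = 100) -> np.ndarray:
    """Centered-start running mean for smoothed trace plots.

    Uses a trailing window of up to ``window`` points, so the output has the
    same length as the input and starts at the raw first value.
    """
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    csum = np.cumsum(np.insert(values, 0, 0.0))
    out = np.empty_like(values)
    for i in range(len(values)):
        lo = max(0, i - window + 1)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return out
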