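"""Trajectory descriptor time series and activation-state calls.

An MD trajectory of the receptor is reduced to one scalar per frame: the
Val84-Leu249 C-alpha distance. The first stretch of a run (default 50 ns) is
treated as annealing/relaxation and excluded; the production segment is
summarised by its median and compared across runs with Mann-Whitney and
Kolmogorov-Smirnov tests. A run is called agonist-like when its production
median sits closer to the active-state reference distance than to the
inactive one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import ks_2sample_p, mann_whitney_p
from .structio import ResiduePairDescriptor, StructureModel, pair_distance

DEFAULT_ANNEAL_NS = 50.0
DEFAULT_BIN_FRAMES = 20


@dataclass
class DistanceSeries:
    """Per-frame descriptor values from one trajectory.

    Frame i is stamped with time (i + 1) * frame_interval_ns, i.e. the end of
    the interval it covers; the frame falling exactly on the annealing
    boundary is still part of the annealing segment.
    """

    label: str
    frame_interval_ns: float
    distances: np.ndarray
    anneal_ns: float = DEFAULT_ANNEAL_NS

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.frame_interval_ns <= 0:
            raise ValueError("frame_interval_ns must be positive")
        if self.anneal_ns < 0:
            raise ValueError("anneal_ns must be non-negative")
        if self.distances.ndim != 1:
            raise ValueError("distances must be one-dimensional")
        if self.distances.size and not (
            np.all(np.isfinite(self.distances)) and np.all(self.distances > 0)
        ):
            raise ValueError("distances must be finite and positive")

    @property
    def n_frames(self) -> int:
        return int(self.distances.size)

    @property
    def total_ns(self) -> float:
        return self.n_frames * self.frame_interval_ns

    @property
    def times_ns(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 1) * self.frame_interval_ns


@dataclass
class DescriptorComparison:
    label_a: str
    label_b: str
    median_a: float
    median_b: float
    mw_p: float
    ks_p: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.median_a - self.median_b))


def series_from_frames(
    frames: Sequence[StructureModel],
    pair: ResiduePairDescriptor = ResiduePairDescriptor(),
    frame_interval_ns: float = 0.1,
    label: str = "trajectory",
    anneal_ns: float = DEFAULT_ANNEAL_NS,
) -> DistanceSeries:
    """One descriptor value per frame, order preserved."""
    distances = []
    for i, frame in enumerate(frames):
        try:
            distances.append(pair_distance(frame, pair))
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    return DistanceSeries(label, frame_interval_ns, np.array(distances), anneal_ns)


def moving_average(series: DistanceSeries | np.ndarray, bin_frames: int = DEFAULT_BIN_FRAMES) -> np.ndarray:
    """Trailing moving average with partial leading windows.

    Output i (for i >= bin_frames - 1) is the mean of frames
    [i - bin_frames + 1, i]; earlier positions average the frames available
    so far, so output length equals input length.
    """
    values = series.distances if isinstance(series, DistanceSeries) else np.asarray(series, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("cannot smooth an empty series")
    if not (1 <= bin_frames <= n):
        raise ValueError(f"bin_frames must be in [1, {n}], got {bin_frames}")
    # per-window summation, not a running cumsum: the cumulative sum
    # accumulates rounding drift over long trajectories
    out = np.empty(n)
    head = min(bin_frames - 1, n)
    for i in range(head):
        out[i] = values[: i + 1].mean()
    if n >= bin_frames:
        windows = np.lib.stride_tricks.sliding_window_view(values, bin_frames)
        out[bin_frames - 1:] = windows.mean(axis=1)
    return out


def production_segment(series: DistanceSeries) -> np.ndarray:
    """Distances with frame time strictly after the annealing period."""
    if series.anneal_ns >= series.total_ns:
        raise ValueError(
            f"{series.label}: annealing period ({series.anneal_ns} ns) covers the whole "
            f"trajectory ({series.total_ns} ns)"
        )
    # relative tolerance so e.g. 50 ns / 0.1 ns counts as exactly 500 frames
    n_skip = int(np.floor(series.anneal_ns / series.frame_interval_ns * (1 + 1e-9) + 1e-9))
    return series.distances[n_skip:]


def compare_distributions(a: DistanceSeries, b: DistanceSeries) -> DescriptorComparison:
    """Mann-Whitney + KS comparison of the two production-segment distributions."""
    seg_a = production_segment(a)
    seg_b = production_segment(b)
    if seg_a.size == 0 or seg_b.size == 0:
        raise ValueError("both production segments must be non-empty")
    return DescriptorComparison(
        label_a=a.label,
        label_b=b.label,
        median_a=float(np.median(seg_a)),
        median_b=float(np.median(seg_b)),
        mw_p=mann_whitney_p(seg_a, seg_b),
        ks_p=ks_2sample_p(seg_a, seg_b),
    )


def classify_state(
    series: DistanceSeries,
    active_ref: float,
    inactive_ref: float,
    dead_band: float = 0.1,
) -> str:
    """Call a run agonist-like / antagonist-like / indeterminate.

    The production-segment median is compared with the midpoint of the two
    reference distances; medians within +/- dead_band of the midpoint are
    indeterminate.
    """
    if active_ref == inactive_ref:
        raise ValueError("active and inactive reference distances must differ")
    if active_ref < inactive_ref:
        raise ValueError("active_ref must exceed inactive_ref")
    median = float(np.median(production_segment(series)))
    midpoint = 0.5 * (active_ref + inactive_ref)
    if abs(median - midpoint) <= dead_band:
        return "indeterminate"
    return "agonist-like" if median > midpoint else "antagonist-like"


# ---------------------------------------------------------------------------
# CSV interchange (time_ns, distance_A)
# ---------------------------------------------------------------------------

def read_series_csv(path, label: str | None = None, anneal_ns: float = DEFAULT_ANNEAL_NS) -> DistanceSeries:
    """Load a pre-reduced trajectory from a two-column CSV (time_ns, distance_A)."""
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_ns", "distance_A"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_ns, distance_A")
    times = df["time_ns"].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError(f"{path}: need >= 2 frames to infer the frame interval")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: frame times are not evenly spaced")
    return DistanceSeries(
        label=label if label is not None else path.stem,
        frame_interval_ns=float(dt[0]),
        distances=df["distance_A"].to_numpy(dtype=float),
        anneal_ns=anneal_ns,
    )


def write_series_csv(series: DistanceSeries, path) -> None:
    pd.DataFrame({"time_ns": series.times_ns, "distance_A": series.distances}).to_csv(path, index=False)


def quantile_summary(series: DistanceSeries, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Violin-plot style summary of the production segment."""
    seg = production_segment(series)
    return pd.DataFrame(
        {
            "label": series.label,
            "quantile": list(quantiles),
            "distance_A": np.quantile(seg, quantiles),
        }
    )
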