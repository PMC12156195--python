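"""Dwell-time aggregation statistics on MD-derived observable time series.

Post-trajectory analysis for polymer-surfactant contact formation (here:
chitosan-saponin).  Two molecules are considered aggregated when their
minimum interatomic distance stays below a cutoff (default 0.25 nm) for at
least a minimum dwell time (default 5 ns); the aggregation probability is
the fraction of simulated time spent in such qualifying episodes.  The
mean hydrogen-bond energy is taken over aggregated frames only, and a
trajectory-average hydrophobic-interaction score at or above 5 flags
possible "hydrophobic bonding".

Conventions (the observable stream fixes them only loosely, so they are
pinned here): the distance test is strict (< cutoff), the dwell test
inclusive (>= min_dwell); a run truncated by either trajectory end
qualifies if its *observed* duration reaches the dwell minimum; dwell
labeling operates on the raw per-frame distances, block averaging being a
reporting convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySeries",
    "AggregationSummary",
    "block_average",
    "label_aggregated",
    "aggregation_probability",
    "mean_hbond_energy",
    "hydrophobic_bonding_flag",
    "summarize_trajectory",
    "summarize_replicates",
    "read_trajectory_tsv",
]


@dataclass
class TrajectorySeries:
    """Uniformly sampled per-frame observables from a production MD run."""

    dt: float                                 # sampling interval, ns
    min_distance: np.ndarray                  # nm
    hbond_count: Optional[np.ndarray] = None
    hbond_energy: Optional[np.ndarray] = None  # kJ/mol
    hydrophobic_score: Optional[np.ndarray] = None
    meta: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.min_distance = np.asarray(self.min_distance, dtype=float)
        if self.min_distance.size == 0:
            raise ValueError("empty trajectory")
        if np.any(self.min_distance <= 0):
            raise ValueError("distances must be > 0")
        n = self.min_distance.size
        for name in ("hbond_count", "hbond_energy", "hydrophobic_score"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise ValueError(f"{name} length differs from min_distance")
                setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return int(self.min_distance.size)

    @property
    def duration(self) -> float:
        """Total sampled duration in ns."""
        return self.n_frames * self.dt


@dataclass
class AggregationSummary:
    probability: float
    mean_hbond_energy: Optional[float]  # kJ/mol; None when never aggregated
    hydrophobic_bonding: Optional[bool]
    n_episodes: int


def block_average(series, dt: float, window_ns: float = 5.0) -> np.ndarray:
    """Non-overlapping block means over windows of ``window_ns``.

    The window must be a positive multiple of ``dt``; a trailing partial
    block is dropped, so the output has floor(n*dt/window) entries.
    """
    series = np.asarray(series, dtype=float)
    if window_ns < dt:
        raise ValueError("window must be >= dt")
    frames_per_block = window_ns / dt
    k = int(round(frames_per_block))
    if abs(frames_per_block - k) > 1e-9:
        raise ValueError("window must be an integer multiple of dt")
    n_blocks = series.size // k
    if n_blocks == 0:
        return np.empty(0)
    return series[: n_blocks * k].reshape(n_blocks, k).mean(axis=1)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is exclusive."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def label_aggregated(
    min_distance,
    dt: float,
    cutoff_nm: float = 0.25,
    min_dwell_ns: float = 5.0,
) -> np.ndarray:
    """Boolean per-frame aggregation state after dwell filtering.

    A frame is aggregated iff it belongs to a maximal run of frames with
    distance strictly below ``cutoff_nm`` whose observed duration
    (frames * dt) is at least ``min_dwell_ns``.  Runs truncated by the
    trajectory boundaries are judged by their observed duration.
    """
    d = np.asarray(min_distance, dtype=float)
    below = d < cutoff_nm
    state = np.zeros(d.size, dtype=bool)
    for start, stop in _runs(below):
        if (stop - start) * dt >= min_dwell_ns - 1e-12:
            state[start:stop] = True
    return state


def aggregation_probability(state: np.ndarray) -> float:
    """Fraction of simulated time spent aggregated (in [0, 1])."""
    state = np.asarray(state, dtype=bool)
    if state.size == 0:
        raise ValueError("empty state series")
    # uniform dt cancels: count*dt / (n*dt)
    return float(np.count_nonzero(state)) / state.size


def mean_hbond_energy(state: np.ndarray, hbond_energy) -> Optional[float]:
    """Mean hydrogen-bond energy (kJ/mol) over aggregated frames; None if none."""
    state = np.asarray(state, dtype=bool)
    e = np.asarray(hbond_energy, dtype=float)
    if state.size != e.size:
        raise ValueError("state and hbond_energy lengths differ")
    if not state.any():
        return None
    return float(e[state].mean())


def hydrophobic_bonding_flag(hydrophobic_score, threshold: float = 5.0) -> bool:
    """True iff the trajectory-average score reaches the threshold (inclusive)."""
    s = np.asarray(hydrophobic_score, dtype=float)
    if s.size == 0:
        raise ValueError("empty score series")
    return bool(s.mean() >= threshold)


def summarize_trajectory(
    traj: TrajectorySeries,
    *,
    cutoff_nm: float = 0.25,
    min_dwell_ns: float = 5.0,
) -> AggregationSummary:
    """Full dwell-filtered aggregation summary of one trajectory."""
    state = label_aggregated(traj.min_distance, traj.dt, cutoff_nm, min_dwell_ns)
    n_episodes = len(_runs(state))
    return AggregationSummary(
        probability=aggregation_probability(state),
        mean_hbond_energy=(
            mean_hbond_energy(state, traj.hbond_energy)
            if traj.hbond_energy is not None
            else None
        ),
        hydrophobic_bonding=(
            hydrophobic_bonding_flag(traj.hydrophobic_score)
            if traj.hydrophobic_score is not None
            else None
        ),
        n_episodes=n_episodes,
    )


def summarize_replicates(
    trajectories: Sequence[TrajectorySeries],
    *,
    cutoff_nm: float = 0.25,
    min_dwell_ns: float = 5.0,
):
    """Per-replicate summaries plus mean and half-range of the probability.

    Mirrors the practice of running several independent starting
    configurations and reporting the spread as half the range.
    """
    summaries = [
        summarize_trajectory(t, cutoff_nm=cutoff_nm, min_dwell_ns=min_dwell_ns)
        for t in trajectories
    ]
    probs = np.array([s.probability for s in summaries])
    return {
        "replicates": summaries,
        "probability_mean": float(probs.mean()),
        "probability_half_range": float((probs.max() - probs.min()) / 2.0),
    }


def read_trajectory_tsv(path, dt: Optional[float] = None) -> TrajectorySeries:
    """Read a tab-separated observable table.

    Expected columns: ``time_ns  min_distance_nm`` and optionally
    ``hbond_count``, ``hbond_energy_kJ_mol``, ``hydrophobic_score``.
    ``dt`` is inferred from the time column when not given.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"time_ns", "min_distance_nm"}.issubset(df.columns):
        raise ValueError("TSV must contain time_ns and min_distance_nm columns")
    t = df["time_ns"].to_numpy(float)
    if dt is None:
        steps = np.diff(t)
        if steps.size == 0 or np.ptp(steps) > 1e-6 * steps[0]:
            raise ValueError("cannot infer a uniform dt from time_ns")
        dt = float(steps[0])
    opt = {
        "hbond_count": "hbond_count",
        "hbond_energy": "hbond_energy_kJ_mol",
        "hydrophobic_score": "hydrophobic_score",
    }
    kwargs = {
        field: df[col].to_numpy(float) for field, col in opt.items() if col in df.columns
    }
    return TrajectorySeries(dt=dt, min_distance=df["min_distance_nm"].to_numpy(float), **kwargs)
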