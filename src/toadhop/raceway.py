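"""Raceway-trial summaries and their link to single-jump kinematics.

A raceway trial forces a toad along a 15 m track scored in 5 m segments;
a trial ends when the animal either completes the track or refuses 10
consecutive pokes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, InsufficientOverlapError, NoDataError
from . import stats as _stats

TRACK_LENGTH_M = 15.0
SEGMENT_LENGTH_M = 5.0
REFUSAL_LIMIT = 10


@dataclass
class RacewayTrial:
    """Hop/refusal event log for one animal on the raceway.

    ``hops`` is an (n, 2) array of (timestamp s, cumulative position m);
    refusal pokes carry timestamps only (no displacement).
    ``terminated_early`` is set iff the 10-consecutive-refusal rule fired.
    """

    animal_id: str
    hops: np.ndarray
    refusals: np.ndarray = field(default_factory=lambda: np.empty(0))
    terminated_early: bool = False
    track_length: float = TRACK_LENGTH_M
    segment_length: float = SEGMENT_LENGTH_M

    def __post_init__(self) -> None:
        self.hops = np.asarray(self.hops, dtype=float).reshape(-1, 2)
        self.refusals = np.asarray(self.refusals, dtype=float).reshape(-1)
        pos = self.hops[:, 1]
        if len(pos) and (np.any(np.diff(pos) < 0) or pos.min() < 0):
            raise DataIntegrityError("hop positions must be non-decreasing and >= 0")
        if len(pos) and pos.max() > self.track_length + 1e-9:
            raise DataIntegrityError("hop position beyond the end of the track")

    @property
    def final_position(self) -> float:
        return float(self.hops[-1, 1]) if len(self.hops) else 0.0

    @property
    def finished(self) -> bool:
        return self.final_position >= self.track_length - 1e-9


@dataclass
class SegmentStats:
    segment: int          # 1-based
    time_s: float         # time spent in the segment (partial if incomplete)
    hops: int
    completed: bool


@dataclass
class RacewaySummary:
    animal_id: str
    segments: list
    n_hops: int
    total_time_s: float
    mean_hop_distance_m: float
    mean_speed_m_s: float
    finished: bool
    terminated_early: bool


def summarize_raceway(trial: RacewayTrial) -> RacewaySummary:
    """Per-5 m segment times/hop counts plus whole-trial summaries.

    Mean hop distance is final position over hop count; speed is final
    position over elapsed time (distance actually covered, whether or not
    the animal finished). A partial final segment is reported with
    ``completed=False`` rather than dropped.
    """
    if len(trial.hops) == 0 and not trial.terminated_early:
        raise NoDataError(f"trial {trial.animal_id!r} has no events")
    times = trial.hops[:, 0]
    pos = trial.hops[:, 1]
    n_segments = int(np.ceil(trial.track_length / trial.segment_length))
    segments = []
    t_prev = 0.0
    for k in range(1, n_segments + 1):
        lo = (k - 1) * trial.segment_length
        hi = k * trial.segment_length
        in_seg = (pos > lo) & (pos <= hi)
        crossed = pos >= hi - 1e-9
        if crossed.any():
            t_cross = float(times[np.argmax(crossed)])
            segments.append(SegmentStats(k, t_cross - t_prev, int(in_seg.sum()), True))
            t_prev = t_cross
        else:
            if in_seg.any() or (k == 1 and len(pos)):
                t_last = float(times[-1])
                segments.append(SegmentStats(k, t_last - t_prev, int(in_seg.sum()), False))
            break
    n_hops = len(trial.hops)
    total_time = float(times[-1]) if n_hops else 0.0
    mean_hop = trial.final_position / n_hops if n_hops else 0.0
    speed = trial.final_position / total_time if total_time > 0 else 0.0
    return RacewaySummary(
        animal_id=trial.animal_id,
        segments=segments,
        n_hops=n_hops,
        total_time_s=total_time,
        mean_hop_distance_m=mean_hop,
        mean_speed_m_s=speed,
        finished=trial.finished,
        terminated_early=trial.terminated_early,
    )


def jump_vs_raceway(joined: pd.DataFrame):
    """Correlate raceway mean hop distance with jump distance and height.

    ``joined`` must have one row per animal with columns
    ``raceway_mean_hop_m``, ``jump_distance_cm`` and ``jump_height_cm``.
    Returns ``(r_distance, r_height)`` as CorrelationResult objects.
    """
    required = {"raceway_mean_hop_m", "jump_distance_cm", "jump_height_cm"}
    missing = required - set(joined.columns)
    if missing:
        raise DataIntegrityError(f"joined table missing columns {sorted(missing)}")
    if len(joined) < 3:
        raise InsufficientOverlapError(
            f"only {len(joined)} animals in both datasets; need >=3"
        )
    x = joined["raceway_mean_hop_m"].to_numpy(dtype=float)
    r_dist = _stats.pearson_corr(x, joined["jump_distance_cm"].to_numpy(dtype=float))
    r_height = _stats.pearson_corr(x, joined["jump_height_cm"].to_numpy(dtype=float))
    return r_dist, r_height
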