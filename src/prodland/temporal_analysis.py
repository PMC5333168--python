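"""Temporal structure of a probability landscape: per-state time curves,
peak-trajectory tracking, and steady-state detection.

Peaks detected independently at each time step are stitched into
trajectories by greedy nearest-neighbour matching in copy-number space
(L1 metric, closest pairs first, lexicographic tie-break), which is
deterministic and adequate for the smooth peak motion these landscapes
exhibit.  A landscape has reached steady state once successive
distributions stop changing in the sup norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landscape_io import ProbabilityLandscape
from .peak_analysis import SystemPeak
from .projection import MarginalSeries1D, MarginalSeries2D


@dataclass
class TimeCurve:
    """Probability of one (possibly aggregated) state at every time."""

    state_key: tuple[int, ...]
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have the same length")


def state_time_curve(
    series: MarginalSeries1D | MarginalSeries2D | ProbabilityLandscape,
    state_key: int | Sequence[int],
) -> TimeCurve:
    """Time curve of one state of a 1D marginal (key: copy number), a 2D
    marginal (key: copy-number pair) or the full landscape (key: full
    microstate tuple)."""
    key = (int(state_key),) if np.isscalar(state_key) else tuple(
        int(c) for c in state_key
    )
    if isinstance(series, MarginalSeries1D):
        (c,) = key
        if not 0 <= c < series.probs.shape[0]:
            raise KeyError(f"copy number {c} outside axis of {series.species.name}")
        return TimeCurve(key, series.times, series.probs[c, :])
    if isinstance(series, MarginalSeries2D):
        if len(key) != 2:
            raise KeyError("2D marginal expects a (copies_a, copies_b) key")
        a, b = key
        na, nb, _ = series.grid.shape
        if not (0 <= a < na and 0 <= b < nb):
            raise KeyError(f"state {key} outside the {na}x{nb} grid")
        return TimeCurve(key, series.times, series.grid[a, b, :])
    if isinstance(series, ProbabilityLandscape):
        if len(key) != series.state_space.n_species:
            raise KeyError(
                f"microstate key needs {series.state_space.n_species} components"
            )
        match = np.where((series.state_space.states == np.asarray(key)).all(axis=1))[0]
        if match.size == 0:
            raise KeyError(f"microstate {key} not in the state space")
        return TimeCurve(key, series.times, series.probs[match[0], :])
    raise TypeError(f"unsupported series type {type(series).__name__}")


@dataclass
class PeakTrajectory:
    """One peak's matched evolution across consecutive time steps."""

    id: int
    samples: list[tuple[int, tuple[int, ...], float]] = field(default_factory=list)

    @property
    def born_at(self) -> int:
        return self.samples[0][0]

    @property
    def died_at(self) -> int:
        return self.samples[-1][0]

    @property
    def locations(self) -> list[tuple[int, ...]]:
        return [loc for _, loc, _ in self.samples]

    def __len__(self) -> int:
        return len(self.samples)


def _l1(a: tuple[int, ...], b: tuple[int, ...]) -> int:
    return int(sum(abs(x - y) for x, y in zip(a, b)))


def track_peaks(
    peaks_per_time: Sequence[Sequence[SystemPeak]],
    max_displacement: int,
) -> list[PeakTrajectory]:
    """Stitch per-time peak lists into trajectories.

    Between consecutive time steps, candidate matches are sorted by
    (L1 distance, old location, new location) and assigned greedily;
    matches farther than ``max_displacement`` are rejected.  Unmatched old
    peaks end their trajectories; unmatched new peaks start new ones.
    Trajectory ids are assigned in order of birth (ties by location).
    """
    trajectories: list[PeakTrajectory] = []
    # active: location at previous step -> trajectory
    active: dict[tuple[int, ...], PeakTrajectory] = {}
    for step_index, step_peaks in enumerate(peaks_per_time):
        peaks = sorted(step_peaks, key=lambda pk: pk.location)
        if peaks:
            tis = {pk.time_index for pk in peaks}
            if len(tis) != 1:
                raise ValueError("peaks within one step must share a time index")
        new_active: dict[tuple[int, ...], PeakTrajectory] = {}
        unmatched = {pk.location: pk for pk in peaks}
        if active and unmatched:
            candidates = sorted(
                (
                    ( _l1(old, new), old, new)
                    for old in active
                    for new in unmatched
                ),
            )
            taken_old: set[tuple[int, ...]] = set()
            for dist, old, new in candidates:
                if dist > max_displacement:
                    break
                if old in taken_old or new not in unmatched:
                    continue
                traj = active[old]
                pk = unmatched.pop(new)
                traj.samples.append(
                    (pk.time_index, pk.location, pk.value if pk.value is not None else pk.marginal_product)
                )
                taken_old.add(old)
                new_active[new] = traj
        for loc in sorted(unmatched):
            pk = unmatched[loc]
            traj = PeakTrajectory(id=len(trajectories))
            traj.samples.append(
                (pk.time_index, pk.location, pk.value if pk.value is not None else pk.marginal_product)
            )
            trajectories.append(traj)
            new_active[loc] = traj
        active = new_active
    return trajectories


def trajectories_to_records(
    trajectories: Sequence[PeakTrajectory],
    times: Sequence[float] | None = None,
) -> list[dict]:
    """Flatten trajectories into export records (one per sample)."""
    records = []
    for traj in trajectories:
        for ti, loc, value in traj.samples:
            records.append(
                {
                    "trajectory_id": traj.id,
                    "time_index": ti,
                    "time": float(times[ti]) if times is not None else float(ti),
                    "location": " ".join(str(c) for c in loc),
                    "value": float(value),
                    "suspect": False,
                }
            )
    return records


def detect_steady_state(
    landscape: ProbabilityLandscape, tol: float
) -> int | None:
    """Earliest time index from which the landscape no longer changes.

    Returns the first index ``t`` such that the sup norm of successive
    column differences stays below ``tol`` from ``t`` through the end of
    the run, or ``None`` if the landscape is still changing at the last
    step.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if landscape.n_times < 2:
        raise ValueError("need at least two time steps")
    diffs = np.abs(np.diff(landscape.probs, axis=1)).max(axis=0)
    above = np.where(diffs >= tol)[0]
    if above.size == 0:
        return 0
    first = int(above[-1]) + 1
    # a change between the last two steps means the run never settled
    return None if first == diffs.size else first
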