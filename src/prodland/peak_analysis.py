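"""Peak detection and classification on marginal probability distributions.

A *peak* in a 1D marginal is a copy number whose probability exceeds both of
its neighbours and a detection threshold (default ``1e-12``, the noise floor
of the numerical solver).  Because the marginals of the different protein
dimensions are treated as independent, system-level peak states are formed
as the Cartesian product of the per-dimension peak locations: the number of
peaks in the whole system is the product of the per-dimension counts.

Very small detected peaks are typically numerical artefacts of the solver
rather than genuine metastable states; :func:`classify_suspect` flags them
so downstream views can grey them out instead of discarding them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .landscape_io import ProbabilityLandscape
from .projection import MarginalSeries1D, all_marginals_1d

#: default detection threshold — the solver's empirical error floor.
DETECTION_THRESHOLD = 1e-12
#: default cutoff below which a system peak is classified as suspect.
SUSPECT_THRESHOLD = 1e-6


@dataclass(frozen=True)
class Peak1D:
    """A local maximum of one protein's marginal at one time step."""

    species: str
    copy_number: int
    value: float
    time_index: int = 0


@dataclass
class SystemPeak:
    """A candidate multistable state: one peak location per protein.

    ``per_dim_values`` are the marginal probabilities of the contributing 1D
    peaks; ``value`` is the aggregated joint probability of all microstates
    whose protein copy numbers equal ``location`` (filled by
    :func:`evaluate_system_peak`).
    """

    location: tuple[int, ...]
    per_dim_values: tuple[float, ...]
    time_index: int = 0
    value: float | None = None
    suspect: bool = False
    species: tuple[str, ...] = field(default=())

    @property
    def marginal_product(self) -> float:
        """Joint probability under the per-dimension independence
        approximation (product of marginal peak values)."""
        return float(np.prod(self.per_dim_values))


def detect_peaks_1d(
    prob_vector: np.ndarray,
    threshold: float = DETECTION_THRESHOLD,
    species: str = "",
    time_index: int = 0,
) -> list[Peak1D]:
    """Scan a 1D probability vector for local maxima above ``threshold``.

    An interior index is a peak iff it is strictly greater than both
    neighbours; a boundary index is compared only against its single
    neighbour (the landscape boundary can carry genuine spikes, e.g. the
    extinct state at copy number 0).  A plateau — a run of equal values
    strictly above both flanks — contributes one peak at its leftmost
    index.  Results are ordered by copy number.
    """
    p = np.asarray(prob_vector, dtype=float)
    if p.ndim != 1:
        raise ValueError("prob_vector must be 1-D")
    if p.size == 0:
        raise ValueError("empty probability vector")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")

    peaks: list[Peak1D] = []
    i = 0
    n = p.size
    while i < n:
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i - 1] < p[i]
        right_ok = j == n - 1 or p[j + 1] < p[i]
        if left_ok and right_ok and p[i] > threshold:
            peaks.append(Peak1D(species, i, float(p[i]), time_index))
        i = j + 1
    return peaks


def detect_peaks_marginal(
    marginal: MarginalSeries1D,
    time_index: int,
    threshold: float = DETECTION_THRESHOLD,
) -> list[Peak1D]:
    """Peaks of one species' marginal at one time step."""
    return detect_peaks_1d(
        marginal.column(time_index),
        threshold=threshold,
        species=marginal.species.name,
        time_index=time_index,
    )


def combine_peaks(
    per_dimension_peaks: Sequence[Sequence[Peak1D]],
) -> list[SystemPeak]:
    """Cartesian product of per-dimension peak locations.

    The count of system peaks is the product of the per-dimension counts;
    any dimension with zero peaks yields an empty result.  All input peaks
    must share the same time index.
    """
    dims = [list(d) for d in per_dimension_peaks]
    time_indices = {pk.time_index for d in dims for pk in d}
    if len(time_indices) > 1:
        raise ValueError(
            f"peaks from different time indices cannot be combined: "
            f"{sorted(time_indices)}"
        )
    ti = time_indices.pop() if time_indices else 0
    out: list[SystemPeak] = []
    for combo in itertools.product(*dims):
        out.append(
            SystemPeak(
                location=tuple(pk.copy_number for pk in combo),
                per_dim_values=tuple(pk.value for pk in combo),
                time_index=ti,
                species=tuple(pk.species for pk in combo),
            )
        )
    return out


def evaluate_system_peak(
    landscape: ProbabilityLandscape, peak: SystemPeak
) -> SystemPeak:
    """Fill ``peak.value`` with the aggregated joint probability of the
    peak's location.

    The value is the sum, at the peak's time step, over all microstates
    whose protein copy numbers equal the location tuple.  A location inside
    the axes but covering no enumerated microstate has value 0.
    """
    proteins = landscape.state_space.proteins
    if len(peak.location) != len(proteins):
        raise ValueError(
            f"location has {len(peak.location)} components for "
            f"{len(proteins)} proteins"
        )
    for c, sp in zip(peak.location, proteins):
        if not 0 <= c <= sp.max_copies:
            raise ValueError(
                f"location component {c} outside axis 0..{sp.max_copies} "
                f"of {sp.name!r}"
            )
    mask = np.ones(landscape.state_space.n_states, dtype=bool)
    for c, sp in zip(peak.location, proteins):
        mask &= landscape.state_space.column(sp.name) == c
    value = float(landscape.probs[mask, peak.time_index].sum())
    return replace(peak, value=value)


def classify_suspect(
    peaks: Sequence[SystemPeak],
    suspect_threshold: float = SUSPECT_THRESHOLD,
) -> list[SystemPeak]:
    """Flag peaks whose joint value falls below ``suspect_threshold`` as
    suspect (numerical-error) peaks; the rest stay authentic."""
    out = []
    for pk in peaks:
        if pk.value is None:
            raise ValueError(
                "peak values must be filled (evaluate_system_peak) before "
                "suspect classification"
            )
        out.append(replace(pk, suspect=pk.value < suspect_threshold))
    return out


def find_system_peaks(
    landscape: ProbabilityLandscape,
    time_index: int,
    threshold: float = DETECTION_THRESHOLD,
    suspect_threshold: float = SUSPECT_THRESHOLD,
    rank_by_joint: bool = False,
) -> list[SystemPeak]:
    """Full per-time pipeline: marginalize every protein, detect 1D peaks,
    combine across dimensions, evaluate joint values and classify suspects.

    With ``rank_by_joint`` the combined peaks are re-ordered by decreasing
    evaluated joint probability, which surfaces spurious product-rule
    combinations on correlated landscapes; the default keeps the
    deterministic Cartesian-product order.
    """
    marginals = all_marginals_1d(landscape)
    per_dim = [
        detect_peaks_marginal(m, time_index, threshold)
        for m in marginals.values()
    ]
    peaks = [
        evaluate_system_peak(landscape, pk) for pk in combine_peaks(per_dim)
    ]
    peaks = classify_suspect(peaks, suspect_threshold)
    if rank_by_joint:
        peaks.sort(key=lambda pk: (-pk.value, pk.location))
    return peaks
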