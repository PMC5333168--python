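"""Exact marginalization of probability landscapes onto 1D and 2D axes.

A landscape over six or more molecular species cannot be drawn directly, so
it is projected by *aggregation*: all microstates sharing the same copy
number of one protein (1D) or the same copy-number pair of two proteins (2D)
are summed.  Aggregation is exact — no probability mass is lost — so every
marginal conserves the per-time column mass of the full landscape.

Projections are taken over protein-role species only; gene-occupancy species
are aggregated out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .landscape_io import ProbabilityLandscape, SpeciesDescriptor


@dataclass
class MarginalSeries1D:
    """Per-time probability over one protein's copy-number axis.

    ``probs`` has shape ``(max_copies + 1, T)``; the axis always spans
    0..max_copies even where the mass is zero, so views of the same species
    share a fixed geometry across time and simulations.
    """

    species: SpeciesDescriptor
    axis: np.ndarray
    probs: np.ndarray
    times: np.ndarray

    @property
    def n_times(self) -> int:
        return self.times.size

    def column(self, time_index: int) -> np.ndarray:
        return self.probs[:, time_index]

    def masses(self) -> np.ndarray:
        return self.probs.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: species, copy_number, time, probability."""
        c, t = np.meshgrid(self.axis, self.times, indexing="ij")
        return pd.DataFrame(
            {
                "species": self.species.name,
                "copy_number": c.ravel(),
                "time": t.ravel(),
                "probability": self.probs.ravel(),
            }
        )


@dataclass
class MarginalSeries2D:
    """Per-time probability over the joint copy numbers of two proteins.

    ``grid[a, b, t]`` is the aggregated probability of the first species
    having ``a`` copies and the second ``b`` copies at time index ``t``.
    The first species maps to the vertical axis in downstream layouts.
    """

    species_pair: tuple[SpeciesDescriptor, SpeciesDescriptor]
    grid: np.ndarray
    times: np.ndarray

    @property
    def n_times(self) -> int:
        return self.times.size

    def frame(self, time_index: int) -> np.ndarray:
        return self.grid[:, :, time_index]

    def masses(self) -> np.ndarray:
        return self.grid.sum(axis=(0, 1))

    def collapse(self, keep: int) -> MarginalSeries1D:
        """Sum out one axis, recovering the 1D marginal of the other.

        ``keep=0`` keeps the first species of the pair, ``keep=1`` the
        second.
        """
        if keep not in (0, 1):
            raise ValueError("keep must be 0 or 1")
        probs = self.grid.sum(axis=1 - keep)
        sp = self.species_pair[keep]
        return MarginalSeries1D(
            species=sp,
            axis=np.arange(sp.max_copies + 1),
            probs=probs,
            times=self.times,
        )

    def to_frame(self) -> pd.DataFrame:
        a_ax = np.arange(self.grid.shape[0])
        b_ax = np.arange(self.grid.shape[1])
        a, b, t = np.meshgrid(a_ax, b_ax, self.times, indexing="ij")
        return pd.DataFrame(
            {
                "species_a": self.species_pair[0].name,
                "species_b": self.species_pair[1].name,
                "copies_a": a.ravel(),
                "copies_b": b.ravel(),
                "time": t.ravel(),
                "probability": self.grid.ravel(),
            }
        )


def _protein_descriptor(
    landscape: ProbabilityLandscape, label: str
) -> SpeciesDescriptor:
    sp = landscape.state_space.descriptor(label)
    if not sp.is_protein:
        raise ValueError(
            f"{label!r} has role {sp.role!r}; projections are defined over "
            "protein species only"
        )
    return sp


def marginalize_1d(
    landscape: ProbabilityLandscape, species: str
) -> MarginalSeries1D:
    """Aggregate the landscape over all microstates sharing each copy number
    of ``species``."""
    sp = _protein_descriptor(landscape, species)
    copies = landscape.state_space.column(species)
    out = np.zeros((sp.max_copies + 1, landscape.n_times))
    np.add.at(out, copies, landscape.probs)
    return MarginalSeries1D(
        species=sp,
        axis=np.arange(sp.max_copies + 1),
        probs=out,
        times=landscape.times.copy(),
    )


def marginalize_2d(
    landscape: ProbabilityLandscape, species_a: str, species_b: str
) -> MarginalSeries2D:
    """Aggregate over all microstates sharing each (copies_a, copies_b)
    pair; every other species is summed out."""
    if species_a == species_b:
        raise ValueError("the two projected species must be distinct")
    sa = _protein_descriptor(landscape, species_a)
    sb = _protein_descriptor(landscape, species_b)
    ca = landscape.state_space.column(species_a)
    cb = landscape.state_space.column(species_b)
    na, nb = sa.max_copies + 1, sb.max_copies + 1
    flat = np.zeros((na * nb, landscape.n_times))
    np.add.at(flat, ca * nb + cb, landscape.probs)
    return MarginalSeries2D(
        species_pair=(sa, sb),
        grid=flat.reshape(na, nb, landscape.n_times),
        times=landscape.times.copy(),
    )


def enumerate_projections(
    protein_labels: Sequence[str],
) -> list[tuple[str, str]]:
    """All unordered protein pairs, in input order: C(k, 2) 2D projections
    for a k-protein network."""
    labels = list(protein_labels)
    if len(labels) < 2:
        raise ValueError("need at least two proteins to form 2D projections")
    if len(set(labels)) != len(labels):
        raise ValueError("protein labels must be unique")
    return list(itertools.combinations(labels, 2))


def all_marginals_1d(landscape: ProbabilityLandscape) -> dict[str, MarginalSeries1D]:
    """1D marginal for every protein in the network, keyed by name."""
    return {
        sp.name: marginalize_1d(landscape, sp.name)
        for sp in landscape.state_space.proteins
    }


def all_marginals_2d(
    landscape: ProbabilityLandscape,
) -> dict[tuple[str, str], MarginalSeries2D]:
    """2D marginal for every unordered protein pair, keyed by name pair."""
    labels = [sp.name for sp in landscape.state_space.proteins]
    return {
        pair: marginalize_2d(landscape, *pair)
        for pair in enumerate_projections(labels)
    }
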