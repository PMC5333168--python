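"""Reading, writing and validation of probability-landscape data.

A *simulation* of a stochastic reaction network is stored as plain text:

* one **state-space table** — one microstate per row, one whitespace-separated
  integer column per molecular species, with an optional single header line of
  species names;
* **T probability files** — file *j* holds one probability per line, line *i*
  giving the probability of microstate *i* (row *i* of the state-space table)
  at time *t_j*.

The in-memory containers (:class:`StateSpace`, :class:`ProbabilityLandscape`)
are thin, validated wrappers around integer / float NumPy arrays.  Probability
columns must each sum to one: every landscape is a family of probability
distributions over the same discrete state space, indexed by time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLE_PROTEIN = "protein"
ROLE_GENE_UNBOUND = "gene_unbound"
ROLE_GENE_BOUND = "gene_bound_complex"
_ROLES = (ROLE_PROTEIN, ROLE_GENE_UNBOUND, ROLE_GENE_BOUND)

#: |column mass - 1| below this is considered exact.
MASS_PASS_TOL = 1e-9
#: deviations between the pass and warn tier are logged but accepted.
MASS_WARN_TOL = 1e-6
#: deviations above this reject the file outright.
MASS_ERROR_TOL = 1e-2


class LandscapeIOError(ValueError):
    """Base class for ingestion failures."""


class ParseError(LandscapeIOError):
    """A file could not be tokenised into the expected dialect."""


class ValidationError(LandscapeIOError):
    """A file parsed, but its contents violate a container invariant."""


@dataclass(frozen=True)
class SpeciesDescriptor:
    """One molecular species: a protein, an unbound gene, or a bound
    protein–DNA complex.

    ``max_copies`` is the largest copy number the species may take; gene
    species (a promoter site either free or occupied) are single-copy.
    """

    name: str
    role: str = ROLE_PROTEIN
    max_copies: int = 0

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown species role {self.role!r}")
        if self.max_copies < 0:
            raise ValueError(f"{self.name}: max_copies must be >= 0")
        if self.role != ROLE_PROTEIN and self.max_copies != 1:
            raise ValueError(f"{self.name}: gene species have max_copies = 1")

    @property
    def is_protein(self) -> bool:
        return self.role == ROLE_PROTEIN


@dataclass
class StateSpace:
    """The enumerated microstates of a network.

    ``states`` is an ``N x n`` integer matrix: row *i* is microstate *s_i*,
    entry ``(i, j)`` the copy number of species *j* in that state.  Rows are
    unique and every entry respects its species' ``max_copies``.
    """

    species: list[SpeciesDescriptor]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValidationError("states must be a 2-D matrix")
        if not np.issubdtype(self.states.dtype, np.integer):
            if not np.all(self.states == np.floor(self.states)):
                raise ValidationError("copy numbers must be integers")
            self.states = self.states.astype(np.int64)
        if self.states.shape[0] == 0:
            raise ValidationError("no states")
        if self.states.shape[1] != len(self.species):
            raise ValidationError(
                f"{len(self.species)} species but {self.states.shape[1]} columns"
            )
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValidationError("species names must be unique")
        if (self.states < 0).any():
            raise ValidationError("negative copy number")
        caps = np.array([s.max_copies for s in self.species])
        if (self.states > caps).any():
            bad = np.argwhere(self.states > caps)[0]
            raise ValidationError(
                f"state row {bad[0]} exceeds max_copies of species "
                f"{self.species[bad[1]].name!r}"
            )
        if np.unique(self.states, axis=0).shape[0] != self.states.shape[0]:
            raise ValidationError("duplicate microstate rows")

    # -- basic queries -----------------------------------------------------
    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def n_species(self) -> int:
        return self.states.shape[1]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def proteins(self) -> list[SpeciesDescriptor]:
        return [s for s in self.species if s.is_protein]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def descriptor(self, name: str) -> SpeciesDescriptor:
        return self.species[self.index_of(name)]

    def column(self, name: str) -> np.ndarray:
        """Copy numbers of one species across all microstates."""
        return self.states[:, self.index_of(name)]


@dataclass
class ProbabilityLandscape:
    """Probability of every microstate at every output time.

    ``probs`` is ``N x T``; column *j* is the distribution over the state
    space at time ``times[j]`` and sums to one (up to the ingestion
    tolerances above).
    """

    state_space: StateSpace
    times: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("times must be 1-D")
        if self.probs.shape != (self.state_space.n_states, self.times.size):
            raise ValidationError(
                f"probs shape {self.probs.shape} does not match "
                f"({self.state_space.n_states}, {self.times.size})"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    @property
    def n_times(self) -> int:
        return self.times.size

    def column(self, time_index: int) -> np.ndarray:
        return self.probs[:, time_index]

    def column_masses(self) -> np.ndarray:
        return self.probs.sum(axis=0)


# ---------------------------------------------------------------------------
# state-space files
# ---------------------------------------------------------------------------

def _is_int_token(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


def read_state_space(
    path: str | Path,
    species_meta: Sequence[SpeciesDescriptor] | None = None,
) -> StateSpace:
    """Read a state-space table.

    The file holds one microstate per row as whitespace-separated integers.
    A single optional first line containing any non-numeric token is taken
    as a header of species names.  When ``species_meta`` is absent, species
    are protein-role with ``max_copies`` inferred as the per-column maximum.
    """
    path = Path(path)
    rows: list[list[int]] = []
    header: list[str] | None = None
    n_cols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if lineno == 1 and not all(_is_int_token(t) for t in toks):
                header = toks
                continue
            try:
                vals = [int(t) for t in toks]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer token in state row"
                ) from None
            if any(v < 0 for v in vals):
                raise ParseError(f"{path}: line {lineno}: negative copy number")
            if n_cols is None:
                n_cols = len(vals)
            elif len(vals) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"found {len(vals)}"
                )
            rows.append(vals)
    if not rows:
        raise ValidationError(f"{path}: no states")
    states = np.asarray(rows, dtype=np.int64)

    if species_meta is not None:
        species = list(species_meta)
        if len(species) != states.shape[1]:
            raise ValidationError(
                f"{path}: species_meta has {len(species)} entries for "
                f"{states.shape[1]} columns"
            )
    else:
        maxima = states.max(axis=0)
        if header is not None:
            if len(header) != states.shape[1]:
                raise ParseError(
                    f"{path}: header has {len(header)} names for "
                    f"{states.shape[1]} columns"
                )
            names = header
        else:
            names = [f"x{j + 1}" for j in range(states.shape[1])]
        species = [
            SpeciesDescriptor(name, ROLE_PROTEIN, int(m))
            for name, m in zip(names, maxima)
        ]
    try:
        return StateSpace(species, states)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_state_space(state_space: StateSpace, path: str | Path) -> Path:
    """Write the table in the same dialect :func:`read_state_space` accepts."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(" ".join(state_space.names) + "\n")
        np.savetxt(fh, state_space.states, fmt="%d")
    return path


# ---------------------------------------------------------------------------
# probability files
# ---------------------------------------------------------------------------

def read_probability_series(
    state_space: StateSpace,
    paths: Sequence[str | Path],
    times: Sequence[float],
) -> ProbabilityLandscape:
    """Read one probability file per time step into a landscape.

    File *j* must hold exactly ``N`` numeric lines (scientific notation is
    fine); line *i* is the probability of state row *i* at ``times[j]``.
    Files are sorted by their time stamp on ingestion, so the resulting
    landscape does not depend on the order the paths are supplied in.
    """
    if len(paths) != len(times):
        raise ValidationError(
            f"{len(paths)} probability files but {len(times)} time values"
        )
    if len(paths) == 0:
        raise ValidationError("no probability files")
    order = np.argsort(np.asarray(times, dtype=float), kind="stable")
    paths = [Path(paths[i]) for i in order]
    times_sorted = np.asarray(times, dtype=float)[order]

    n = state_space.n_states
    probs = np.empty((n, len(paths)))
    for j, p in enumerate(paths):
        try:
            col = np.loadtxt(p, dtype=float, ndmin=1)
        except ValueError as exc:
            raise ParseError(f"{p}: {exc}") from None
        if col.ndim != 1:
            raise ParseError(f"{p}: expected one value per line")
        if col.size != n:
            raise ValidationError(
                f"{p}: has {col.size} lines but the state space has {n} states"
            )
        if col.min() < -1e-12 or col.max() > 1 + 1e-12:
            raise ValidationError(f"{p}: probability outside [0, 1]")
        mass_dev = abs(col.sum() - 1.0)
        if mass_dev > MASS_ERROR_TOL:
            raise ValidationError(
                f"{p}: probability mass {col.sum():.6g} deviates from 1 "
                f"by more than {MASS_ERROR_TOL}"
            )
        if mass_dev > MASS_WARN_TOL:
            logger.warning(
                "%s: probability mass deviates from 1 by %.3g", p, mass_dev
            )
        probs[:, j] = np.clip(col, 0.0, 1.0)
    return ProbabilityLandscape(state_space, times_sorted, probs)


def write_probability_series(
    landscape: ProbabilityLandscape,
    directory: str | Path,
    prefix: str = "prob",
) -> list[Path]:
    """Write one full-precision text file per time step plus a YAML manifest
    mapping each file name to its time value."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(landscape.n_times - 1)))
    paths = []
    manifest: dict[str, float] = {}
    for j, t in enumerate(landscape.times):
        p = directory / f"{prefix}_{j:0{width}d}.txt"
        np.savetxt(p, landscape.probs[:, j], fmt="%.17e")
        paths.append(p)
        manifest[p.name] = float(t)
    with open(directory / f"{prefix}_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def resolve_series_inputs(
    spec: str | Path, base_dir: str | Path | None = None
) -> tuple[list[Path], list[float]]:
    """Resolve a manifest file or a glob pattern to (paths, times).

    A YAML manifest maps file names (relative to the manifest) to time
    values.  A glob pattern yields files in lexicographic order with their
    position index used as the time value.
    """
    spec = str(spec)
    p = Path(spec)
    if p.is_file() and p.suffix in {".yaml", ".yml"}:
        with open(p) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict) or not mapping:
            raise ValidationError(f"{p}: manifest must map file names to times")
        items = sorted(mapping.items(), key=lambda kv: float(kv[1]))
        paths = [p.parent / name for name, _ in items]
        times = [float(t) for _, t in items]
    else:
        base = Path(base_dir) if base_dir is not None else Path(".")
        paths = sorted(base.glob(spec)) if not p.is_absolute() else sorted(
            p.parent.glob(p.name)
        )
        times = [float(i) for i in range(len(paths))]
    if not paths:
        raise ValidationError(f"no probability files match {spec!r}")
    missing = [str(q) for q in paths if not Path(q).is_file()]
    if missing:
        raise ValidationError(f"missing probability file: {missing[0]}")
    return [Path(q) for q in paths], times


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class LandscapeValidationReport:
    """Per-time probability-mass audit of a landscape."""

    times: np.ndarray
    masses: np.ndarray
    min_value: float
    max_value: float
    violations: list[str] = field(default_factory=list)

    @property
    def max_mass_deviation(self) -> float:
        return float(np.abs(self.masses - 1.0).max())

    @property
    def passed(self) -> bool:
        return not self.violations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mass": self.masses,
                "deviation": np.abs(self.masses - 1.0),
            }
        )


def validate_landscape(
    landscape: ProbabilityLandscape, mass_tol: float = MASS_PASS_TOL
) -> LandscapeValidationReport:
    """Audit a landscape: per-time total mass and value range.

    Passes iff every entry lies in [0, 1] and every column mass is within
    ``mass_tol`` of one.  Failures are reported, not raised.
    """
    masses = landscape.column_masses()
    vmin = float(landscape.probs.min()) if landscape.probs.size else 0.0
    vmax = float(landscape.probs.max()) if landscape.probs.size else 0.0
    violations: list[str] = []
    bad = np.where(np.abs(masses - 1.0) > mass_tol)[0]
    for j in bad:
        violations.append(
            f"time index {j} (t={landscape.times[j]:g}): mass {masses[j]:.12g} "
            f"deviates from 1 by {abs(masses[j] - 1.0):.3g}"
        )
    if vmin < 0.0:
        violations.append(f"negative probability {vmin:.3g}")
    if vmax > 1.0:
        violations.append(f"probability {vmax:.3g} exceeds 1")
    return LandscapeValidationReport(
        times=landscape.times.copy(),
        masses=masses,
        min_value=vmin,
        max_value=vmax,
        violations=violations,
    )


# ---------------------------------------------------------------------------
# peaks / trajectories tables
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = [
    "trajectory_id",
    "time_index",
    "time",
    "location",
    "value",
    "suspect",
]


def _location_str(location: Iterable[int]) -> str:
    return " ".join(str(int(c)) for c in location)


def peaks_to_records(
    peaks: Iterable,
    times: Sequence[float] | None = None,
    trajectory_id: int | None = None,
) -> list[dict]:
    """Convert peak-like objects (anything with ``location``, ``value``,
    ``suspect``, ``time_index`` attributes) to plain export records."""
    records = []
    for pk in peaks:
        ti = int(pk.time_index)
        records.append(
            {
                "trajectory_id": trajectory_id,
                "time_index": ti,
                "time": float(times[ti]) if times is not None else float(ti),
                "location": _location_str(pk.location),
                "value": None if pk.value is None else float(pk.value),
                "suspect": bool(pk.suspect),
            }
        )
    return records


def write_peaks_table(records: Sequence[dict], path: str | Path) -> Path:
    """Write peak/trajectory records as CSV or JSON (by file suffix).

    An empty record list yields a header-only CSV / empty JSON array.
    """
    path = Path(path)
    frame = pd.DataFrame(list(records), columns=_PEAK_COLUMNS)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=1)
            fh.write("\n")
    else:
        frame.to_csv(path, index=False)
    return path


def species_to_meta(species: Sequence[SpeciesDescriptor]) -> list[dict]:
    return [dataclasses.asdict(s) for s in species]


def meta_to_species(meta: Sequence[dict]) -> list[SpeciesDescriptor]:
    return [SpeciesDescriptor(**m) for m in meta]
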