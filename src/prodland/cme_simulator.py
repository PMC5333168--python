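"""Finite-buffer state-space enumeration and discrete CME propagation.

The discrete chemical master equation (dCME) describes a reaction network as
a continuous-time Markov chain over microstates (copy-number tuples):

    dp/dt = A p,

where ``A`` is the sparse transition-rate operator assembled from mass-action
propensities.  The state space is made finite by the buffer-queue device:
species are partitioned into *molecular equivalence groups* (MEGs) — subsets
interconvertible through mass-balanced reactions — and each MEG is assigned a
buffer capacity bounding the total number of molecular units it may hold.  A
protein counts as one unit; a protein–DNA complex formed by dimer binding
sequesters two units of the binding protein.  Gene (promoter) sites conserve
exactly one copy across their occupancy species.  Reactions that would
overflow a buffer are suppressed (reflecting boundary).

Presets are provided for the classic 2-gene toggle switch (two mutually
repressing genes whose protein dimers occupy each other's promoter), a
3-gene cascade in which the output gene is activated by the two upstream
proteins, and the single-species birth-death process whose truncated-Poisson
stationary law serves as an analytic benchmark.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .landscape_io import (
    ROLE_GENE_BOUND,
    ROLE_GENE_UNBOUND,
    ROLE_PROTEIN,
    ProbabilityLandscape,
    SpeciesDescriptor,
    StateSpace,
)


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction.

    Stoichiometries are copy-number changes keyed by species name; the
    propensity in state x is ``rate * prod_s ff(x_s, r_s)`` with ``ff`` the
    falling factorial over reactant counts.
    """

    name: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"{self.name}: rate must be non-negative")
        if any(v < 0 for v in (*self.reactants.values(), *self.products.values())):
            raise ValueError(f"{self.name}: stoichiometries must be non-negative")
        net = {
            s: self.products.get(s, 0) - self.reactants.get(s, 0)
            for s in {*self.reactants, *self.products}
        }
        if not any(net.values()):
            raise ValueError(f"{self.name}: at least one species must change")


@dataclass(frozen=True)
class MolecularEquivalenceGroup:
    """A buffered group of interconvertible species.

    ``weights`` gives the molecular units one copy of each member species
    occupies in the buffer (free protein = 1; a bound complex that
    sequesters a protein dimer = 2).  ``capacity`` bounds the weighted sum.
    """

    name: str
    weights: Mapping[str, int]
    capacity: int

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError(f"MEG {self.name}: buffer capacity must be positive")


@dataclass
class ReactionNetwork:
    """Species, reactions, gene-site conservation and MEG buffers."""

    species: list[SpeciesDescriptor]
    reactions: list[Reaction]
    megs: list[MolecularEquivalenceGroup]
    #: each gene site lists its mutually exclusive occupancy species
    #: (unbound + bound forms), whose copy numbers sum to exactly 1.
    gene_sites: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        known = set(names)
        for r in self.reactions:
            for s in {*r.reactants, *r.products}:
                if s not in known:
                    raise ValueError(f"reaction {r.name}: unknown species {s!r}")
        site_species = {s for site in self.gene_sites for s in site}
        buffered = {s for meg in self.megs for s in meg.weights}
        for s in self.species:
            if s.name not in site_species and s.name not in buffered:
                raise ValueError(
                    f"species {s.name!r} is neither a gene-site species nor "
                    "covered by a MEG buffer: state space would be unbounded"
                )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class InitialCondition:
    """A single microstate carrying probability one at t = 0."""

    microstate: tuple[int, ...]

    def to_vector(self, states: StateSpace) -> np.ndarray:
        match = np.where(
            (states.states == np.asarray(self.microstate)).all(axis=1)
        )[0]
        if match.size == 0:
            raise ValueError(
                f"initial microstate {self.microstate} is not in the "
                "enumerated state space"
            )
        p0 = np.zeros(states.n_states)
        p0[match[0]] = 1.0
        return p0


# ---------------------------------------------------------------------------
# state-space enumeration
# ---------------------------------------------------------------------------

def _bounded_tuples(weights: Sequence[int], capacity: int):
    """All non-negative integer tuples x with sum_i w_i x_i <= capacity."""
    if not weights:
        yield ()
        return
    w0 = weights[0]
    for x0 in range(capacity // w0 + 1):
        for rest in _bounded_tuples(weights[1:], capacity - w0 * x0):
            yield (x0, *rest)


def enumerate_states(network: ReactionNetwork) -> StateSpace:
    """Enumerate every microstate admitted by the finite-buffer constraints.

    A tuple is admitted iff (i) each gene site holds exactly one copy across
    its occupancy species and (ii) for each MEG the weighted unit count —
    free copies plus units sequestered in bound complexes — does not exceed
    the buffer capacity.  Rows are returned in lexicographic order of the
    copy-number tuple (species order of the network), which makes outputs
    byte-reproducible.
    """
    names = network.names
    idx = {n: j for j, n in enumerate(names)}
    site_species = {s for site in network.gene_sites for s in site}

    # per-MEG free (non-gene-site) members, in species order
    meg_free: list[list[str]] = []
    for meg in network.megs:
        members = [n for n in names if n in meg.weights and n not in site_species]
        meg_free.append(members)

    # occupancy combinations: one active species per gene site
    site_choices = [range(len(site)) for site in network.gene_sites]
    rows: list[np.ndarray] = []
    for combo in itertools.product(*site_choices):
        base = np.zeros(len(names), dtype=np.int64)
        for site, choice in zip(network.gene_sites, combo):
            base[idx[site[choice]]] = 1
        # remaining buffer per MEG after sequestration by bound complexes
        blocks: list[list[tuple[int, ...]]] = []
        feasible = True
        for meg, members in zip(network.megs, meg_free):
            sequestered = sum(
                meg.weights[s] * base[idx[s]] for s in meg.weights if s in site_species
            )
            remaining = meg.capacity - sequestered
            if remaining < 0:
                feasible = False
                break
            weights = [meg.weights[m] for m in members]
            blocks.append(list(_bounded_tuples(weights, remaining)))
        if not feasible:
            continue
        flat_members = [m for members in meg_free for m in members]
        member_cols = [idx[m] for m in flat_members]
        for parts in itertools.product(*blocks):
            row = base.copy()
            row[member_cols] = list(itertools.chain.from_iterable(parts))
            rows.append(row)
    if not rows:
        raise ValueError("enumeration produced no states")
    states = np.vstack(rows)
    order = np.lexsort(states[:, ::-1].T)
    return StateSpace(list(network.species), states[order])


def state_space_size_bound(network: ReactionNetwork) -> int:
    """Product over MEGs of C(b_j + n_j, n_j): the finite-buffer bound on
    the state-space size (conservation constraints can only remove
    states)."""
    bound = 1
    for meg in network.megs:
        n_j = len(meg.weights)
        bound *= math.comb(meg.capacity + n_j, n_j)
    return bound


# ---------------------------------------------------------------------------
# rate matrix and propagation
# ---------------------------------------------------------------------------

def _falling_factorial(x: np.ndarray, k: int) -> np.ndarray:
    out = np.ones_like(x, dtype=float)
    for i in range(k):
        out *= np.maximum(x - i, 0)
    return out


def build_rate_matrix(
    network: ReactionNetwork, states: StateSpace
) -> sp.csc_matrix:
    """Assemble the sparse transition-rate operator A.

    Off-diagonal ``A[to, from]`` is the mass-action propensity of the
    reaction taking ``from -> to``; firings whose target falls outside the
    enumerated space (buffer overflow) are suppressed, and the diagonal is
    the negated off-diagonal column sum, so every column of A cancels to
    zero at machine precision and probability mass is conserved.
    """
    mat = states.states
    n = states.n_states
    # row lookup via the lexicographic order enumerate_states guarantees
    view = np.ascontiguousarray(mat).view(
        np.dtype((np.void, mat.dtype.itemsize * mat.shape[1]))
    ).ravel()
    sorter = np.argsort(view)
    sorted_view = view[sorter]

    def locate(targets: np.ndarray) -> np.ndarray:
        tview = np.ascontiguousarray(targets).view(
            np.dtype((np.void, targets.dtype.itemsize * targets.shape[1]))
        ).ravel()
        pos = np.searchsorted(sorted_view, tview)
        pos = np.clip(pos, 0, n - 1)
        found = sorted_view[pos] == tview
        out = np.where(found, sorter[pos], -1)
        return out

    data: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    names = states.names
    for reac in network.reactions:
        prop = np.full(n, reac.rate)
        for s, k in reac.reactants.items():
            prop *= _falling_factorial(mat[:, names.index(s)], k)
        src = np.where(prop > 0)[0]
        if src.size == 0:
            continue
        delta = np.zeros(len(names), dtype=np.int64)
        for s, k in reac.reactants.items():
            delta[names.index(s)] -= k
        for s, k in reac.products.items():
            delta[names.index(s)] += k
        targets = mat[src] + delta
        ok = (targets >= 0).all(axis=1)
        tgt_idx = np.full(src.size, -1)
        tgt_idx[ok] = locate(targets[ok])
        keep = tgt_idx >= 0
        data.append(prop[src[keep]])
        rows.append(tgt_idx[keep])
        cols.append(src[keep])
    if data:
        a = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsc()
    else:
        a = sp.csc_matrix((n, n))
    a = a - sp.diags(np.asarray(a.sum(axis=0)).ravel(), format="csc")
    return a.tocsc()


def propagate(
    A: sp.spmatrix,
    p0: np.ndarray,
    times: Sequence[float],
    state_space: StateSpace,
    method: str = "expm",
    rtol: float = 1e-10,
) -> ProbabilityLandscape:
    """Solve dp/dt = A p from ``p0`` (the state at ``times[0]``).

    ``method='expm'`` uses the scaled matrix-exponential action (exact for
    this linear system up to round-off); ``method='ivp'`` uses stiff BDF
    integration at tolerance ``rtol``.  Columns of the result each carry
    probability mass one to well within 1e-9.
    """
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"p0 mass {p0.sum():.12g} is not 1")
    if (p0 < 0).any():
        raise ValueError("p0 must be non-negative")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be strictly increasing and start >= 0")

    n = p0.size
    out = np.empty((n, times.size))
    out[:, 0] = p0
    if method == "expm":
        p = p0
        A = A.tocsc()
        for j in range(1, times.size):
            dt = times[j] - times[j - 1]
            p = spla.expm_multiply(A * dt, p)
            out[:, j] = p
    elif method == "ivp":
        sol = solve_ivp(
            lambda _, y: A @ y,
            (times[0], times[-1]),
            p0,
            t_eval=times,
            method="BDF",
            jac=sp.csc_matrix(A),
            rtol=rtol,
            atol=rtol * 1e-2,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        out = sol.y
    else:
        raise ValueError(f"unknown propagation method {method!r}")
    # round-off can leave tiny negatives; clamp without touching real mass
    np.clip(out, 0.0, 1.0, out=out)
    return ProbabilityLandscape(state_space, times, out)


def run_simulation(
    network: ReactionNetwork,
    initial: InitialCondition,
    times: Sequence[float],
    method: str = "expm",
    rtol: float = 1e-10,
) -> ProbabilityLandscape:
    """Enumerate, assemble and propagate in one call."""
    states = enumerate_states(network)
    a = build_rate_matrix(network, states)
    p0 = initial.to_vector(states)
    return propagate(a, p0, times, states, method=method, rtol=rtol)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToggleRates:
    """Rate constants of the 2-gene toggle switch.

    Defaults are symmetric and sit in the strong-repression bistable
    regime: slow promoter switching relative to protein turnover keeps the
    bound and unbound gene states long-lived, so each protein marginal is a
    well-separated mixture of an expressing mode near synthesis/degradation
    and a repressed mode at zero.
    """

    synthesis_a: float = 12.0
    synthesis_b: float = 12.0
    degradation_a: float = 1.0
    degradation_b: float = 1.0
    binding_a: float = 0.002   # Pa dimer occupying gene B's promoter
    unbinding_a: float = 0.015
    binding_b: float = 0.002   # Pb dimer occupying gene A's promoter
    unbinding_b: float = 0.015


def toggle_switch_preset(
    buffers: tuple[int, int] = (120, 240),
    rates: ToggleRates | None = None,
) -> tuple[ReactionNetwork, InitialCondition]:
    """The 2-gene toggle switch: 6 species (Pa, Pb, Da, Db, BDa, BDb).

    Single-copy genes A and B express proteins Pa and Pb; a dimer of each
    protein can occupy the other gene's promoter (BDb = gene B bound by a
    Pa dimer, sequestering 2 Pa units from buffer A; symmetrically BDa).
    The initial condition is zero proteins with both genes unbound.
    """
    ba, bb = buffers
    if ba < 4 or bb < 4:
        raise ValueError(
            "toggle buffers must be >= 4 so that a buffer can hold a "
            "protein dimer plus free copies"
        )
    r = rates or ToggleRates()
    species = [
        SpeciesDescriptor("Pa", ROLE_PROTEIN, ba),
        SpeciesDescriptor("Pb", ROLE_PROTEIN, bb),
        SpeciesDescriptor("Da", ROLE_GENE_UNBOUND, 1),
        SpeciesDescriptor("Db", ROLE_GENE_UNBOUND, 1),
        SpeciesDescriptor("BDa", ROLE_GENE_BOUND, 1),
        SpeciesDescriptor("BDb", ROLE_GENE_BOUND, 1),
    ]
    reactions = [
        Reaction("synthesis_Pa", {"Da": 1}, {"Da": 1, "Pa": 1}, r.synthesis_a),
        Reaction("synthesis_Pb", {"Db": 1}, {"Db": 1, "Pb": 1}, r.synthesis_b),
        Reaction("degradation_Pa", {"Pa": 1}, {}, r.degradation_a),
        Reaction("degradation_Pb", {"Pb": 1}, {}, r.degradation_b),
        Reaction(
            "bind_Pa_dimer_to_Db", {"Pa": 2, "Db": 1}, {"BDb": 1}, r.binding_a
        ),
        Reaction(
            "unbind_Pa_dimer_from_Db", {"BDb": 1}, {"Pa": 2, "Db": 1}, r.unbinding_a
        ),
        Reaction(
            "bind_Pb_dimer_to_Da", {"Pb": 2, "Da": 1}, {"BDa": 1}, r.binding_b
        ),
        Reaction(
            "unbind_Pb_dimer_from_Da", {"BDa": 1}, {"Pb": 2, "Da": 1}, r.unbinding_b
        ),
    ]
    megs = [
        MolecularEquivalenceGroup("A_units", {"Pa": 1, "BDb": 2}, ba),
        MolecularEquivalenceGroup("B_units", {"Pb": 1, "BDa": 2}, bb),
    ]
    gene_sites = [("Da", "BDa"), ("Db", "BDb")]
    network = ReactionNetwork(species, reactions, megs, gene_sites)
    initial = InitialCondition((0, 0, 1, 1, 0, 0))
    return network, initial


@dataclass(frozen=True)
class CascadeRates:
    """Rate constants of the 3-gene cascade (output gene activated by the
    two upstream proteins).

    Defaults target a trimodal output: the basal, A-activated and
    B-activated promoter states of gene C express at well-separated levels
    (about 0.5, 9.5 and 29.5 mean copies), and slow promoter switching
    keeps all three modes populated.
    """

    synthesis_a: float = 8.0
    synthesis_b: float = 8.0
    degradation: float = 1.0
    basal_c: float = 0.5
    activated_c_by_a: float = 9.5
    activated_c_by_b: float = 29.5
    binding_a: float = 0.004   # Pa dimer activating gene C
    unbinding_a: float = 0.3
    binding_b: float = 0.004   # Pb dimer activating gene C
    unbinding_b: float = 0.3


def cascade_preset(
    buffers: tuple[int, int, int] = (20, 20, 45),
    rates: CascadeRates | None = None,
) -> tuple[ReactionNetwork, InitialCondition]:
    """3-gene network: constitutive genes A and B; gene C activated by
    either a Pa dimer or a Pb dimer occupying its promoter.

    With both binding constants zero, protein C reduces to a pure
    birth-death species with a truncated-Poisson(basal_c/degradation)
    marginal.
    """
    ba, bb, bc = buffers
    if min(ba, bb) < 4 or bc < 1:
        raise ValueError("cascade buffers too small (activating dimer needs 2 units)")
    r = rates or CascadeRates()
    species = [
        SpeciesDescriptor("Pa", ROLE_PROTEIN, ba),
        SpeciesDescriptor("Pb", ROLE_PROTEIN, bb),
        SpeciesDescriptor("Pc", ROLE_PROTEIN, bc),
        SpeciesDescriptor("Da", ROLE_GENE_UNBOUND, 1),
        SpeciesDescriptor("Db", ROLE_GENE_UNBOUND, 1),
        SpeciesDescriptor("Dc", ROLE_GENE_UNBOUND, 1),
        SpeciesDescriptor("ADca", ROLE_GENE_BOUND, 1),
        SpeciesDescriptor("ADcb", ROLE_GENE_BOUND, 1),
    ]
    reactions = [
        Reaction("synthesis_Pa", {"Da": 1}, {"Da": 1, "Pa": 1}, r.synthesis_a),
        Reaction("synthesis_Pb", {"Db": 1}, {"Db": 1, "Pb": 1}, r.synthesis_b),
        Reaction("degradation_Pa", {"Pa": 1}, {}, r.degradation),
        Reaction("degradation_Pb", {"Pb": 1}, {}, r.degradation),
        Reaction("degradation_Pc", {"Pc": 1}, {}, r.degradation),
        Reaction("basal_synthesis_Pc", {"Dc": 1}, {"Dc": 1, "Pc": 1}, r.basal_c),
        Reaction(
            "activated_synthesis_Pc_by_A",
            {"ADca": 1},
            {"ADca": 1, "Pc": 1},
            r.activated_c_by_a,
        ),
        Reaction(
            "activated_synthesis_Pc_by_B",
            {"ADcb": 1},
            {"ADcb": 1, "Pc": 1},
            r.activated_c_by_b,
        ),
        Reaction(
            "bind_Pa_dimer_to_Dc", {"Pa": 2, "Dc": 1}, {"ADca": 1}, r.binding_a
        ),
        Reaction(
            "unbind_Pa_dimer_from_Dc", {"ADca": 1}, {"Pa": 2, "Dc": 1}, r.unbinding_a
        ),
        Reaction(
            "bind_Pb_dimer_to_Dc", {"Pb": 2, "Dc": 1}, {"ADcb": 1}, r.binding_b
        ),
        Reaction(
            "unbind_Pb_dimer_from_Dc", {"ADcb": 1}, {"Pb": 2, "Dc": 1}, r.unbinding_b
        ),
    ]
    megs = [
        MolecularEquivalenceGroup("A_units", {"Pa": 1, "ADca": 2}, ba),
        MolecularEquivalenceGroup("B_units", {"Pb": 1, "ADcb": 2}, bb),
        MolecularEquivalenceGroup("C_units", {"Pc": 1}, bc),
    ]
    gene_sites = [("Da",), ("Db",), ("Dc", "ADca", "ADcb")]
    network = ReactionNetwork(species, reactions, megs, gene_sites)
    initial = InitialCondition((0, 0, 0, 1, 1, 1, 0, 0))
    return network, initial


def birth_death_preset(
    k: float = 1.0, gamma: float = 1.0, buffer: int = 30
) -> tuple[ReactionNetwork, InitialCondition]:
    """Single-species birth-death process (0 -> P at rate k, P -> 0 at rate
    gamma per copy) with copy numbers truncated at ``buffer``.

    Its stationary law is the Poisson(k/gamma) distribution truncated to
    0..buffer — the analytic benchmark for the propagator.
    """
    species = [SpeciesDescriptor("P", ROLE_PROTEIN, buffer)]
    reactions = [
        Reaction("birth", {}, {"P": 1}, k),
        Reaction("death", {"P": 1}, {}, gamma),
    ]
    megs = [MolecularEquivalenceGroup("P_units", {"P": 1}, buffer)]
    network = ReactionNetwork(species, reactions, megs, [])
    return network, InitialCondition((0,))


def truncated_poisson(lam: float, buffer: int) -> np.ndarray:
    """Stationary law of the truncated birth-death process: Poisson(lam)
    renormalized on 0..buffer."""
    x = np.arange(buffer + 1)
    log_p = x * math.log(lam) - lam - np.array(
        [math.lgamma(v + 1) for v in x]
    )
    p = np.exp(log_p)
    return p / p.sum()


PRESETS = {
    "toggle": toggle_switch_preset,
    "cascade": cascade_preset,
    "birthdeath": birth_death_preset,
}
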