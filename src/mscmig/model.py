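"""Core domain types for the MSC-M (isolation-with-migration) model.

Parameters of the model are Theta = {tau, theta, M}:

* ``tau``   -- species divergence times, expected mutations per site;
* ``theta`` -- mutation-scaled population sizes (a pair of sequences in a
  population of size theta coalesces at rate 2/theta);
* ``M``     -- directed population migration rates, M_sj = N_j m_sj, the
  expected number of migrants from species s into species j per generation
  (defined forward in time).  Traced backward in time, a lineage currently
  in population j jumps into s at rate 4 M_sj / theta_j.

A gene tree at a locus carries its full migration history: an ordered list
of lineage population-switch events in addition to the topology and
coalescent times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .species import SpeciesTree

__all__ = [
    "MigrationSpec",
    "ParamSet",
    "PriorSpec",
    "GeneTree",
    "MigrationEvent",
    "Locus",
    "validate_model",
    "active_migration_entries",
    "sample_prior",
    "log_prior",
    "gamma_logpdf",
]


# ---------------------------------------------------------------------------
# migration structure

@dataclass(frozen=True)
class MigrationEvent:
    """One lineage population switch.

    ``source -> dest`` is the forward-time direction of the migrant: traced
    backward in time the lineage resided in ``dest`` below ``time`` and
    jumps into ``source`` at ``time``.
    """

    time: float
    node: int  # child node of the gene-tree edge carrying the event
    source: int  # species-tree population index (forward-time origin)
    dest: int  # species-tree population index (forward-time destination)


class MigrationSpec:
    """The set of directed migration connections of an MSC-M model.

    Only the structure (which ordered pairs of populations may exchange
    migrants) lives here; the rate values are part of :class:`ParamSet`.
    An entry (s, j) is *active* exactly while both populations are extant;
    its activity window therefore depends on the current ``tau``.
    """

    def __init__(self, stree: SpeciesTree, pairs: list[tuple[str, str]]):
        self.stree = stree
        self.pairs = [(s, j) for (s, j) in pairs]
        self.source = np.array([stree.node(s) for s, _ in pairs], dtype=np.int64)
        self.dest = np.array([stree.node(j) for _, j in pairs], dtype=np.int64)
        for k, (s, j) in enumerate(zip(self.source, self.dest)):
            if s == j:
                raise ValueError(f"self-migration entry {self.pairs[k]}")
        seen = set()
        for p in self.pairs:
            if p in seen:
                raise ValueError(f"duplicate migration entry {p}")
            seen.add(p)
        # entries into each destination, used by simulators/densities
        self.into: list[np.ndarray] = [
            np.where(self.dest == j)[0] for j in range(stree.n_nodes)
        ]
        self.pair_index: dict[tuple[int, int], int] = {
            (int(s), int(j)): k
            for k, (s, j) in enumerate(zip(self.source, self.dest))
        }

    @property
    def n_entries(self) -> int:
        return len(self.pairs)

    def index(self, s_label: str, j_label: str) -> int:
        return self.pairs.index((s_label, j_label))

    def windows(self, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Activity window [a0, a1) of every entry under the given tau."""
        a0 = np.empty(self.n_entries)
        a1 = np.empty(self.n_entries)
        for k in range(self.n_entries):
            s0, s1 = self.stree.lifespan(int(self.source[k]), tau)
            d0, d1 = self.stree.lifespan(int(self.dest[k]), tau)
            a0[k] = max(s0, d0)
            a1[k] = min(s1, d1)
        return a0, a1

    def active(self, tau: np.ndarray) -> np.ndarray:
        a0, a1 = self.windows(tau)
        return a0 < a1


@dataclass
class ParamSet:
    """Joint parameter vector Theta = {tau, theta, M}.

    ``tau`` and ``theta`` are full-length per-node arrays (tips have
    tau = 0); ``M`` is aligned with the entries of a :class:`MigrationSpec`.
    """

    tau: np.ndarray
    theta: np.ndarray
    M: np.ndarray

    def copy(self) -> "ParamSet":
        return ParamSet(self.tau.copy(), self.theta.copy(), self.M.copy())


@dataclass(frozen=True)
class PriorSpec:
    """Gamma priors, parameterized by (shape alpha, rate beta), mean alpha/beta.

    The root age carries the gamma prior ``tau_root``; the remaining node
    ages are uniform order statistics on (0, tau_root) subject to the tree's
    ancestor-descendant constraints.  Every theta shares one gamma prior and
    every migration rate another.
    """

    theta_shape: float = 2.0
    theta_rate: float = 100.0
    tau_shape: float = 2.0
    tau_rate: float = 100.0
    mig_shape: float = 2.0
    mig_rate: float = 10.0

    def __post_init__(self):
        for v in (self.theta_shape, self.theta_rate, self.tau_shape,
                  self.tau_rate, self.mig_shape, self.mig_rate):
            if not v > 0:
                raise ValueError("gamma shapes and rates must be positive")


def gamma_logpdf(x: float, shape: float, rate: float) -> float:
    """log Gamma(x | shape, rate); -inf for x <= 0."""
    if x <= 0.0:
        return -math.inf
    return (
        shape * math.log(rate)
        - math.lgamma(shape)
        + (shape - 1.0) * math.log(x)
        - rate * x
    )


# ---------------------------------------------------------------------------
# gene trees


class GeneTree:
    """A per-locus genealogy with an explicit migration history.

    Tips are nodes ``0 .. n-1``; internal (coalescent) nodes occupy ids
    ``n .. 2n-2`` but, because topology moves rearrange the tree, the root
    is tracked via ``parent == -1`` rather than by position.  ``node_pop``
    records the population of each coalescence (for tips, the sampled
    species); between recorded migration events a lineage's population
    follows the species tree passively (when its population ends at a
    divergence, the lineage belongs to the ancestral population).

    Migration events are stored per edge, keyed by the child node of the
    edge, sorted by time.  Each event is a ``[time, source, dest]`` triple
    with the forward-time convention of :class:`MigrationEvent`.
    """

    __slots__ = ("n_tips", "labels", "time", "children", "parent",
                 "node_pop", "edge_events", "root")

    def __init__(self, n_tips: int, labels: list[str], tip_species: np.ndarray):
        n_nodes = 2 * n_tips - 1
        self.n_tips = n_tips
        self.labels = labels
        self.time = np.zeros(n_nodes)
        self.children = np.full((n_nodes, 2), -1, dtype=np.int64)
        self.parent = np.full(n_nodes, -1, dtype=np.int64)
        self.node_pop = np.full(n_nodes, -1, dtype=np.int64)
        self.node_pop[:n_tips] = tip_species
        self.edge_events: list[list[list[float]]] = [[] for _ in range(n_nodes)]
        self.root = -1

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def tip_species(self) -> np.ndarray:
        return self.node_pop[: self.n_tips]

    def copy(self) -> "GeneTree":
        g = GeneTree.__new__(GeneTree)
        g.n_tips = self.n_tips
        g.labels = self.labels
        g.time = self.time.copy()
        g.children = self.children.copy()
        g.parent = self.parent.copy()
        g.node_pop = self.node_pop.copy()
        g.edge_events = [[ev.copy() for ev in lst] for lst in self.edge_events]
        g.root = self.root
        return g

    # -- queries -----------------------------------------------------------

    def migration_events(self) -> list[MigrationEvent]:
        out = []
        for c, lst in enumerate(self.edge_events):
            for t, s, j in lst:
                out.append(MigrationEvent(t, c, int(s), int(j)))
        out.sort(key=lambda e: e.time)
        return out

    @property
    def n_migrations(self) -> int:
        return sum(map(len, self.edge_events))

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            if self.children[nd, 0] >= 0:
                stack.append(int(self.children[nd, 0]))
                stack.append(int(self.children[nd, 1]))
        order.reverse()
        return order

    def pop_exiting(self, c: int) -> int:
        """Population of edge (c -> parent) just below the parent node,
        before passive species-tree remapping."""
        lst = self.edge_events[c]
        return int(lst[-1][1]) if lst else int(self.node_pop[c])

    def pop_at(self, c: int, t: float, stree: SpeciesTree, tau: np.ndarray) -> int:
        """Population of the lineage on edge (c -> parent) at time t."""
        pop = int(self.node_pop[c])
        for te, s, j in self.edge_events[c]:
            if te <= t:
                pop = int(s)
            else:
                break
        return stree.ancestor_at(pop, t, tau)

    # -- invariant checking ------------------------------------------------

    def validate(self, stree: SpeciesTree, tau: np.ndarray,
                 mig: MigrationSpec | None = None) -> list[str]:
        """Full consistency check; empty list iff the genealogy is valid."""
        problems: list[str] = []
        n = self.n_tips
        if self.root < 0 or self.parent[self.root] != -1:
            return ["root not set"]
        a0 = a1 = None
        if mig is not None:
            a0, a1 = mig.windows(tau)
            widx = {(int(mig.source[k]), int(mig.dest[k])): k
                    for k in range(mig.n_entries)}
        seen = 0
        for c in range(self.n_nodes):
            p = int(self.parent[c])
            if p == -1:
                if c != self.root:
                    problems.append(f"node {c} detached")
                continue
            seen += 1
            t_lo, t_hi = float(self.time[c]), float(self.time[p])
            if not t_lo < t_hi:
                problems.append(f"edge {c}->{p}: child time {t_lo} >= parent {t_hi}")
                continue
            pop = int(self.node_pop[c])
            t_prev = t_lo
            for te, s, j in self.edge_events[c]:
                s, j = int(s), int(j)
                if not (t_prev <= te < t_hi):
                    problems.append(f"edge {c}: event at {te} out of order")
                cur = stree.ancestor_at(pop, te, tau)
                if cur != j:
                    problems.append(
                        f"edge {c}: event at {te} leaves pop "
                        f"{stree.labels[j]} but lineage is in {stree.labels[cur]}"
                    )
                if mig is not None:
                    k = widx.get((s, j))
                    if k is None:
                        problems.append(
                            f"edge {c}: event {stree.labels[s]}->{stree.labels[j]} "
                            "has no migration entry"
                        )
                    elif not (a0[k] <= te < a1[k]):
                        problems.append(
                            f"edge {c}: event at {te} outside activity window "
                            f"of {stree.labels[s]}->{stree.labels[j]}"
                        )
                lo, hi = stree.lifespan(s, tau)
                if not (lo <= te < hi):
                    problems.append(f"edge {c}: event at {te} outside lifespan of "
                                    f"{stree.labels[s]}")
                pop = s
                t_prev = te
            arrive = stree.ancestor_at(pop, t_hi, tau)
            if arrive != int(self.node_pop[p]):
                problems.append(
                    f"edge {c}: arrives at node {p} in pop {stree.labels[arrive]} "
                    f"but node is in {stree.labels[int(self.node_pop[p])]}"
                )
        for i in range(self.n_nodes):
            if self.children[i, 0] >= 0:
                pop = int(self.node_pop[i])
                lo, hi = stree.lifespan(pop, tau)
                if not (lo <= self.time[i] < hi):
                    problems.append(
                        f"coalescence {i} at {self.time[i]} outside lifespan of "
                        f"{stree.labels[pop]}"
                    )
        if seen != self.n_nodes - 1:
            problems.append("tree is not connected")
        return problems


@dataclass
class Locus:
    """One sequence alignment plus its heredity scalar.

    ``seqs`` holds nucleotide codes 0..3 (T, C, A, G) with 4 for
    missing/ambiguous sites.  ``h`` is the heredity/ploidy multiplier of
    theta (1 autosomal, 3/4 X-linked, 1/4 Y or mitochondrial).
    """

    names: list[str]
    seqs: np.ndarray  # (n_seq, n_sites) int8
    h: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("heredity scalar must be positive")

    @property
    def n_sites(self) -> int:
        return int(self.seqs.shape[1])


# ---------------------------------------------------------------------------
# model-level operations


def active_migration_entries(stree: SpeciesTree, mig: MigrationSpec,
                             tau: np.ndarray) -> set[tuple[str, str]]:
    """The migration entries whose populations' lifespans overlap under tau."""
    act = mig.active(tau)
    return {mig.pairs[k] for k in range(mig.n_entries) if act[k]}


def validate_model(stree: SpeciesTree, mig: MigrationSpec,
                   params: ParamSet) -> list[str]:
    """Diagnostic check of every model invariant; empty list iff clean."""
    problems = stree.validate_tau(params.tau)
    for i, th in enumerate(params.theta):
        if not th > 0:
            problems.append(f"population {stree.labels[i]} needs theta > 0")
    for k in range(mig.n_entries):
        if params.M[k] < 0:
            problems.append(f"migration entry {mig.pairs[k]} has negative rate")
    act = mig.active(params.tau)
    for k in range(mig.n_entries):
        if not act[k]:
            s, j = mig.pairs[k]
            problems.append(
                f"migration entry {s}->{j} inactive: populations are never "
                "contemporary under the current tau"
            )
    return problems


def _order_poset(stree: SpeciesTree) -> tuple[list[int], dict[int, int]]:
    """Non-root internal nodes and subtree sizes in the internal-node poset."""
    root = stree.root
    nodes = [i for i in stree.internal_nodes if i != root]
    size: dict[int, int] = {i: 1 for i in nodes}
    # internal ids are in postorder, so children are visited before parents
    for i in nodes:
        p = int(stree.parent[i])
        if p != root:
            size[p] += size[i]
    return nodes, size


def log_order_constant(stree: SpeciesTree) -> float:
    """log of the normalising constant of the uniform order-statistics prior
    on non-root divergence times, from the hook-length formula."""
    nodes, size = _order_poset(stree)
    return float(sum(math.log(size[i]) for i in nodes))


def log_prior(params: ParamSet, priors: PriorSpec, stree: SpeciesTree,
              mig: MigrationSpec) -> float:
    """Joint log prior density p(Theta).

    Sum of gamma log densities for every theta, the root age and every
    migration rate (inactive entries keep their gamma term: it doubles as
    the pseudo-prior of the composite-space sampler), plus the uniform
    order-statistics term for non-root divergence times.
    """
    lp = 0.0
    for i in range(stree.n_nodes):
        lp += gamma_logpdf(float(params.theta[i]), priors.theta_shape,
                           priors.theta_rate)
    root = stree.root
    tau_r = float(params.tau[root])
    lp += gamma_logpdf(tau_r, priors.tau_shape, priors.tau_rate)
    s = stree.n_tips - 2  # number of non-root internal nodes
    if s > 0:
        if stree.validate_tau(params.tau):
            return -math.inf
        lp += log_order_constant(stree) - s * math.log(tau_r)
    for k in range(mig.n_entries):
        m = float(params.M[k])
        if m < 0:
            return -math.inf
        if m == 0.0:
            # degenerate no-migration test case: point mass, no density term
            continue
        lp += gamma_logpdf(m, priors.mig_shape, priors.mig_rate)
    return lp


def sample_prior(priors: PriorSpec, stree: SpeciesTree, mig: MigrationSpec,
                 rng: np.random.Generator) -> ParamSet:
    """Draw Theta from the joint prior."""
    n = stree.n_nodes
    theta = rng.gamma(priors.theta_shape, 1.0 / priors.theta_rate, size=n)
    tau = np.zeros(n)
    root = stree.root
    tau[root] = rng.gamma(priors.tau_shape, 1.0 / priors.tau_rate)
    inner = [i for i in stree.internal_nodes if i != root]
    if inner:
        while True:  # rejection from iid uniforms; cheap for small trees
            ages = rng.uniform(0.0, tau[root], size=len(inner))
            for i, a in zip(inner, ages):
                tau[i] = a
            if not stree.validate_tau(tau):
                break
    M = rng.gamma(priors.mig_shape, 1.0 / priors.mig_rate,
                  size=mig.n_entries)
    return ParamSet(tau=tau, theta=theta, M=M)
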