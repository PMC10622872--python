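"""Exact gene-tree density under the MSC-M model.

The coalescent-with-migration is a piecewise constant-rate Poisson process:
between any two events (coalescence, migration, species divergence) the
per-population rates are constant.  The log density of a gene tree with its
migration history is therefore a sum, over populations, of

* ``log(2 / (theta_j h))`` per coalescence in population j,
* ``log(4 M_sj / (theta_j h))`` per recorded migration event whose
  forward-time destination is j (backward in time the lineage leaves j),
* minus the exposure ``n(n-1) t / (theta_j h)`` for coalescence and
  ``4 n t sum_s I_s M_sj / (theta_j h)`` for migration, accumulated over the
  time segments during which population j holds ``n`` lineages and the
  indicator ``I_s`` marks migration connections active in the segment.

``h`` is the per-locus heredity scalar.  By default it rescales theta in
the migration terms exactly as in the coalescent terms
(``scale_migration_by_h=True``); the switch is exposed because the two
conventions coincide only at h = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import GeneTree, MigrationSpec, ParamSet
from .species import SpeciesTree

__all__ = [
    "SegmentDecomposition",
    "decompose",
    "log_density_mscm",
    "log_density_from_stats",
    "locus_stats",
    "log_density_fig1b_oracle",
    "phi0",
]


# ---------------------------------------------------------------------------
# segment decomposition


@dataclass
class PopSegments:
    """Piecewise constant-rate segments of one population at one locus."""

    pop: int
    start: np.ndarray  # segment start times
    duration: np.ndarray  # t_k
    n_lineages: np.ndarray  # n_k
    active: np.ndarray  # (K, E) 0/1 indicator: entry e open during segment k


@dataclass
class SegmentDecomposition:
    """Everything Eq.-level bookkeeping needs, per population.

    ``c[j]``: coalescent events in population j; ``w[e]``: migration events
    recorded for entry e (destination-side); ``coal_exposure[j]`` is
    ``sum_k n(n-1) t`` and ``mig_exposure[e]`` is ``sum_k n t`` restricted
    to segments where entry e is active.
    """

    segments: list[PopSegments]
    c: np.ndarray
    w: np.ndarray
    coal_exposure: np.ndarray
    mig_exposure: np.ndarray


class InconsistentGenealogy(ValueError):
    """Raised when a gene tree's population path contradicts the model."""


def _gather_events(gtree: GeneTree, stree: SpeciesTree, tau: np.ndarray,
                   mig: MigrationSpec):
    """All events sorted by time: (time, kind, payload).

    kind 0 = coalescence (payload: population), 1 = migration (payload:
    entry index), 2 = species divergence (payload: species node).  Ties are
    broken so divergences precede same-time genealogical events, matching
    the half-open [start, end) population lifespans.
    """
    ev = []
    for i in range(gtree.n_nodes):
        if gtree.children[i, 0] >= 0:
            ev.append((float(gtree.time[i]), 0, int(gtree.node_pop[i])))
    for c, lst in enumerate(gtree.edge_events):
        for t, s, j in lst:
            k = mig.pair_index.get((int(s), int(j)))
            if k is None:
                raise InconsistentGenealogy(
                    f"edge {c}: event at {t} uses migration "
                    f"{stree.labels[int(s)]}->{stree.labels[int(j)]} which is "
                    "not in the model")
            ev.append((float(t), 1, k))
    for i in stree.internal_nodes:
        ev.append((float(tau[i]), 2, int(i)))
    ev.sort(key=lambda e: (e[0], -e[1]))
    return ev


def decompose(gtree: GeneTree, stree: SpeciesTree, tau: np.ndarray,
              mig: MigrationSpec) -> SegmentDecomposition:
    """Break each population's lifespan into constant-rate segments.

    Segment boundaries for population j are exactly the coalescences in j,
    the migration events entering or leaving j, and the species divergences
    that start or end j or one of its migration partners' windows.
    """
    P, E = stree.n_nodes, mig.n_entries
    events = _gather_events(gtree, stree, tau, mig)
    a0, a1 = mig.windows(tau)
    src, dst = mig.source, mig.dest

    n = np.zeros(P, dtype=np.int64)
    for sp in gtree.tip_species:
        n[sp] += 1
    c = np.zeros(P)
    w = np.zeros(E)
    coal_exp = np.zeros(P)
    mig_exp = np.zeros(E)

    # per-population segment records
    seg_start: list[list[float]] = [[] for _ in range(P)]
    seg_dur: list[list[float]] = [[] for _ in range(P)]
    seg_n: list[list[int]] = [[] for _ in range(P)]
    seg_act: list[list[np.ndarray]] = [[] for _ in range(P)]
    alive = np.zeros(P, dtype=bool)
    alive[: stree.n_tips] = True

    t_prev = 0.0
    total = int(n.sum())
    for t, kind, a in events:
        if total <= 1:
            break  # the process stops at the MRCA; later history
            # (a single lineage wandering between populations) is
            # marginalized out exactly and carries no density terms
        dt = t - t_prev
        if dt > 0:
            act = (a0 <= t_prev) & (t <= a1)
            for j in range(P):
                if alive[j]:
                    seg_start[j].append(t_prev)
                    seg_dur[j].append(dt)
                    seg_n[j].append(int(n[j]))
                    row = act & (dst == j)
                    seg_act[j].append(row.astype(np.int8))
                    coal_exp[j] += n[j] * (n[j] - 1) * dt
            mig_exp += np.where(act, n[dst] * dt, 0.0)
        if kind == 0:
            if n[a] < 2:
                raise InconsistentGenealogy(
                    f"coalescence at {t} in {stree.labels[a]} with "
                    f"{n[a]} lineage(s) present")
            c[a] += 1
            n[a] -= 1
            total -= 1
        elif kind == 1:
            j, s = int(dst[a]), int(src[a])
            if n[j] < 1:
                raise InconsistentGenealogy(
                    f"migration at {t} out of empty population "
                    f"{stree.labels[j]}")
            if not (a0[a] <= t < a1[a]):
                raise InconsistentGenealogy(
                    f"migration at {t} outside the window of "
                    f"{mig.pairs[a]}")
            w[a] += 1
            n[j] -= 1
            n[s] += 1
        else:  # species divergence: daughters merge into the ancestor
            c1, c2 = stree.children[a]
            n[a] += n[c1] + n[c2]
            n[c1] = n[c2] = 0
            alive[a] = True
            alive[c1] = alive[c2] = False
        t_prev = t

    segments = []
    for j in range(P):
        start, dur, nl, act = seg_start[j], seg_dur[j], seg_n[j], seg_act[j]
        # merge consecutive segments split by events elsewhere in the tree:
        # boundaries of population j are only the events that touch j
        ms, md, mn, ma = [], [], [], []
        for k in range(len(start)):
            if (ms and mn[-1] == nl[k] and np.array_equal(ma[-1], act[k])
                    and abs(ms[-1] + md[-1] - start[k]) < 1e-12):
                md[-1] += dur[k]
            else:
                ms.append(start[k])
                md.append(dur[k])
                mn.append(nl[k])
                ma.append(act[k])
        segments.append(PopSegments(
            pop=j,
            start=np.array(ms),
            duration=np.array(md),
            n_lineages=np.array(mn, dtype=np.int64),
            active=(np.vstack(ma) if ma else np.zeros((0, E), dtype=np.int8)),
        ))
    return SegmentDecomposition(segments=segments, c=c, w=w,
                                coal_exposure=coal_exp, mig_exposure=mig_exp)


# ---------------------------------------------------------------------------
# densities


def log_density_from_stats(c: np.ndarray, coal_exp: np.ndarray,
                           w: np.ndarray, mig_exp: np.ndarray,
                           theta: np.ndarray, M: np.ndarray,
                           mig: MigrationSpec, h: float = 1.0,
                           scale_migration_by_h: bool = True) -> float:
    """MSC-M log density given the sufficient statistics of one locus.

    The statistics (coalescence counts ``c``, migration counts ``w`` and
    the two exposures) depend only on the genealogy and tau, not on theta
    or M, which makes parameter updates in the sampler O(1) per locus.
    """
    th = theta * h
    thm = th if scale_migration_by_h else theta
    lp = float(np.sum(c * np.log(2.0 / th) - coal_exp / th))
    if mig.n_entries:
        dst_th = thm[mig.dest]
        rate = 4.0 * M / dst_th
        with np.errstate(divide="ignore"):
            ev = np.where(w > 0, w * np.log(rate), 0.0)
        if np.any((w > 0) & (rate <= 0.0)):
            return -math.inf
        lp += float(np.sum(ev) - np.sum(rate * mig_exp))
    return lp


def log_density_mscm(gtree: GeneTree, params: ParamSet, mig: MigrationSpec,
                     h: float = 1.0, *,
                     scale_migration_by_h: bool = True) -> float:
    """Exact log density of a gene tree (with migration history) given Theta.

    Computed from the full segment decomposition; raises
    :class:`InconsistentGenealogy` if the tree's population path is
    incompatible with the species tree or the migration model.
    """
    stree = mig.stree
    dec = decompose(gtree, stree, params.tau, mig)
    return log_density_from_stats(dec.c, dec.coal_exposure, dec.w,
                                  dec.mig_exposure, params.theta, params.M,
                                  mig, h, scale_migration_by_h)


def locus_stats(gtree: GeneTree, stree: SpeciesTree, tau: np.ndarray,
                mig: MigrationSpec):
    """Fast path to the sufficient statistics (c, coal_exp, w, mig_exp).

    Same sweep as :func:`decompose` but without materialising per-segment
    records; used inside the MCMC sampler.
    """
    from ._kernels import stats_sweep

    events = _gather_events(gtree, stree, tau, mig)
    ne = len(events)
    ev_time = np.fromiter((e[0] for e in events), dtype=np.float64, count=ne)
    ev_kind = np.fromiter((e[1] for e in events), dtype=np.int64, count=ne)
    ev_a = np.fromiter((e[2] for e in events), dtype=np.int64, count=ne)
    P, E = stree.n_nodes, mig.n_entries
    n0 = np.zeros(P, dtype=np.int64)
    for sp in gtree.tip_species:
        n0[sp] += 1
    a0, a1 = mig.windows(tau)
    c = np.zeros(P)
    coal_exp = np.zeros(P)
    w = np.zeros(E)
    mig_exp = np.zeros(E)
    ok = stats_sweep(ev_time, ev_kind, ev_a, n0, stree.children,
                     mig.source, mig.dest, a0, a1, c, coal_exp, w, mig_exp)
    if not ok:
        raise InconsistentGenealogy("gene tree inconsistent with the model")
    return c, coal_exp, w, mig_exp


# ---------------------------------------------------------------------------
# the worked six-sequence example and the lineage-transfer probability


def log_density_fig1b_oracle(stree: SpeciesTree, params: ParamSet,
                             mig: MigrationSpec,
                             t: tuple[float, float, float, float, float],
                             s: tuple[float, float],
                             h: float = 1.0) -> float:
    """Hand-transcribed density of the worked three-species example.

    The model is the tree ((A,B)S,C)R with bidirectional B<->C migration;
    the genealogy has two sequences per species, coalescences at
    t1 < t2 < t3 < t4 < t5 and a lineage that (backward in time) leaves B
    for C at s1 and returns at s2, with t1 < t2 < s1 < s2 < tauS < t3 <
    tauR < t4 < t5.  Written term by term, independently of the generic
    segment machinery, as a cross-check oracle.
    """
    t1, t2, t3, t4, t5 = t
    s1, s2 = s
    tauS = float(params.tau[stree.node("S")])
    tauR = float(params.tau[stree.node("R")])
    if not (t1 < t2 < s1 < s2 < tauS < t3 < tauR < t4 < t5):
        raise ValueError("event times violate the required ordering "
                         "t1<t2<s1<s2<tauS<t3<tauR<t4<t5")
    thA = params.theta[stree.node("A")] * h
    thB = params.theta[stree.node("B")] * h
    thC = params.theta[stree.node("C")] * h
    thS = params.theta[stree.node("S")] * h
    thR = params.theta[stree.node("R")] * h
    MBC = params.M[mig.index("B", "C")]
    MCB = params.M[mig.index("C", "B")]

    # A: one coalescence at t1 with two lineages present
    lp = math.log(2.0 / thA) - (2.0 / thA) * t1
    # B: no coalescence; one backward exit into C (forward C->B event);
    #    2 lineages on (0,s1) and (s2,tauS), 1 on (s1,s2)
    rCB = 4.0 * MCB / thB
    lp += -(2.0 / thB) * (s1 + tauS - s2)
    lp += math.log(rCB) - rCB * (2.0 * (s1 + tauS - s2) + (s2 - s1))
    # C: coalescence at t2; one backward exit into B (forward B->C event);
    #    2 lineages on (0,t2) and (s1,s2), 1 on (t2,s1) and (s2,tauS)
    rBC = 4.0 * MBC / thC
    lp += math.log(2.0 / thC) - (2.0 / thC) * (t2 + s2 - s1)
    lp += math.log(rBC) - rBC * (
        2.0 * (t2 + s2 - s1) + (s1 - t2) + (tauS - s2))
    # S: 3 lineages enter at tauS, coalesce once at t3
    lp += math.log(2.0 / thS) - (6.0 / thS) * (t3 - tauS) \
        - (2.0 / thS) * (tauR - t3)
    # R: 3 lineages enter at tauR, coalesce at t4 and t5
    lp += 2.0 * math.log(2.0 / thR) - (6.0 / thR) * (t4 - tauR) \
        - (2.0 / thR) * (t5 - t4)
    return lp


def phi0(M: float, tau_d: float, theta: float) -> float:
    """Probability that a lineage is traced into the migration source.

    For a destination population of size ``theta`` receiving migrants at
    population rate ``M`` over a divergence span ``tau_d``, a sampled
    lineage escapes backward into the source population with probability
    ``1 - exp(-4 M tau_d / theta)``.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if M < 0 or tau_d < 0:
        raise ValueError("M and tau_d must be non-negative")
    return -math.expm1(-4.0 * M * tau_d / theta)
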