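"""MCMC over parameters and gene trees with migration histories.

The sampler targets  p(Theta, G | X) ∝ p(Theta) p(G|Theta) p(X|G)^beta
(beta = 1 for the posterior; beta in (0,1) gives the power posteriors used
for marginal likelihoods; with no data the chain samples the prior, which
is the primary correctness check for every kernel).

Moves
-----
* sliding-window updates of each theta and each migration rate M;
* sliding-window updates of migration-event times on gene trees;
* per-locus gene-tree node-age updates;
* SPR regraft of a pruned lineage by re-simulating its backward path of
  migration and coalescence under the current parameters;
* species divergence-time updates by the rubber-band proposal, either
  rescaling affected migration times together with the node ages
  ("extended") or abandoning the move on any conflict ("rejection");
  the same move doubles as the composite-space (Carlin–Chib) kernel:
  rates of currently inactive migration connections stay in the state
  under their prior as pseudo-prior, so activity flips caused by tau
  changes need no dimension-matching factors;
* a mixing move rescaling every time variable jointly.

Internally each locus caches the sufficient statistics of the gene-tree
density (coalescent/migration counts and exposures); theta and M updates
are then O(loci) scalar work, and only moves that change times or topology
re-run the event sweep or the pruning likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import dens_rows, jc_pruning, stats_merge_sweep
from .likelihood import SitePatternTable
from .model import (GeneTree, Locus, MigrationSpec, ParamSet, PriorSpec,
                    log_prior)
from .simulate import simulate_gene_tree
from .species import SpeciesTree

__all__ = [
    "MCMCSettings",
    "MCMCState",
    "Trace",
    "run_mcmc",
    "hpd_interval",
    "propose_theta",
    "propose_migration_rate",
    "propose_migration_time",
    "propose_node_age",
    "propose_tau_rubberband_extended",
    "propose_tau_rejection",
    "propose_tau_composite_space",
    "propose_tau_slide",
    "init_from_distances",
    "propose_spr_migration",
    "propose_mixing",
]

_INF = math.inf


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold x into the open interval (lo, hi) by reflection."""
    if hi == _INF:
        while x < lo:
            x = 2.0 * lo - x
        return x
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


# ---------------------------------------------------------------------------
# settings


@dataclass
class MCMCSettings:
    """Chain-length, proposal and schedule configuration."""

    n_iter: int = 2000
    burnin: int = 500
    thin: int = 1
    beta: float = 1.0  # likelihood power (thermodynamic integration)
    tau_kernel: str = "extended"  # or "rejection"
    # per-iteration counts of per-locus gene-tree moves
    ages_per_locus: int = 2
    sprs_per_locus: int = 1
    migtimes_per_locus: int = 2
    # extra cheap divergence-time slides (no gene-tree remapping) per
    # iteration: they sample tau's conditional given the genealogies and
    # speed up the slow tau/theta ridge without likelihood recomputation
    tau_slides: int = 3
    tune: bool = True
    tune_interval: int = 100
    target_accept: float = 0.30
    mix_theta: bool = False
    debug_check_every: int = 0  # 0 = never; else assert caches every k iters

    def __post_init__(self):
        if self.tau_kernel not in ("extended", "rejection"):
            raise ValueError("tau_kernel must be 'extended' or 'rejection'")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if self.burnin >= self.n_iter:
            raise ValueError("burnin must be smaller than n_iter")


# ---------------------------------------------------------------------------
# state


class MCMCState:
    """Current parameters, per-locus gene trees, and all density caches."""

    def __init__(self, stree: SpeciesTree, mig: MigrationSpec,
                 priors: PriorSpec, params: ParamSet,
                 gtrees: list[GeneTree], loci: list[Locus] | None,
                 beta: float = 1.0):
        self.stree = stree
        self.mig = mig
        self.priors = priors
        self.params = params
        self.gtrees = gtrees
        self.loci = loci
        self.beta = beta
        self.L = len(gtrees)
        self.h = np.array([loc.h for loc in loci] if loci is not None
                          else [1.0] * self.L)
        P, E = stree.n_nodes, mig.n_entries
        self.C = np.zeros((self.L, P))
        self.A = np.zeros((self.L, P))
        self.W = np.zeros((self.L, E))
        self.B = np.zeros((self.L, E))
        self.dens_loc = np.zeros(self.L)
        self.loglik = np.zeros(self.L)
        self.use_likelihood = loci is not None

        self.tables: list[SitePatternTable] = []
        self.tipcodes: list[np.ndarray] = []
        if loci is not None:
            for g, loc in zip(gtrees, loci):
                tab = SitePatternTable.from_locus(loc)
                self.tables.append(tab)
                self.tipcodes.append(tab.reorder(g.labels))
        self._post: list[np.ndarray | None] = [None] * self.L
        self._gev: list[tuple | None] = [None] * self.L
        self.n0 = np.zeros((self.L, P), dtype=np.int64)
        for i, g in enumerate(gtrees):
            for sp in g.tip_species:
                self.n0[i, sp] += 1

        self._div_nodes = np.array(sorted(stree.internal_nodes,
                                          key=lambda i: params.tau[i]),
                                   dtype=np.int64)
        self._refresh_tau_cache()
        for i in range(self.L):
            self.refresh_locus(i)
        self.logpri = log_prior(params, priors, stree, mig)

    # -- caches ------------------------------------------------------------

    def _refresh_tau_cache(self) -> None:
        tau = self.params.tau
        self._div_nodes = self._div_nodes[np.argsort(tau[self._div_nodes],
                                                     kind="stable")]
        self._div_t = tau[self._div_nodes].astype(np.float64)
        self.a0, self.a1 = self.mig.windows(tau)

    def _locus_gev(self, i: int):
        """Gene-only events (coalescences + migrations) of locus i.

        Returned unsorted; the sweep kernel sorts in place, so after the
        first use the cached arrays stay sorted.
        """
        cached = self._gev[i]
        if cached is not None:
            return cached
        g = self.gtrees[i]
        ne = (g.n_tips - 1) + g.n_migrations
        times = np.empty(ne)
        kinds = np.empty(ne, dtype=np.int64)
        payload = np.empty(ne, dtype=np.int64)
        pos = 0
        gtime = g.time
        gpop = g.node_pop
        for v in range(g.n_nodes):
            if g.children[v, 0] >= 0:
                times[pos] = gtime[v]
                kinds[pos] = 0
                payload[pos] = gpop[v]
                pos += 1
        pair_index = self.mig.pair_index
        for lst in g.edge_events:
            for t, s, j in lst:
                times[pos] = t
                kinds[pos] = 1
                payload[pos] = pair_index[(int(s), int(j))]
                pos += 1
        out = (times, kinds, payload)
        self._gev[i] = out
        return out

    def locus_stats_rows(self, i: int):
        """(c, coal_exp, w, mig_exp) for locus i, or None if inconsistent."""
        gt, gk, ga = self._locus_gev(i)
        P, E = self.stree.n_nodes, self.mig.n_entries
        c = np.zeros(P)
        ce = np.zeros(P)
        w = np.zeros(E)
        me = np.zeros(E)
        ok = stats_merge_sweep(gt, gk, ga, self._div_t, self._div_nodes,
                               self.n0[i], self.stree.children,
                               self.mig.source, self.mig.dest,
                               self.a0, self.a1, c, ce, w, me)
        if not ok:
            return None
        return c, ce, w, me

    def _dens_from_rows(self, rows, h: float,
                        params: ParamSet | None = None) -> float:
        c, ce, w, me = rows
        p = params if params is not None else self.params
        return float(dens_rows(c, ce, w, me, p.theta, p.M, self.mig.dest, h))

    def density_vector(self, params: ParamSet | None = None) -> np.ndarray:
        """Per-locus log gene-tree densities from the cached statistics."""
        p = params if params is not None else self.params
        th = self.h[:, None] * p.theta[None, :]
        v = np.sum(self.C * np.log(2.0 / th) - self.A / th, axis=1)
        if self.mig.n_entries:
            thd = self.h[:, None] * p.theta[self.mig.dest][None, :]
            rate = 4.0 * p.M[None, :] / thd
            with np.errstate(divide="ignore", invalid="ignore"):
                lw = np.where(self.W > 0,
                              self.W * np.log(np.where(rate > 0, rate, 1.0)),
                              0.0)
            lw = np.where((self.W > 0) & (rate <= 0.0), -_INF, lw)
            v = v + np.sum(lw, axis=1) - np.sum(rate * self.B, axis=1)
        return v

    def locus_loglik(self, i: int) -> float:
        g = self.gtrees[i]
        post = self._post[i]
        if post is None:
            post = np.array([nd for nd in g.postorder()
                             if g.children[nd, 0] >= 0], dtype=np.int64)
            self._post[i] = post
        val = jc_pruning(post, g.children, g.time, self.tipcodes[i],
                         self.tables[i].counts)
        if math.isnan(val):
            raise ValueError(f"negative branch length at locus {i}")
        return float(val)

    def refresh_locus(self, i: int) -> None:
        """Recompute stats, density and likelihood caches of locus i."""
        self._gev[i] = None
        self._post[i] = None
        rows = self.locus_stats_rows(i)
        if rows is None:
            raise ValueError(f"locus {i}: gene tree inconsistent with model")
        self.C[i], self.A[i], self.W[i], self.B[i] = rows
        self.dens_loc[i] = self._dens_from_rows(rows, self.h[i])
        if self.use_likelihood:
            self.loglik[i] = self.locus_loglik(i)

    # -- totals ------------------------------------------------------------

    @property
    def log_density(self) -> float:
        return float(self.dens_loc.sum())

    @property
    def log_posterior(self) -> float:
        return self.logpri + self.log_density + self.beta * float(
            self.loglik.sum())

    def assert_consistent(self, tol: float = 1e-8) -> None:
        """Debug check: every cache equals a from-scratch recomputation."""
        dens = self.density_vector()
        if not np.allclose(dens, self.dens_loc, atol=tol, rtol=0):
            raise AssertionError("density cache inconsistent")
        for i in range(self.L):
            self._gev[i] = None
            rows = self.locus_stats_rows(i)
            assert rows is not None, f"locus {i} invalid"
            for cached, fresh in zip((self.C[i], self.A[i], self.W[i],
                                      self.B[i]), rows):
                if not np.allclose(cached, fresh, atol=tol, rtol=0):
                    raise AssertionError(f"stats cache inconsistent, locus {i}")
            if self.use_likelihood:
                self._post[i] = None
                if abs(self.locus_loglik(i) - self.loglik[i]) > tol:
                    raise AssertionError(f"likelihood cache off, locus {i}")
            probs = self.gtrees[i].validate(self.stree, self.params.tau,
                                            self.mig)
            if probs:
                raise AssertionError(f"locus {i} invalid: {probs[0]}")
        lp = log_prior(self.params, self.priors, self.stree, self.mig)
        if abs(lp - self.logpri) > tol:
            raise AssertionError("prior cache inconsistent")


def _initial_params(stree: SpeciesTree, priors: PriorSpec,
                    mig: MigrationSpec) -> ParamSet:
    """Start the chain at the prior means (ordered non-root ages)."""
    P = stree.n_nodes
    theta = np.full(P, priors.theta_shape / priors.theta_rate)
    tau = np.zeros(P)
    root = stree.root
    tau_r = priors.tau_shape / priors.tau_rate
    niv = np.zeros(P, dtype=np.int64)
    for i in stree.internal_nodes:
        niv[i] = 1 + niv[stree.children[i, 0]] + niv[stree.children[i, 1]]
    for i in stree.internal_nodes:
        tau[i] = tau_r * niv[i] / niv[root]
    M = np.full(mig.n_entries, priors.mig_shape / priors.mig_rate)
    return ParamSet(tau=tau, theta=theta, M=M)


def init_from_distances(loci: list[Locus], stree: SpeciesTree,
                        mig: MigrationSpec, priors: PriorSpec) -> ParamSet:
    """Moment-based starting point from average JC distances.

    Within-species divergence estimates theta for the tips; half the
    between-clade divergence (minus the average within-species theta)
    estimates each node age.  Crude, but it starts the chain inside the
    high-likelihood region, which matters because the root age relaxes
    slowly.
    """
    S = stree.n_tips
    dsum = np.zeros((S, S))
    dcnt = np.zeros((S, S))
    for loc in loci:
        sp = [stree.node(nm.split("^")[0]) for nm in loc.names]
        seqs = loc.seqs
        for i in range(len(sp)):
            for j in range(i + 1, len(sp)):
                p = float(np.mean(seqs[i] != seqs[j]))
                p = min(p, 0.70)
                d = -0.75 * math.log1p(-4.0 * p / 3.0)
                a, b = sp[i], sp[j]
                dsum[a, b] += d
                dsum[b, a] += d
                dcnt[a, b] += 1
                dcnt[b, a] += 1
    with np.errstate(invalid="ignore"):
        dbar = np.where(dcnt > 0, dsum / np.maximum(dcnt, 1), np.nan)
    prior_theta = priors.theta_shape / priors.theta_rate
    theta = np.full(stree.n_nodes, prior_theta)
    for a in range(S):
        if dcnt[a, a] > 0:
            theta[a] = max(dbar[a, a], 1e-6)
    theta_bar = float(np.mean(theta[:S]))
    theta[S:] = theta_bar
    # clade memberships, then node ages from between-clade divergence;
    # gene flow only lowers apparent divergence, so the largest spanning
    # species-pair mean is the least contaminated estimate of the age
    below: list[list[int]] = [[i] for i in range(S)] + \
        [[] for _ in range(S, stree.n_nodes)]
    tau = np.zeros(stree.n_nodes)
    prior_tau = _initial_params(stree, priors, mig).tau
    for v in stree.internal_nodes:
        kids = [int(stree.children[v, 0]), int(stree.children[v, 1])]
        below[v] = below[kids[0]] + below[kids[1]]
        ds = [dbar[a, b] for a in below[kids[0]] for b in below[kids[1]]
              if dcnt[a, b] > 0]
        est = 0.5 * (float(np.max(ds)) - theta_bar) if ds else 0.0
        # gene flow can only shrink the distance estimate, so never start
        # below the prior-implied age
        floor = 1.05 * max(tau[kids[0]], tau[kids[1]])
        tau[v] = max(est, float(prior_tau[v]), floor, 1e-6)
    M = np.full(mig.n_entries, priors.mig_shape / priors.mig_rate)
    return ParamSet(tau=tau, theta=theta, M=M)


def init_state(stree: SpeciesTree, mig: MigrationSpec, priors: PriorSpec,
               loci: list[Locus] | None, settings: MCMCSettings,
               rng: np.random.Generator,
               params0: ParamSet | None = None,
               sample_config=None) -> MCMCState:
    """Build a valid starting state.

    Gene trees are simulated from the starting parameters, which yields a
    consistent genealogy-with-migration state by construction.  With data,
    tips are matched to the sequence names of each locus (bpp-style
    ``species^individual`` labels); without data a
    :class:`~mscmig.simulate.SampleConfig` describes the sampling design.
    """
    if params0 is not None:
        params = params0.copy()
    elif loci is not None:
        params = init_from_distances(loci, stree, mig, priors)
    else:
        params = _initial_params(stree, priors, mig)
    gtrees = []
    if loci is not None:
        for loc in loci:
            tips = []
            for name in loc.names:
                sp = name.split("^")[0]
                tips.append((name, stree.node(sp)))
            g = simulate_gene_tree(stree, mig, params, tips, rng, h=loc.h)
            gtrees.append(g)
    else:
        if sample_config is None:
            raise ValueError("sample_config required for prior-only chains")
        counts = sample_config.counts(stree)
        for _ in range(sample_config.n_loci):
            gtrees.append(simulate_gene_tree(stree, mig, params, counts, rng,
                                             h=sample_config.h))
    return MCMCState(stree, mig, priors, params, gtrees, loci,
                     beta=settings.beta)


# ---------------------------------------------------------------------------
# parameter moves


def propose_theta(state: MCMCState, pop: int, step: float,
                  rng: np.random.Generator) -> bool:
    """Sliding-window update of theta for one population.

    The phylogenetic likelihood does not involve theta, so only the prior
    and the gene-tree density enter the ratio.
    """
    p = state.params
    old = float(p.theta[pop])
    new = _reflect(old + step * (rng.random() - 0.5), 0.0, _INF)
    if new == 0.0:
        return False
    newp = ParamSet(p.tau, p.theta.copy(), p.M)
    newp.theta[pop] = new
    dens_new = state.density_vector(newp)
    lp_new = log_prior(newp, state.priors, state.stree, state.mig)
    delta = lp_new - state.logpri + float(dens_new.sum()) - state.log_density
    if math.log(rng.random()) < delta:
        p.theta[pop] = new
        state.dens_loc = dens_new
        state.logpri = lp_new
        return True
    return False


def propose_migration_rate(state: MCMCState, entry: int, step: float,
                           rng: np.random.Generator) -> bool:
    """Sliding-window update of one migration rate M_sj.

    For an inactive entry (composite space) the density terms vanish and
    the move samples the prior, i.e. the pseudo-prior of the Carlin–Chib
    construction.
    """
    p = state.params
    old = float(p.M[entry])
    new = _reflect(old + step * (rng.random() - 0.5), 0.0, _INF)
    if new == 0.0:
        return False
    newp = ParamSet(p.tau, p.theta, p.M.copy())
    newp.M[entry] = new
    dens_new = state.density_vector(newp)
    lp_new = log_prior(newp, state.priors, state.stree, state.mig)
    delta = lp_new - state.logpri + float(dens_new.sum()) - state.log_density
    if math.log(rng.random()) < delta:
        p.M[entry] = new
        state.dens_loc = dens_new
        state.logpri = lp_new
        return True
    return False


# ---------------------------------------------------------------------------
# per-locus gene-tree moves


def propose_migration_time(state: MCMCState, i: int, step: float,
                           rng: np.random.Generator) -> bool:
    """Slide one migration event's time within its feasible interval.

    The interval is bounded by the neighbouring events on the same edge
    (or the edge's endpoints) and by the activity window of the entry;
    coalescent times are untouched, so the likelihood is unchanged.
    """
    g = state.gtrees[i]
    total = g.n_migrations
    if not total:
        return False
    pick = int(rng.integers(total))
    c = -1
    for c, lst in enumerate(g.edge_events):
        if pick < len(lst):
            break
        pick -= len(lst)
    lst = g.edge_events[c]
    idx = pick
    t_old, s, j = lst[idx]
    k = state.mig.pair_index[(int(s), int(j))]
    lo = lst[idx - 1][0] if idx > 0 else float(g.time[c])
    hi = (lst[idx + 1][0] if idx + 1 < len(lst)
          else float(g.time[int(g.parent[c])]))
    lo = max(lo, float(state.a0[k]))
    hi = min(hi, float(state.a1[k]))
    if not lo < hi:
        return False
    width = hi - lo
    t_new = _reflect(t_old + step * width * (rng.random() - 0.5), lo, hi)
    lst[idx][0] = t_new
    gidx = _gev_update(state, i, 1, t_old, k, t_new)
    rows = state.locus_stats_rows(i)
    accepted = False
    if rows is not None:
        dens_new = state._dens_from_rows(rows, state.h[i])
        if math.log(rng.random()) < dens_new - state.dens_loc[i]:
            state.C[i], state.A[i], state.W[i], state.B[i] = rows
            state.dens_loc[i] = dens_new
            accepted = True
    if not accepted:
        lst[idx][0] = t_old
        _gev_update(state, i, 1, t_new, k, t_old)
    return accepted


def _gev_update(state: MCMCState, i: int, kind: int, t_old: float,
                payload_old: int, t_new: float,
                payload_new: int | None = None) -> None:
    """Patch one entry of the cached per-locus event arrays in place."""
    cached = state._gev[i]
    if cached is None:
        return
    times, kinds, payload = cached
    hit = np.nonzero((kinds == kind) & (times == t_old)
                     & (payload == payload_old))[0]
    if hit.size == 0:  # stale cache; rebuild lazily
        state._gev[i] = None
        return
    idx = int(hit[0])
    times[idx] = t_new
    if payload_new is not None:
        payload[idx] = payload_new


def propose_node_age(state: MCMCState, i: int, step: float,
                     rng: np.random.Generator) -> bool:
    """Slide one coalescent node's age within its feasible interval.

    Bounds come from the last migration event (or child node) on each
    child edge, the first event on the node's own edge (or its parent),
    and the species divergence below which the two entering lineages are
    in different populations.  The node's population follows the move.
    """
    g = state.gtrees[i]
    stree, tau = state.stree, state.params.tau
    internals = [v for v in range(g.n_nodes) if g.children[v, 0] >= 0]
    v = internals[int(rng.integers(len(internals)))]
    c1, c2 = int(g.children[v, 0]), int(g.children[v, 1])
    lo = max(float(g.time[c1]), float(g.time[c2]))
    q1 = g.pop_exiting(c1)
    q2 = g.pop_exiting(c2)
    if g.edge_events[c1]:
        lo = max(lo, g.edge_events[c1][-1][0])
    if g.edge_events[c2]:
        lo = max(lo, g.edge_events[c2][-1][0])
    if q1 != q2:
        lo = max(lo, float(tau[stree.mrca(q1, q2)]))
    par = int(g.parent[v])
    if par == -1:
        hi = _INF
    elif g.edge_events[v]:
        hi = float(g.edge_events[v][0][0])
    else:
        hi = float(g.time[par])
    if not lo < hi:
        return False
    t_old = float(g.time[v])
    pop_old = int(g.node_pop[v])
    if hi == _INF:
        # unbounded (root) ages: window scaled by the root coalescent scale
        width = float(state.params.theta[stree.root]) * float(state.h[i])
    else:
        width = hi - lo
    t_new = _reflect(t_old + step * width * (rng.random() - 0.5), lo, hi)
    g.time[v] = t_new
    pop_new = stree.ancestor_at(q1, t_new, tau)
    g.node_pop[v] = pop_new
    _gev_update(state, i, 0, t_old, pop_old, t_new, pop_new)
    rows = state.locus_stats_rows(i)
    accepted = False
    if rows is not None:
        dens_new = state._dens_from_rows(rows, state.h[i])
        delta = dens_new - state.dens_loc[i]
        lik_new = 0.0
        if state.use_likelihood:
            lik_new = state.locus_loglik(i)
            delta += state.beta * (lik_new - state.loglik[i])
        if math.log(rng.random()) < delta:
            state.C[i], state.A[i], state.W[i], state.B[i] = rows
            state.dens_loc[i] = dens_new
            if state.use_likelihood:
                state.loglik[i] = lik_new
            accepted = True
    if not accepted:
        g.time[v] = t_old
        g.node_pop[v] = pop_old
        _gev_update(state, i, 0, t_new, pop_new, t_old, pop_old)
    return accepted


# ---------------------------------------------------------------------------
# SPR with migration: regraft by re-simulating the backward path


def _subtree_nodes(g: GeneTree, u: int) -> set[int]:
    out = set()
    stack = [u]
    while stack:
        v = stack.pop()
        out.add(v)
        for side in range(2):
            ch = int(g.children[v, side])
            if ch >= 0:
                stack.append(ch)
    return out


def _build_backbone(state: MCMCState, g: GeneTree, u: int):
    """Chronological breakpoints of the gene-tree backbone after pruning u.

    The pruned subtree's parent node is removed; the sibling edge extends
    through it, inheriting its events.  Returns (breakpoints, initial edge
    -> population map).  Breakpoint kinds: 0 coalescence (edge merge),
    1 migration on a backbone edge, 2 species divergence.
    """
    p = int(g.parent[u])
    sib = int(g.children[p, 0]) if int(g.children[p, 1]) == u \
        else int(g.children[p, 1])
    under = _subtree_nodes(g, u)
    bps = []
    for v in range(g.n_nodes):
        if g.children[v, 0] < 0 or v in under or v == p:
            continue
        kids = [int(g.children[v, 0]), int(g.children[v, 1])]
        kids = [sib if k == p else k for k in kids]
        bps.append((float(g.time[v]), 0, (v, kids, int(g.node_pop[v]))))
    for c in range(g.n_nodes):
        if c in under or c == u:
            continue
        owner = sib if c == p else c
        for t, s, j in g.edge_events[c]:
            bps.append((float(t), 1, (owner, int(s), int(j))))
    tau = state.params.tau
    for d in state.stree.internal_nodes:
        bps.append((float(tau[d]), 2, int(d)))
    bps.sort(key=lambda e: (e[0], -e[1]))
    init = {tip: int(sp) for tip, sp in enumerate(g.tip_species)
            if tip not in under}
    return bps, init


def _spr_path(state: MCMCState, g: GeneTree, u: int,
              rng: np.random.Generator | None = None,
              fixed: tuple | None = None,
              backbone: tuple | None = None, h: float = 1.0):
    """Sample (rng) or score (fixed) the re-attachment path of lineage u.

    The path starts at u's age in u's population and experiences, backward
    in time, migration at the per-lineage rates 4 M_sq/(theta_q h) and
    coalescence at rate 2/(theta_q h) with each backbone lineage currently
    in the same population.  Returns (log path density, events, t_attach,
    edge_attach, pop_attach) or None when a fixed path cannot be realised.
    """
    stree, mig, params = state.stree, state.mig, state.params
    tau, theta, M = params.tau, params.theta, params.M
    if backbone is None:
        backbone = _build_backbone(state, g, u)
    bps, init = backbone
    cur = dict(init)
    counts = np.zeros(stree.n_nodes, dtype=np.int64)
    for e, pop in cur.items():
        counts[pop] += 1
    a0, a1 = state.a0, state.a1
    into = mig.into

    t_now = float(g.time[u])
    bi = 0
    # fast-forward breakpoints below the path start
    while bi < len(bps) and bps[bi][0] <= t_now:
        _apply_bp(bps[bi], cur, counts, stree)
        bi += 1
    q = int(g.node_pop[u])
    q = stree.ancestor_at(q, t_now, tau)

    logq = 0.0
    events: list[tuple[float, int, int]] = []
    if fixed is not None:
        fixed_events, t_att_f, edge_att_f = fixed
        fi = 0
    while True:
        th_q = theta[q] * h
        rate_m = 0.0
        m_entries = []
        for k in into[q]:
            if a0[k] <= t_now < a1[k] and M[k] > 0.0:
                r = 4.0 * M[k] / th_q
                m_entries.append((int(k), r))
                rate_m += r
        k_q = int(counts[q])
        rate_c = 2.0 * k_q / th_q
        R = rate_c + rate_m
        t_bp = bps[bi][0] if bi < len(bps) else _INF

        if fixed is None:
            t_ev = t_now + rng.exponential(1.0 / R) if R > 0.0 else _INF
            if t_ev < t_bp:
                logq -= R * (t_ev - t_now)
                uu = rng.random() * R
                if uu < rate_c:
                    members = [e for e, pop in cur.items() if pop == q]
                    att = members[int(rng.integers(len(members)))]
                    logq += math.log(2.0 / th_q)
                    return logq, events, t_ev, att, q
                uu -= rate_c
                pick = None
                for k, r in m_entries:
                    if uu < r:
                        pick = (k, r)
                        break
                    uu -= r
                if pick is None:
                    pick = m_entries[-1]
                k, r = pick
                logq += math.log(r)
                s = int(mig.source[k])
                events.append((t_ev, s, q))
                q = s
                t_now = t_ev
                continue
        else:
            if fi < len(fixed_events):
                t_ev, s_f, j_f = fixed_events[fi]
            else:
                t_ev, s_f, j_f = t_att_f, -1, -1
            if t_ev < t_bp:
                logq -= R * (t_ev - t_now)
                if s_f < 0:  # attachment
                    if cur.get(edge_att_f) != q or k_q == 0:
                        return None
                    logq += math.log(2.0 / th_q)
                    return logq, list(fixed_events), t_ev, edge_att_f, q
                if j_f != q:
                    return None
                r = 4.0 * M[mig.pair_index[(s_f, j_f)]] / th_q
                if not r > 0.0:
                    return None
                logq += math.log(r)
                q = s_f
                t_now = t_ev
                fi += 1
                continue
        # no path event before the next breakpoint
        if t_bp == _INF:  # cannot happen: root population coalesces
            return None
        logq -= R * (t_bp - t_now)
        q = _apply_bp(bps[bi], cur, counts, stree, q)
        t_now = t_bp
        bi += 1


def _apply_bp(bp, cur: dict, counts: np.ndarray, stree: SpeciesTree,
              q: int | None = None):
    """Advance the backbone occupancy through one breakpoint."""
    t, kind, data = bp
    if kind == 0:
        v, kids, pop = data
        for k in kids:
            counts[cur.pop(k)] -= 1
        cur[v] = pop
        counts[pop] += 1
    elif kind == 1:
        owner, s, j = data
        counts[cur[owner]] -= 1
        cur[owner] = s
        counts[s] += 1
    else:
        d = data
        c1, c2 = int(stree.children[d, 0]), int(stree.children[d, 1])
        for e in list(cur):
            if cur[e] == c1 or cur[e] == c2:
                cur[e] = d
        counts[d] += counts[c1] + counts[c2]
        counts[c1] = 0
        counts[c2] = 0
        if q is not None and (q == c1 or q == c2):
            q = d
    return q


def _edges_ok(g: GeneTree) -> bool:
    """Every edge's child, events and parent strictly ordered in time."""
    for c in range(g.n_nodes):
        p = int(g.parent[c])
        if p == -1:
            if c == g.root and g.edge_events[c]:
                return False
            continue
        t0 = float(g.time[c])
        t1 = float(g.time[p])
        if not t0 < t1:
            return False
        prev = t0
        for e in g.edge_events[c]:
            if not prev <= e[0] < t1:
                return False
            prev = e[0]
    return True


def _apply_spr(g: GeneTree, u: int, events, t_att: float, edge_att: int,
               pop_att: int) -> bool:
    """Regraft lineage u at (edge_att, t_att); False if the result would
    leave migration events above the new MRCA (outside the state space)."""
    p = int(g.parent[u])
    sib = int(g.children[p, 0]) if int(g.children[p, 1]) == u \
        else int(g.children[p, 1])
    gp = int(g.parent[p])
    # detach: sibling edge extends through p, inheriting p's edge events
    if gp != -1:
        side = 0 if int(g.children[gp, 0]) == p else 1
        g.children[gp, side] = sib
        g.parent[sib] = gp
    else:
        g.parent[sib] = -1
        g.root = sib
    g.edge_events[sib] = g.edge_events[sib] + g.edge_events[p]
    g.edge_events[p] = []
    # attach p back onto edge_att at t_att
    w = int(g.parent[edge_att])
    lst = g.edge_events[edge_att]
    g.edge_events[edge_att] = [e for e in lst if e[0] < t_att]
    g.edge_events[p] = [e for e in lst if e[0] >= t_att]
    g.children[p, 0] = u
    g.children[p, 1] = edge_att
    g.parent[u] = p
    g.parent[edge_att] = p
    g.time[p] = t_att
    g.node_pop[p] = pop_att
    if w == -1:
        g.parent[p] = -1
        g.root = p
    else:
        side = 0 if int(g.children[w, 0]) == edge_att else 1
        g.children[w, side] = p
        g.parent[p] = w
    g.edge_events[u] = [[t, float(s), float(j)] for t, s, j in events]
    return not g.edge_events[g.root]


def propose_spr_migration(state: MCMCState, i: int,
                          rng: np.random.Generator) -> bool:
    """Prune a lineage and regraft it by simulating its backward path.

    The Hastings ratio is the density of the reverse path (the old edge
    with its events, scored under the same simulation law against the same
    backbone) over the density of the sampled forward path.
    """
    g = state.gtrees[i]
    u = int(rng.integers(g.n_nodes - 1))
    if u >= g.root:
        u += 1
    p = int(g.parent[u])
    sib = int(g.children[p, 0]) if int(g.children[p, 1]) == u \
        else int(g.children[p, 1])
    old_events = [(float(t), int(s), int(j)) for t, s, j in g.edge_events[u]]
    old_att = (float(g.time[p]), sib)

    backbone = _build_backbone(state, g, u)
    h = float(state.h[i])
    fwd = _spr_path(state, g, u, rng=rng, backbone=backbone, h=h)
    if fwd is None:
        return False
    logq_fwd, new_events, t_att, edge_att, pop_att = fwd
    rev = _spr_path(state, g, u, fixed=(old_events, old_att[0], old_att[1]),
                    backbone=backbone, h=h)
    if rev is None:
        return False
    logq_rev = rev[0]

    g2 = g.copy()
    if not _apply_spr(g2, u, new_events, t_att, edge_att, pop_att):
        return False
    old_g = g
    old_gev = state._gev[i]
    old_post = state._post[i]
    state.gtrees[i] = g2
    state._gev[i] = None
    state._post[i] = None
    rows = state.locus_stats_rows(i)
    accepted = False
    if rows is not None and _edges_ok(g2):
        dens_new = state._dens_from_rows(rows, state.h[i])
        delta = dens_new - state.dens_loc[i] + logq_rev - logq_fwd
        lik_new = 0.0
        if state.use_likelihood:
            lik_new = state.locus_loglik(i)
            delta += state.beta * (lik_new - state.loglik[i])
        if math.log(rng.random()) < delta:
            state.C[i], state.A[i], state.W[i], state.B[i] = rows
            state.dens_loc[i] = dens_new
            if state.use_likelihood:
                state.loglik[i] = lik_new
            accepted = True
    if not accepted:
        state.gtrees[i] = old_g
        state._gev[i] = old_gev
        state._post[i] = old_post
    return accepted


# ---------------------------------------------------------------------------
# divergence-time moves (rubber band, composite space)


def _propose_tau(state: MCMCState, node: int, step: float,
                 rng: np.random.Generator, extended: bool = True) -> bool:
    """Rubber-band update of one species divergence time.

    Gene-tree node ages in the two daughter populations within
    (tau_l, tau) are mapped linearly onto (tau_l, tau'), ages in the
    updated population within (tau, tau_u) onto (tau', tau_u); for the
    root the upper side is a rigid shift.  With ``extended`` the affected
    migration times are mapped the same way; otherwise they are left
    untouched and any conflict rejects the move.  Activity windows are
    recomputed, so migration-rate parameters may flip between active and
    inactive (composite space): their priors cancel because inactive rates
    keep the prior as pseudo-prior, and a flip that would orphan existing
    migration events is rejected by the validity screen.
    """
    stree, params = state.stree, state.params
    tau = params.tau
    is_root = node == stree.root
    c1, c2 = int(stree.children[node, 0]), int(stree.children[node, 1])
    tau_l = max(float(tau[c1]), float(tau[c2]))
    tau_u = _INF if is_root else float(tau[int(stree.parent[node])])
    t_old = float(tau[node])
    t_new = _reflect(t_old + step * (rng.random() - 0.5), tau_l, tau_u)
    if t_new <= tau_l or t_new == t_old:
        return False
    k_lo = (t_new - tau_l) / (t_old - tau_l)
    k_hi = 1.0 if is_root else (tau_u - t_new) / (tau_u - t_old)
    shift = t_new - t_old

    n_lo = 0
    n_hi = 0
    undo_nodes: list[tuple[int, int, float]] = []
    undo_evs: list[tuple[int, int, int, float]] = []
    touched = np.zeros(state.L, dtype=bool)
    lik_changed = np.zeros(state.L, dtype=bool)
    for i, g in enumerate(state.gtrees):
        for v in range(g.n_nodes):
            if g.children[v, 0] < 0:
                continue
            pv = int(g.node_pop[v])
            t = float(g.time[v])
            if (pv == c1 or pv == c2) and t > tau_l:
                t2 = tau_l + (t - tau_l) * k_lo
                n_lo += 1
            elif pv == node:
                t2 = t + shift if is_root else tau_u - (tau_u - t) * k_hi
                if not is_root:
                    n_hi += 1
            else:
                continue
            undo_nodes.append((i, v, t))
            g.time[v] = t2
            touched[i] = True
            lik_changed[i] = True
        if extended:
            for c in range(g.n_nodes):
                lst = g.edge_events[c]
                for idx, ev in enumerate(lst):
                    t = float(ev[0])
                    jj = int(ev[2])
                    if (jj == c1 or jj == c2) and tau_l < t < t_old:
                        t2 = tau_l + (t - tau_l) * k_lo
                        n_lo += 1
                    elif jj == node and t >= t_old:
                        t2 = t + shift if is_root \
                            else tau_u - (tau_u - t) * k_hi
                        if not is_root:
                            n_hi += 1
                    else:
                        continue
                    undo_evs.append((i, c, idx, t))
                    ev[0] = t2
                    touched[i] = True

    old_C = state.C.copy()
    old_A = state.A.copy()
    old_W = state.W.copy()
    old_B = state.B.copy()
    old_dens = state.dens_loc.copy()
    old_lik = state.loglik.copy()
    old_pri = state.logpri

    tau[node] = t_new
    state._refresh_tau_cache()
    ok = True
    for i in np.nonzero(touched)[0]:
        state._gev[int(i)] = None
        if not _edges_ok(state.gtrees[int(i)]):
            ok = False
            break
    if ok:
        for i in range(state.L):
            rows = state.locus_stats_rows(i)
            if rows is None:
                ok = False
                break
            state.C[i], state.A[i], state.W[i], state.B[i] = rows
    accepted = False
    if ok:
        state.dens_loc = state.density_vector()
        lp_new = log_prior(params, state.priors, stree, state.mig)
        dlik = 0.0
        if state.use_likelihood:
            for i in np.nonzero(lik_changed)[0]:
                new = state.locus_loglik(int(i))
                dlik += new - old_lik[int(i)]
                state.loglik[int(i)] = new
        delta = (lp_new - old_pri
                 + float(state.dens_loc.sum() - old_dens.sum())
                 + state.beta * dlik
                 + n_lo * math.log(k_lo)
                 + (0.0 if is_root else n_hi * math.log(k_hi)))
        if math.log(rng.random()) < delta:
            state.logpri = lp_new
            accepted = True
    if not accepted:
        for i, v, t in undo_nodes:
            state.gtrees[i].time[v] = t
        for i, c, idx, t in undo_evs:
            state.gtrees[i].edge_events[c][idx][0] = t
        tau[node] = t_old
        state._refresh_tau_cache()
        state.C, state.A, state.W, state.B = old_C, old_A, old_W, old_B
        state.dens_loc = old_dens
        state.loglik = old_lik
        state.logpri = old_pri
        for i in np.nonzero(touched)[0]:
            state._gev[int(i)] = None
    return accepted


def propose_tau_slide(state: MCMCState, node: int, step: float,
                      rng: np.random.Generator) -> bool:
    """Slide one divergence time without remapping any gene-tree times.

    Valid whenever every coalescence and migration event remains inside
    its population's (shifted) lifespan and every migration event inside
    its activity window; otherwise the move auto-rejects.  Branch lengths
    are untouched, so only the prior and the gene-tree density enter the
    ratio.  Complements the rubber-band kernels: it makes many cheap
    moves within the slack the current genealogies allow.
    """
    stree, params = state.stree, state.params
    tau = params.tau
    is_root = node == stree.root
    c1, c2 = int(stree.children[node, 0]), int(stree.children[node, 1])
    tau_l = max(float(tau[c1]), float(tau[c2]))
    tau_u = _INF if is_root else float(tau[int(stree.parent[node])])
    t_old = float(tau[node])
    t_new = _reflect(t_old + step * (rng.random() - 0.5), tau_l, tau_u)
    if t_new <= tau_l or t_new == t_old:
        return False
    old_C = state.C.copy()
    old_A = state.A.copy()
    old_W = state.W.copy()
    old_B = state.B.copy()
    old_dens = state.dens_loc.copy()
    old_pri = state.logpri
    tau[node] = t_new
    state._refresh_tau_cache()
    # deterministic relabelling of coalescences the boundary crossed:
    # a node recorded in a daughter population whose lifespan no longer
    # contains its age belongs to the ancestor, and vice versa; the
    # correct population follows from the entering lineages' paths
    affected = (c1, c2, node)
    undo_pops: list[tuple[int, int, int]] = []
    ok = True
    lo = min(t_old, t_new)
    hi = max(t_old, t_new)
    for i, g in enumerate(state.gtrees):
        cand = [(float(g.time[v]), v) for v in range(g.n_nodes)
                if int(g.node_pop[v]) in affected
                and lo <= g.time[v] < hi]
        if not cand:
            continue
        cand.sort()  # children before parents: labels propagate upward
        touched = False
        for t, v in cand:
            pv = int(g.node_pop[v])
            q1 = stree.ancestor_at(g.pop_exiting(int(g.children[v, 0])),
                                   t, tau)
            q2 = stree.ancestor_at(g.pop_exiting(int(g.children[v, 1])),
                                   t, tau)
            if q1 != q2:
                ok = False
                break
            if q1 != pv:
                undo_pops.append((i, v, pv))
                g.node_pop[v] = q1
                touched = True
        if touched:
            state._gev[i] = None
        if not ok:
            break
    if ok:
        for i in range(state.L):
            rows = state.locus_stats_rows(i)
            if rows is None:
                ok = False
                break
            state.C[i], state.A[i], state.W[i], state.B[i] = rows
    if ok:
        state.dens_loc = state.density_vector()
        lp_new = log_prior(params, state.priors, stree, state.mig)
        delta = (lp_new - old_pri
                 + float(state.dens_loc.sum() - old_dens.sum()))
        if math.log(rng.random()) < delta:
            state.logpri = lp_new
            return True
    tau[node] = t_old
    state._refresh_tau_cache()
    for i, v, pv in undo_pops:
        state.gtrees[i].node_pop[v] = pv
        state._gev[i] = None
    state.C, state.A, state.W, state.B = old_C, old_A, old_W, old_B
    state.dens_loc = old_dens
    state.logpri = old_pri
    return False


def propose_tau_rubberband_extended(state, node, step, rng) -> bool:
    """Rubber-band tau update rescaling affected migration times too."""
    return _propose_tau(state, node, step, rng, extended=True)


def propose_tau_rejection(state, node, step, rng) -> bool:
    """Rubber-band tau update that abandons the move whenever the mapped
    coalescent times conflict with (untouched) migration events."""
    return _propose_tau(state, node, step, rng, extended=False)


def propose_tau_composite_space(state, node, step, rng,
                                extended: bool = True) -> bool:
    """Trans-model tau update across activity flips of migration rates.

    Identical machinery to the rubber-band moves: because inactive rates
    remain in the state under their prior (pseudo-prior = prior, the
    metropolized Carlin–Chib choice), the prior terms of flipping entries
    cancel from the acceptance ratio and no further factors are needed.
    """
    return _propose_tau(state, node, step, rng, extended=extended)


# ---------------------------------------------------------------------------
# mixing move


def propose_mixing(state: MCMCState, step: float, rng: np.random.Generator,
                   mix_theta: bool = False) -> bool:
    """Rescale every time variable (and optionally theta) by a common factor.

    All species divergence times, coalescent times and migration times are
    multiplied by c = exp(step (u - 1/2)); the proposal-density ratio is
    c^d with d the number of scaled variables.
    """
    c = math.exp(step * (rng.random() - 0.5))
    if c == 1.0:
        return True
    stree, params = state.stree, state.params
    d = len(list(stree.internal_nodes))
    for g in state.gtrees:
        d += (g.n_tips - 1) + g.n_migrations
    new_tau = params.tau * c
    new_theta = params.theta * c if mix_theta else params.theta
    if mix_theta:
        d += stree.n_nodes
    newp = ParamSet(new_tau, new_theta, params.M)

    # exposures are linear in time: stats rescale without a resweep
    A2 = state.A * c
    B2 = state.B * c
    th = state.h[:, None] * new_theta[None, :]
    dens_new = np.sum(state.C * np.log(2.0 / th) - A2 / th, axis=1)
    if state.mig.n_entries:
        thd = state.h[:, None] * new_theta[state.mig.dest][None, :]
        rate = 4.0 * params.M[None, :] / thd
        with np.errstate(divide="ignore"):
            lw = np.where(state.W > 0,
                          state.W * np.log(np.where(rate > 0, rate, 1.0)),
                          0.0)
        lw = np.where((state.W > 0) & (rate <= 0.0), -_INF, lw)
        dens_new = dens_new + np.sum(lw, axis=1) - np.sum(rate * B2, axis=1)
    lp_new = log_prior(newp, state.priors, stree, state.mig)
    dlik = 0.0
    lik_new = None
    if state.use_likelihood:
        lik_new = np.empty(state.L)
        for i, g in enumerate(state.gtrees):
            post = state._post[i]
            if post is None:
                post = np.array([nd for nd in g.postorder()
                                 if g.children[nd, 0] >= 0], dtype=np.int64)
                state._post[i] = post
            lik_new[i] = jc_pruning(post, g.children, g.time * c,
                                    state.tipcodes[i], state.tables[i].counts)
        dlik = float(lik_new.sum() - state.loglik.sum())
    delta = (lp_new - state.logpri
             + float(dens_new.sum() - state.dens_loc.sum())
             + state.beta * dlik + d * math.log(c))
    if math.log(rng.random()) < delta:
        params.tau[:] = new_tau
        if mix_theta:
            params.theta[:] = new_theta
        state.A = A2
        state.B = B2
        state.dens_loc = dens_new
        if state.use_likelihood:
            state.loglik = lik_new
        state.logpri = lp_new
        for i, g in enumerate(state.gtrees):
            g.time *= c
            for lst in g.edge_events:
                for ev in lst:
                    ev[0] *= c
            if state._gev[i] is not None:
                t_arr, k_arr, a_arr = state._gev[i]
                state._gev[i] = (t_arr * c, k_arr, a_arr)
        state._refresh_tau_cache()
        return True
    return False


# ---------------------------------------------------------------------------
# trace, summaries, driver


@dataclass
class Trace:
    """MCMC output: one row per recorded sample plus acceptance diagnostics."""

    samples: pd.DataFrame
    acceptance: dict[str, float]
    settings: MCMCSettings
    seed: int | None = None

    def __getitem__(self, key: str) -> np.ndarray:
        return self.samples[key].to_numpy()

    @property
    def param_names(self) -> list[str]:
        return [c for c in self.samples.columns
                if c.split("_")[0] in ("tau", "theta", "M")]


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(prob * n)`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    m = int(math.ceil(prob * n))
    m = min(max(m, 1), n)
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def trace_columns(stree: SpeciesTree, mig: MigrationSpec) -> list[str]:
    cols = [f"tau_{stree.labels[i]}" for i in stree.internal_nodes]
    cols += [f"theta_{lab}" for lab in stree.labels]
    cols += [f"M_{s}_{j}" for s, j in mig.pairs]
    return cols


def _default_steps(stree: SpeciesTree, mig: MigrationSpec,
                   priors: PriorSpec) -> dict:
    th_mean = priors.theta_shape / priors.theta_rate
    tau_mean = priors.tau_shape / priors.tau_rate
    m_mean = priors.mig_shape / priors.mig_rate
    steps = {}
    for j in range(stree.n_nodes):
        steps[("theta", j)] = th_mean
    for k in range(mig.n_entries):
        steps[("M", k)] = 2.0 * m_mean
    for nd in stree.internal_nodes:
        steps[("tau", nd)] = 0.3 * tau_mean
        steps[("tslide", nd)] = 0.1 * tau_mean
    steps[("age",)] = 0.7
    steps[("migtime",)] = 0.7
    steps[("mix",)] = 0.4
    return steps


def run_mcmc(loci: list[Locus] | None, stree: SpeciesTree,
             mig: MigrationSpec, priors: PriorSpec,
             settings: MCMCSettings, seed: int,
             params0: ParamSet | None = None,
             sample_config=None) -> Trace:
    """Run the full kernel mixture and collect a parameter trace.

    With ``loci=None`` the likelihood is identically 1 and the chain
    samples the prior (the standard validation mode); ``sample_config``
    then specifies the gene-tree sampling design.  Step sizes are tuned
    toward the target acceptance rate during burn-in only, then frozen.
    """
    rng = np.random.default_rng(seed)
    state = init_state(stree, mig, priors, loci, settings, rng,
                       params0=params0, sample_config=sample_config)
    steps = _default_steps(stree, mig, priors)
    att = {k: 0 for k in steps}
    acc = {k: 0 for k in steps}
    att_tot = {k: 0 for k in steps}
    acc_tot = {k: 0 for k in steps}
    extended = settings.tau_kernel == "extended"

    cols = trace_columns(stree, mig)
    rows = []
    extras = []
    internals = list(stree.internal_nodes)
    P, E, L = stree.n_nodes, mig.n_entries, state.L

    for it in range(settings.n_iter):
        for nd in internals:
            key = ("tau", nd)
            att[key] += 1
            acc[key] += _propose_tau(state, nd, steps[key], rng,
                                     extended=extended)
        for _ in range(settings.tau_slides):
            for nd in internals:
                key = ("tslide", nd)
                att[key] += 1
                acc[key] += propose_tau_slide(state, nd, steps[key], rng)
        for j in range(P):
            key = ("theta", j)
            att[key] += 1
            acc[key] += propose_theta(state, j, steps[key], rng)
        for k in range(E):
            key = ("M", k)
            att[key] += 1
            acc[key] += propose_migration_rate(state, k, steps[key], rng)
        for i in range(L):
            for _ in range(settings.ages_per_locus):
                att[("age",)] += 1
                acc[("age",)] += propose_node_age(state, i, steps[("age",)],
                                                  rng)
            for _ in range(settings.sprs_per_locus):
                propose_spr_migration(state, i, rng)
            for _ in range(settings.migtimes_per_locus):
                if state.gtrees[i].n_migrations:
                    att[("migtime",)] += 1
                    acc[("migtime",)] += propose_migration_time(
                        state, i, steps[("migtime",)], rng)
        att[("mix",)] += 1
        acc[("mix",)] += propose_mixing(state, steps[("mix",)], rng,
                                        mix_theta=settings.mix_theta)

        if (settings.tune and it < settings.burnin
                and (it + 1) % settings.tune_interval == 0):
            for key in steps:
                if att[key] == 0:
                    continue
                rate = acc[key] / att[key]
                steps[key] *= math.exp(1.5 * (rate - settings.target_accept))
                steps[key] = min(max(steps[key], 1e-7), 50.0)
                att_tot[key] += att[key]
                acc_tot[key] += acc[key]
                att[key] = 0
                acc[key] = 0

        if (settings.debug_check_every
                and (it + 1) % settings.debug_check_every == 0):
            state.assert_consistent()

        if it >= settings.burnin and \
                (it - settings.burnin) % settings.thin == 0:
            p = state.params
            row = [float(p.tau[i]) for i in internals]
            row += [float(x) for x in p.theta]
            row += [float(x) for x in p.M]
            rows.append(row)
            extras.append((state.log_density, float(state.loglik.sum()),
                           sum(g.n_migrations for g in state.gtrees) / L))

    for key in steps:
        att_tot[key] += att[key]
        acc_tot[key] += acc[key]
    df = pd.DataFrame(rows, columns=cols)
    ex = pd.DataFrame(extras, columns=["lnG", "lnL", "nmig_mean"])
    df = pd.concat([df, ex], axis=1)
    acceptance = {"/".join(str(x) for x in key):
                  (acc_tot[key] / att_tot[key] if att_tot[key] else math.nan)
                  for key in steps}
    return Trace(samples=df, acceptance=acceptance, settings=settings,
                 seed=seed)
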