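"""Backward-in-time structured-coalescent simulation under MSC-M.

Gene trees are generated by the exact variable-rate Poisson process the
density in :mod:`mscmig.density` describes: within each epoch between
species divergences the total event rate is

    sum_j n_j (n_j - 1) / (theta_j h)  +  sum_(s,j active) n_j 4 M_sj / (theta_j h),

a waiting time is drawn, the event type and population are chosen
proportionally to their rates, and at each species divergence the process
is reset with the daughter populations' lineages relabelled to the
ancestor.  Sequences then evolve down the simulated genealogy under JC69.

This module is the synthetic-data generator for the whole package: every
test input is produced here, reproducibly, from per-locus seed streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import GeneTree, Locus, MigrationSpec, ParamSet, PriorSpec, sample_prior
from .species import SpeciesTree

__all__ = [
    "SampleConfig",
    "simulate_gene_tree",
    "simulate_alignment",
    "simulate_dataset",
    "bayesian_replicate",
    "locus_rng",
]


@dataclass(frozen=True)
class SampleConfig:
    """Sampling design: sequences per species, loci, sites, heredity.

    ``n_seq`` may be an int (same for every species) or a dict keyed by
    tip label; species absent from the dict contribute no sequences.
    """

    n_seq: int | dict[str, int] = 4
    n_loci: int = 100
    n_sites: int = 500
    h: float = 1.0

    def counts(self, stree: SpeciesTree) -> dict[str, int]:
        if isinstance(self.n_seq, dict):
            unknown = set(self.n_seq) - set(stree.labels[: stree.n_tips])
            if unknown:
                raise ValueError(f"unknown species in sample config: {unknown}")
            return {k: int(v) for k, v in self.n_seq.items() if v > 0}
        return {lab: int(self.n_seq) for lab in stree.labels[: stree.n_tips]}


def locus_rng(seed: int, k: int) -> np.random.Generator:
    """Independent, reproducible random stream for locus ``k``.

    A locus drawn alone is bit-identical to the same locus drawn in a
    batch, because each stream is keyed by (seed, locus index) only.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


def simulate_gene_tree(stree: SpeciesTree, mig: MigrationSpec,
                       params: ParamSet,
                       n_per_species: dict[str, int] | int | list,
                       rng: np.random.Generator, h: float = 1.0) -> GeneTree:
    """Simulate one genealogy with its full migration history.

    ``n_per_species`` is an int or dict of per-species sample sizes, or an
    explicit list of ``(name, species_index)`` tips (used to match the
    sequence names of an existing alignment).
    """
    tau, theta, M = params.tau, params.theta, params.M
    labels: list[str] = []
    tip_species: list[int] = []
    if isinstance(n_per_species, list):
        for name, s_idx in n_per_species:
            labels.append(str(name))
            tip_species.append(int(s_idx))
    else:
        if isinstance(n_per_species, int):
            n_per_species = {lab: n_per_species
                             for lab in stree.labels[: stree.n_tips]}
        for s_idx in range(stree.n_tips):
            lab = stree.labels[s_idx]
            for i in range(int(n_per_species.get(lab, 0))):
                labels.append(f"{lab}^{i + 1}")
                tip_species.append(s_idx)
    n_tips = len(labels)
    if n_tips < 2:
        raise ValueError("need at least two sampled sequences")
    gtree = GeneTree(n_tips, labels, np.array(tip_species, dtype=np.int64))

    P = stree.n_nodes
    E = mig.n_entries
    a0, a1 = mig.windows(tau)
    src, dst = mig.source, mig.dest
    boundaries = sorted((float(tau[i]), int(i)) for i in stree.internal_nodes)

    lineage: list[int] = list(range(n_tips))  # node id of each live lineage
    lin_pop: list[int] = list(tip_species)
    next_node = n_tips
    t = 0.0
    bi = 0
    coal_rate = np.zeros(P)
    mig_rate = np.zeros(E)
    while len(lineage) > 1:
        if bi < len(boundaries):
            epoch_end, div_node = boundaries[bi]
        else:
            epoch_end, div_node = math.inf, -1
        n = np.zeros(P, dtype=np.int64)
        for p in lin_pop:
            n[p] += 1
        coal_rate[:] = n * (n - 1) / (theta * h)
        for k in range(E):
            if a0[k] <= t and epoch_end <= a1[k]:
                mig_rate[k] = n[dst[k]] * 4.0 * M[k] / (theta[dst[k]] * h)
            else:
                mig_rate[k] = 0.0
        R = float(coal_rate.sum() + mig_rate.sum())
        dt = rng.exponential(1.0 / R) if R > 0 else math.inf
        if t + dt >= epoch_end:
            # deterministic reset at the divergence: daughters -> ancestor
            t = epoch_end
            c1, c2 = (int(x) for x in stree.children[div_node])
            lin_pop = [div_node if p in (c1, c2) else p for p in lin_pop]
            bi += 1
            continue
        t += dt
        u = rng.uniform(0.0, R)
        acc = 0.0
        chosen_pop = -1
        chosen_entry = -1
        for j in range(P):
            acc += coal_rate[j]
            if u < acc:
                chosen_pop = j
                break
        if chosen_pop < 0:
            for k in range(E):
                acc += mig_rate[k]
                if u < acc:
                    chosen_entry = k
                    break
            if chosen_entry < 0:  # float edge; take the last positive rate
                chosen_entry = int(np.argmax(mig_rate))
        if chosen_pop >= 0:
            members = [i for i, p in enumerate(lin_pop) if p == chosen_pop]
            i1, i2 = rng.choice(len(members), size=2, replace=False)
            l1, l2 = lineage[members[i1]], lineage[members[i2]]
            nd = next_node
            next_node += 1
            gtree.children[nd, 0] = l1
            gtree.children[nd, 1] = l2
            gtree.parent[l1] = nd
            gtree.parent[l2] = nd
            gtree.time[nd] = t
            gtree.node_pop[nd] = chosen_pop
            keep = min(members[i1], members[i2])
            drop = max(members[i1], members[i2])
            lineage[keep] = nd
            lin_pop[keep] = chosen_pop
            del lineage[drop], lin_pop[drop]
        else:
            j = int(dst[chosen_entry])
            s = int(src[chosen_entry])
            members = [i for i, p in enumerate(lin_pop) if p == j]
            pick = members[int(rng.integers(len(members)))]
            gtree.edge_events[lineage[pick]].append([t, float(s), float(j)])
            lin_pop[pick] = s
    gtree.root = lineage[0]
    return gtree


def simulate_alignment(gtree: GeneTree, n_sites: int,
                       rng: np.random.Generator, h: float = 1.0) -> Locus:
    """Evolve ``n_sites`` iid sites down the gene tree under JC69.

    Branch lengths are in expected mutations per site; migration events do
    not affect them (the mutation rate is population-independent).  The
    root sequence is uniform over the four bases.
    """
    n_nodes = gtree.n_nodes
    seq = np.empty((n_nodes, n_sites), dtype=np.int8)
    seq[gtree.root] = rng.integers(0, 4, size=n_sites, dtype=np.int8)
    stack = [gtree.root]
    while stack:
        nd = stack.pop()
        for side in range(2):
            ch = int(gtree.children[nd, side])
            if ch < 0:
                continue
            t = float(gtree.time[nd] - gtree.time[ch])
            p_change = 0.75 * -math.expm1(-4.0 * t / 3.0)
            child_seq = seq[nd].copy()
            mask = rng.random(n_sites) < p_change
            k = int(mask.sum())
            if k:
                child_seq[mask] = (child_seq[mask]
                                   + rng.integers(1, 4, size=k,
                                                  dtype=np.int8)) % 4
            seq[ch] = child_seq
            stack.append(ch)
    return Locus(names=list(gtree.labels),
                 seqs=seq[: gtree.n_tips].copy(), h=h)


def simulate_dataset(stree: SpeciesTree, mig: MigrationSpec,
                     params: ParamSet, config: SampleConfig,
                     seed: int) -> list[tuple[GeneTree, Locus]]:
    """L independent loci (free recombination between, none within)."""
    counts = config.counts(stree)
    out = []
    for k in range(config.n_loci):
        rng = locus_rng(seed, k)
        g = simulate_gene_tree(stree, mig, params, counts, rng, h=config.h)
        loc = simulate_alignment(g, config.n_sites, rng, h=config.h)
        loc.label = f"locus{k + 1}"
        out.append((g, loc))
    return out


def bayesian_replicate(priors: PriorSpec, stree: SpeciesTree,
                       mig: MigrationSpec, config: SampleConfig,
                       rng: np.random.Generator
                       ) -> tuple[ParamSet, list[tuple[GeneTree, Locus]]]:
    """Draw Theta from the prior and simulate one replicate dataset."""
    params = sample_prior(priors, stree, mig, rng)
    seed = int(rng.integers(2**31 - 1))
    return params, simulate_dataset(stree, mig, params, config, seed)
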