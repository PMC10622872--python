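"""Benchmark simulation designs for the MSC-M sampler.

These are the standard three- and four-population isolation-with-migration
configurations used to exercise and validate the method: a three-species
tree with migration between the non-sister tips, the saturated
eight-rate three-species model, and classical population-genetic
stepping-stone / island models embedded as MSC-M models with very large
divergence times (so that all coalescence predates every divergence and
the species phylogeny carries no information).

Each builder returns ``(species_tree, migration_spec, generating_params)``
together with an analysis prior whose means sit near the generating
values: the root-age prior mean is 0.024 (generating value 0.02) and the
migration-rate prior mean equals the centre of the generating rates,
mirroring common practice for these benchmarks.
"""

from __future__ import annotations

import numpy as np

from .model import MigrationSpec, ParamSet, PriorSpec
from .species import SpeciesTree

__all__ = [
    "three_species_bc_migration",
    "three_species_saturated",
    "stepping_stone_four",
    "island_four",
]


def _three_species_base():
    st = SpeciesTree.from_newick("((A, B)S, C)R;")
    tau = np.zeros(st.n_nodes)
    tau[st.node("S")] = 0.01
    tau[st.node("R")] = 0.02
    theta = np.zeros(st.n_nodes)
    for lab, v in [("A", 0.015), ("S", 0.015),
                   ("B", 0.025), ("C", 0.025), ("R", 0.025)]:
        theta[st.node(lab)] = v
    return st, tau, theta


def three_species_bc_migration():
    """Three species, bidirectional migration between the non-sister tips.

    tauR = 0.02, tauS = 0.01, thetaA = thetaS = 0.015,
    thetaB = thetaC = thetaR = 0.025; M_BC = 0.2, M_CB = 0.1
    (the larger rate in the B -> C direction).
    """
    st, tau, theta = _three_species_base()
    mig = MigrationSpec(st, [("B", "C"), ("C", "B")])
    params = ParamSet(tau=tau, theta=theta, M=np.array([0.2, 0.1]))
    priors = PriorSpec(theta_shape=2, theta_rate=100,
                       tau_shape=2, tau_rate=2 / 0.024,
                       mig_shape=2, mig_rate=2 / 0.15)
    return st, mig, params, priors


def three_species_saturated():
    """Three species with all eight possible migration rates.

    Same tau/theta as :func:`three_species_bc_migration`; rates
    M_AB = 0.12, M_BA = 0.21, M_AC = 0.13, M_CA = 0.31, M_BC = 0.23,
    M_CB = 0.32, M_CS = 0.2, M_SC = 0.1.
    """
    st, tau, theta = _three_species_base()
    pairs = [("A", "B"), ("B", "A"), ("A", "C"), ("C", "A"),
             ("B", "C"), ("C", "B"), ("C", "S"), ("S", "C")]
    mig = MigrationSpec(st, pairs)
    M = np.array([0.12, 0.21, 0.13, 0.31, 0.23, 0.32, 0.2, 0.1])
    params = ParamSet(tau=tau, theta=theta, M=M)
    priors = PriorSpec(theta_shape=2, theta_rate=100,
                       tau_shape=2, tau_rate=2 / 0.024,
                       mig_shape=2, mig_rate=10)
    return st, mig, params, priors


def stepping_stone_four():
    """Linear stepping-stone model A - B - C - D as a deep MSC-M model.

    All population sizes theta0 = 0.002, adjacent-pair migration at
    M = 0.15 in both directions, and divergence times (1, 2, 3) that are
    ~1000 coalescent units deep, so every locus reaches its MRCA long
    before the first divergence: the ancestral sizes and the divergence
    times are then informed only by their priors.
    """
    st = SpeciesTree.from_newick("(((A, B)S, C)T, D)R;")
    tau = np.zeros(st.n_nodes)
    tau[st.node("S")] = 1.0
    tau[st.node("T")] = 2.0
    tau[st.node("R")] = 3.0
    theta = np.full(st.n_nodes, 0.002)
    pairs = [("A", "B"), ("B", "A"), ("B", "C"), ("C", "B"),
             ("C", "D"), ("D", "C")]
    mig = MigrationSpec(st, pairs)
    params = ParamSet(tau=tau, theta=theta, M=np.full(6, 0.15))
    priors = PriorSpec(theta_shape=2, theta_rate=1000,
                       tau_shape=2, tau_rate=1.0,
                       mig_shape=2, mig_rate=2 / 0.15)
    return st, mig, params, priors


def island_four():
    """Four-deme island model with a hub: A exchanges with B, C and D.

    theta_A = 10 theta0 with theta0 = 0.002 elsewhere; M = 0.15 on each
    connection; divergence times as in :func:`stepping_stone_four`.
    """
    st = SpeciesTree.from_newick("(((A, B)S, C)T, D)R;")
    tau = np.zeros(st.n_nodes)
    tau[st.node("S")] = 1.0
    tau[st.node("T")] = 2.0
    tau[st.node("R")] = 3.0
    theta = np.full(st.n_nodes, 0.002)
    theta[st.node("A")] = 0.02
    pairs = [("A", "B"), ("A", "C"), ("A", "D")]
    mig = MigrationSpec(st, pairs)
    params = ParamSet(tau=tau, theta=theta, M=np.full(3, 0.15))
    priors = PriorSpec(theta_shape=2, theta_rate=1000,
                       tau_shape=2, tau_rate=1.0,
                       mig_shape=2, mig_rate=2 / 0.15)
    return st, mig, params, priors
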