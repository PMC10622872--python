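"""Shared model builders for the test suite.

The three-species tree ((A,B)S,C)R with bidirectional B<->C migration is
the worked example used throughout; the four-species balanced tree carries
the ancestral S->C connection whose activity depends on tau ordering.
"""

import numpy as np
import pytest

from mscmig import MigrationSpec, ParamSet, PriorSpec, SpeciesTree
from mscmig.model import GeneTree


@pytest.fixture(scope="session")
def three_species():
    st = SpeciesTree.from_newick("((A,B)S,C)R;")
    mig = MigrationSpec(st, [("B", "C"), ("C", "B")])
    return st, mig


@pytest.fixture(scope="session")
def three_species_params(three_species):
    st, mig = three_species
    tau = np.zeros(st.n_nodes)
    tau[st.node("S")] = 0.01
    tau[st.node("R")] = 0.02
    theta = np.zeros(st.n_nodes)
    for lab, v in [("A", 0.015), ("B", 0.025), ("C", 0.025),
                   ("S", 0.015), ("R", 0.025)]:
        theta[st.node(lab)] = v
    return ParamSet(tau=tau, theta=theta, M=np.array([0.23, 0.32]))


@pytest.fixture(scope="session")
def balanced_four_species():
    st = SpeciesTree.from_newick("((A,B)S,(C,D)T)R;")
    mig = MigrationSpec(st, [("S", "C")])
    return st, mig


@pytest.fixture(scope="session")
def default_priors():
    return PriorSpec(theta_shape=2, theta_rate=100, tau_shape=2,
                     tau_rate=100, mig_shape=2, mig_rate=10)


def join(g: GeneTree, a: int, b: int, nd: int, t: float, pop: int) -> None:
    g.children[nd, 0] = a
    g.children[nd, 1] = b
    g.parent[a] = nd
    g.parent[b] = nd
    g.time[nd] = t
    g.node_pop[nd] = pop


def build_fig_tree(st, times, s_times):
    """The worked six-sequence genealogy: two sequences per species,
    coalescences t1<t2<t3<t4<t5, one lineage visiting C between s1 and s2."""
    t1, t2, t3, t4, t5 = times
    s1, s2 = s_times
    nA, nB, nC, nS, nR = (st.node(x) for x in "ABCSR")
    g = GeneTree(6, ["A^1", "A^2", "B^1", "B^2", "C^1", "C^2"],
                 np.array([nA, nA, nB, nB, nC, nC]))
    join(g, 0, 1, 6, t1, nA)
    join(g, 4, 5, 7, t2, nC)
    join(g, 2, 3, 8, t3, nS)
    join(g, 6, 8, 9, t4, nR)
    join(g, 7, 9, 10, t5, nR)
    g.root = 10
    g.edge_events[3] = [[s1, float(nC), float(nB)],
                        [s2, float(nB), float(nC)]]
    return g


@pytest.fixture(scope="session")
def fig_times():
    return (0.002, 0.004, 0.013, 0.025, 0.031), (0.005, 0.007)
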