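"""Structured-coalescent simulator: closed-form checks and reproducibility."""

import math

import numpy as np
import pytest

from mscmig import (MigrationSpec, ParamSet, SampleConfig, SpeciesTree,
                    phi0, simulate_alignment, simulate_dataset,
                    simulate_gene_tree)
from mscmig.simulate import locus_rng


@pytest.fixture(scope="module")
def pair_model():
    """Effectively a single population: two sequences from A, huge tauR."""
    st = SpeciesTree.from_newick("(A,B)R;")
    mig = MigrationSpec(st, [])
    tau = np.zeros(st.n_nodes)
    tau[st.root] = 1e3
    theta = np.full(st.n_nodes, 0.01)
    return st, mig, ParamSet(tau, theta, np.zeros(0))


class TestGeneTreeSimulation:
    def test_pairwise_coalescent_mean_is_half_theta(self, pair_model):
        st, mig, params = pair_model
        rng = np.random.default_rng(0)
        times = np.array([
            simulate_gene_tree(st, mig, params, {"A": 2}, rng).time[2]
            for _ in range(20000)])
        # Exp(2/theta): mean theta/2 = 0.005
        assert times.mean() == pytest.approx(0.005, rel=0.03)

    def test_inactive_entry_produces_no_events(self, balanced_four_species):
        # tauS >= tauT: the S->C connection never opens
        st, mig = balanced_four_species
        tau = np.zeros(st.n_nodes)
        tau[st.node("T")] = 0.010
        tau[st.node("S")] = 0.015
        tau[st.node("R")] = 0.020
        params = ParamSet(tau, np.full(st.n_nodes, 0.01), np.array([5.0]))
        rng = np.random.default_rng(1)
        assert all(
            simulate_gene_tree(st, mig, params, 2, rng).n_migrations == 0
            for _ in range(200))

    def test_lineage_escape_frequency_matches_phi0(self):
        # one entry R->Q: a lineage sampled in Q leaves before tau_d with
        # probability 1 - exp(-4 M tau_d / theta_Q)
        st = SpeciesTree.from_newick("(Q,R)D;")
        mig = MigrationSpec(st, [("R", "Q")])
        tau = np.zeros(st.n_nodes)
        tau_d = 0.008
        tau[st.root] = tau_d
        theta = np.full(st.n_nodes, 0.01)
        M = 0.12
        params = ParamSet(tau, theta, np.array([M]))
        rng = np.random.default_rng(2)
        n = 20000
        hits = 0
        for _ in range(n):
            g = simulate_gene_tree(st, mig, params, {"Q": 1, "R": 1}, rng)
            q_tip = g.labels.index("Q^1")
            evs = [e for e in g.edge_events[q_tip] if e[0] < tau_d]
            hits += bool(evs)
        p_exp = phi0(M, tau_d, 0.01)
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(hits / n - p_exp) < 3 * se

    def test_event_rate_matches_backward_migration_rate(self):
        # mean s->j events per unit lineage-time in j is 4 M / theta_j
        st = SpeciesTree.from_newick("(A,B)R;")
        mig = MigrationSpec(st, [("B", "A")])
        tau = np.zeros(st.n_nodes)
        tau[st.root] = 0.004
        theta = np.full(st.n_nodes, 0.01)
        M = 0.25
        params = ParamSet(tau, theta, np.array([M]))
        rng = np.random.default_rng(3)
        from mscmig.density import decompose
        events = 0.0
        exposure = 0.0
        for _ in range(4000):
            g = simulate_gene_tree(st, mig, params, {"A": 1, "B": 1}, rng)
            dec = decompose(g, st, tau, mig)
            events += dec.w[0]
            exposure += dec.mig_exposure[0]
        assert events / exposure == pytest.approx(4 * M / 0.01, rel=0.05)

    def test_msc_topology_concordance_closed_form(self):
        # M = 0, one sequence per species: P(((A,B),C) topology)
        # = 1 - (2/3) exp(-2 (tauR - tauS) / thetaS)
        st = SpeciesTree.from_newick("((A,B)S,C)R;")
        mig = MigrationSpec(st, [])
        tau = np.zeros(st.n_nodes)
        tau[st.node("S")], tau[st.node("R")] = 0.01, 0.016
        theta = np.full(st.n_nodes, 0.02)
        params = ParamSet(tau, theta, np.zeros(0))
        rng = np.random.default_rng(4)
        n = 6000
        conc = 0
        for _ in range(n):
            g = simulate_gene_tree(st, mig, params, 1, rng)
            first = int(np.argmin(
                np.where(g.children[:, 0] >= 0, g.time, np.inf)))
            kids = {int(g.children[first, 0]), int(g.children[first, 1])}
            conc += kids == {0, 1}  # a1 with b1 first
        p_exp = 1 - (2 / 3) * math.exp(-2 * 0.006 / 0.02)
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(conc / n - p_exp) < 3.5 * se


class TestAlignmentSimulation:
    def test_zero_branch_lengths_give_identical_sequences(self, pair_model):
        st, mig, params = pair_model
        from conftest import join
        from mscmig.model import GeneTree
        g = GeneTree(2, ["A^1", "A^2"], np.array([0, 0]))
        join(g, 0, 1, 2, 0.0, 0)
        g.time[2] = 0.0
        g.root = 2
        loc = simulate_alignment(g, 300, np.random.default_rng(5))
        assert np.array_equal(loc.seqs[0], loc.seqs[1])

    def test_pairwise_divergence_matches_jc_expectation(self):
        from conftest import join
        from mscmig.model import GeneTree
        g = GeneTree(2, ["A^1", "A^2"], np.array([0, 0]))
        d = 0.2  # total path length 2 * 0.1
        join(g, 0, 1, 2, d / 2, 0)
        g.root = 2
        loc = simulate_alignment(g, 100000, np.random.default_rng(6))
        frac = float((loc.seqs[0] != loc.seqs[1]).mean())
        expected = 0.75 * (1 - math.exp(-4 * d / 3))
        assert frac == pytest.approx(expected, abs=3 * math.sqrt(
            expected * (1 - expected) / 100000) + 1e-4)

    def test_seeded_runs_bit_identical(self, three_species,
                                       three_species_params):
        st, mig = three_species
        cfg = SampleConfig(n_seq=2, n_loci=3, n_sites=40)
        d1 = simulate_dataset(st, mig, three_species_params, cfg, seed=9)
        d2 = simulate_dataset(st, mig, three_species_params, cfg, seed=9)
        for (g1, l1), (g2, l2) in zip(d1, d2):
            assert np.array_equal(l1.seqs, l2.seqs)
            assert np.array_equal(g1.time, g2.time)


class TestDatasetAssembly:
    def test_locus_identical_alone_or_in_batch(self, three_species,
                                               three_species_params):
        st, mig = three_species
        p = three_species_params
        cfg = SampleConfig(n_seq=2, n_loci=5, n_sites=30)
        batch = simulate_dataset(st, mig, p, cfg, seed=13)
        for k in (0, 2, 4):
            rng = locus_rng(13, k)
            g = simulate_gene_tree(st, mig, p, cfg.counts(st), rng)
            loc = simulate_alignment(g, 30, rng)
            assert np.array_equal(batch[k][1].seqs, loc.seqs)

    def test_empty_dataset(self, three_species, three_species_params):
        st, mig = three_species
        cfg = SampleConfig(n_seq=2, n_loci=0, n_sites=30)
        assert simulate_dataset(st, mig, three_species_params, cfg,
                                seed=1) == []

    def test_dimensions_follow_design(self, three_species,
                                      three_species_params):
        st, mig = three_species
        cfg = SampleConfig(n_seq=4, n_loci=6, n_sites=120)
        data = simulate_dataset(st, mig, three_species_params, cfg, seed=2)
        assert len(data) == 6
        for g, loc in data:
            assert loc.seqs.shape == (12, 120)
            assert g.n_tips == 12
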