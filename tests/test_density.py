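"""Gene-tree density: decomposition, the worked-example oracle, phi0."""

import math

import numpy as np
import pytest

from conftest import build_fig_tree, join

from mscmig import (MigrationSpec, ParamSet, SpeciesTree, log_density_mscm,
                    log_density_fig1b_oracle, phi0, simulate_gene_tree)
from mscmig.density import (InconsistentGenealogy, decompose,
                            locus_stats, log_density_from_stats)
from mscmig.model import GeneTree


class TestDecompose:
    def test_worked_example_species_b_segments(self, three_species,
                                               three_species_params,
                                               fig_times):
        # B's boundaries are {0, s1, s2, tauS} with 2, 1, 2 lineages and
        # one inbound C->B migration event
        st, mig = three_species
        times, s_times = fig_times
        g = build_fig_tree(st, times, s_times)
        dec = decompose(g, st, three_species_params.tau, mig)
        segB = dec.segments[st.node("B")]
        s1, s2 = s_times
        np.testing.assert_allclose(segB.start, [0.0, s1, s2])
        np.testing.assert_allclose(segB.duration,
                                   [s1, s2 - s1, 0.01 - s2])
        assert segB.n_lineages.tolist() == [2, 1, 2]
        assert dec.w[mig.index("C", "B")] == 1
        assert dec.w[mig.index("B", "C")] == 1

    def test_single_population_single_segment(self):
        st = SpeciesTree.from_newick("(A,B)R;")
        mig = MigrationSpec(st, [])
        tau = np.zeros(st.n_nodes)
        tau[st.root] = 10.0
        g = GeneTree(2, ["A^1", "A^2"], np.array([0, 0]))
        join(g, 0, 1, 2, 0.004, 0)
        g.root = 2
        dec = decompose(g, st, tau, mig)
        segA = dec.segments[0]
        # one segment with both lineages; anything after the coalescence
        # holds a single lineage and contributes no exposure
        assert segA.duration[0] == pytest.approx(0.004)
        assert segA.n_lineages[0] == 2
        assert all(n <= 1 for n in segA.n_lineages[1:])
        assert dec.c[0] == 1
        assert dec.coal_exposure[0] == pytest.approx(2 * 0.004)

    def test_invariants_on_simulated_trees(self, three_species,
                                           three_species_params):
        st, mig = three_species
        rng = np.random.default_rng(3)
        for _ in range(300):
            g = simulate_gene_tree(st, mig, three_species_params, 2, rng)
            dec = decompose(g, st, three_species_params.tau, mig)
            assert dec.c.sum() == g.n_tips - 1
            assert dec.w.sum() == g.n_migrations
            # per-population lineage-time identity
            for seg in dec.segments:
                lt = float(np.sum(seg.n_lineages * seg.duration))
                nn1 = float(np.sum(seg.n_lineages
                                   * (seg.n_lineages - 1) * seg.duration))
                assert nn1 == pytest.approx(
                    dec.coal_exposure[seg.pop], abs=1e-12)
                assert lt >= 0

    def test_inconsistent_tree_raises_structured_error(
            self, three_species, three_species_params, fig_times):
        st, mig = three_species
        times, s_times = fig_times
        g = build_fig_tree(st, times, s_times)
        g.edge_events[3][0][2] = float(st.node("A"))  # impossible path
        with pytest.raises(InconsistentGenealogy):
            decompose(g, st, three_species_params.tau, mig)


class TestDensity:
    def test_single_pair_closed_form(self):
        # one population, theta = 0.01, coalescence at t = 0.005:
        # log(2/theta) - (2/theta) t = log 200 - 1
        st = SpeciesTree.from_newick("(A,B)R;")
        mig = MigrationSpec(st, [])
        tau = np.zeros(st.n_nodes)
        tau[st.root] = 10.0
        theta = np.full(st.n_nodes, 0.01)
        g = GeneTree(2, ["A^1", "A^2"], np.array([0, 0]))
        join(g, 0, 1, 2, 0.005, 0)
        g.root = 2
        lp = log_density_mscm(g, ParamSet(tau, theta, np.zeros(0)), mig)
        assert lp == pytest.approx(math.log(200.0) - 1.0)

    def test_matches_hand_coded_oracle_on_random_draws(self, three_species):
        st, mig = three_species
        rng = np.random.default_rng(11)
        nS, nR = st.node("S"), st.node("R")
        for _ in range(100):
            tauS = rng.uniform(0.005, 0.02)
            tauR = tauS * rng.uniform(1.3, 3.0)
            pts = np.sort(rng.uniform(0, tauS, size=4))
            t1, t2, s1, s2 = pts
            t3 = rng.uniform(tauS, tauR)
            t4 = tauR * rng.uniform(1.01, 2.0)
            t5 = t4 * rng.uniform(1.01, 2.0)
            tau = np.zeros(st.n_nodes)
            tau[nS], tau[nR] = tauS, tauR
            theta = rng.uniform(0.005, 0.05, size=st.n_nodes)
            M = rng.uniform(0.01, 2.0, size=2)
            params = ParamSet(tau, theta, M)
            g = build_fig_tree(st, (t1, t2, t3, t4, t5), (s1, s2))
            got = log_density_mscm(g, params, mig)
            want = log_density_fig1b_oracle(st, params, mig,
                                            (t1, t2, t3, t4, t5), (s1, s2))
            assert abs(got - want) < 1e-10

    def test_fast_stats_path_equals_decomposition(self, three_species,
                                                  three_species_params):
        st, mig = three_species
        rng = np.random.default_rng(5)
        p = three_species_params
        for _ in range(50):
            g = simulate_gene_tree(st, mig, p, 2, rng)
            rows = locus_stats(g, st, p.tau, mig)
            fast = log_density_from_stats(rows[0], rows[1], rows[2],
                                          rows[3], p.theta, p.M, mig)
            assert fast == pytest.approx(log_density_mscm(g, p, mig),
                                         abs=1e-10)

    def test_no_migration_reduces_to_plain_msc(self, three_species):
        # with M = 0 and no events, the density equals an independently
        # coded MSC-only density (per-population piecewise integration)
        st, _ = three_species
        mig0 = MigrationSpec(st, [])
        tau = np.zeros(st.n_nodes)
        tau[st.node("S")], tau[st.node("R")] = 0.01, 0.02
        theta = np.array([0.015, 0.025, 0.025, 0.015, 0.025])
        params = ParamSet(tau, theta, np.zeros(0))
        rng = np.random.default_rng(17)
        for _ in range(100):
            g = simulate_gene_tree(st, mig0, params, 2, rng)
            got = log_density_mscm(g, params, mig0)
            want = _msc_density_reference(g, st, tau, theta)
            assert got == pytest.approx(want, abs=1e-9)

    def test_heredity_rescaling_invariance(self, three_species,
                                           three_species_params, fig_times):
        # replacing (theta -> theta h, h -> 1) leaves the density unchanged
        st, mig = three_species
        times, s_times = fig_times
        g = build_fig_tree(st, times, s_times)
        p = three_species_params
        h = 0.75
        scaled = ParamSet(p.tau, p.theta * h, p.M)
        assert log_density_mscm(g, p, mig, h=h) == pytest.approx(
            log_density_mscm(g, scaled, mig, h=1.0), abs=1e-10)

    def test_migration_event_with_zero_rate_is_impossible(
            self, three_species, three_species_params, fig_times):
        st, mig = three_species
        times, s_times = fig_times
        g = build_fig_tree(st, times, s_times)
        p = three_species_params.copy()
        p.M[:] = 0.0
        assert log_density_mscm(g, p, mig) == -math.inf

    def test_normalisation_by_importance_sampling(self, three_species):
        # E_sim(Theta')[ p(G|Theta) / p(G|Theta') ] = 1 when both densities
        # are normalised against the simulator's measure
        st, mig = three_species
        tau = np.zeros(st.n_nodes)
        tau[st.node("S")], tau[st.node("R")] = 0.01, 0.02
        theta = np.full(st.n_nodes, 0.02)
        p_tgt = ParamSet(tau, theta, np.array([0.3, 0.2]))
        p_sim = ParamSet(tau, theta * 1.15, np.array([0.35, 0.25]))
        rng = np.random.default_rng(23)
        n = 4000
        ratios = np.empty(n)
        for k in range(n):
            g = simulate_gene_tree(st, mig, p_sim, 2, rng)
            ratios[k] = math.exp(log_density_mscm(g, p_tgt, mig)
                                 - log_density_mscm(g, p_sim, mig))
        se = ratios.std(ddof=1) / math.sqrt(n)
        assert abs(ratios.mean() - 1.0) < 3 * se


def _msc_density_reference(g, st, tau, theta):
    """Independent MSC (no migration) log density: explicit per-population
    bookkeeping of lineage counts between sorted event times."""
    lab_of = {}
    for v in range(g.n_nodes):
        if g.children[v, 0] >= 0:
            lab_of[float(g.time[v])] = int(g.node_pop[v])
    # population membership of each lineage over time, no migration:
    # a lineage is in the ancestor of its starting population
    events = sorted(lab_of)
    pops = list(range(st.n_nodes))
    lp = 0.0
    for j in pops:
        start, end = st.lifespan(j, tau)
        # walk this population's interval, tracking how many lineages
        bounds = [start] + [t for t in events if start < t < end] + [end]
        for k in range(len(bounds) - 1):
            a, b = bounds[k], bounds[k + 1]
            if not b > a:
                continue
            mid = 0.5 * (a + b) if math.isfinite(b) else a + 1.0
            n = _lineages_in(g, st, tau, j, mid)
            if math.isfinite(b):
                lp -= n * (n - 1) / theta[j] * (b - a)
        for t, pj in lab_of.items():
            if pj == j:
                lp += math.log(2.0 / theta[j])
    return lp


def _lineages_in(g, st, tau, pop, t):
    n = 0
    for v in range(g.n_nodes):
        p = int(g.parent[v])
        if p == -1:
            if v == g.root and g.time[v] <= t:
                n += int(st.ancestor_at(int(g.node_pop[v]), t, tau) == pop)
            continue
        if g.time[v] <= t < g.time[p]:
            n += int(st.ancestor_at(int(g.node_pop[v]), t, tau) == pop)
    return n


class TestPhi0:
    def test_zero_rate_gives_zero(self):
        assert phi0(0.0, 0.01, 0.01) == 0.0

    def test_direct_evaluation(self):
        assert phi0(0.1, 0.01, 0.01) == pytest.approx(
            1.0 - math.exp(-0.4))

    def test_monotone_in_rate_and_saturates(self):
        vals = [phi0(m, 0.01, 0.01) for m in (0.01, 0.1, 0.5, 1.0, 2.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert phi0(100.0, 0.01, 0.01) == pytest.approx(1.0, abs=1e-12)

    def test_zero_theta_rejected(self):
        with pytest.raises(ValueError):
            phi0(0.1, 0.01, 0.0)
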