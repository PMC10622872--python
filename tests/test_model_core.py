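"""Domain types: model validation, activity windows, priors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from mscmig import (MigrationSpec, ParamSet, PriorSpec, SpeciesTree,
                    active_migration_entries, log_prior, sample_prior,
                    simulate_gene_tree, validate_model)
from mscmig.model import gamma_logpdf, log_order_constant


class TestValidateModel:
    def test_clean_model_passes(self, three_species, three_species_params):
        st, mig = three_species
        assert validate_model(st, mig, three_species_params) == []

    def test_inactive_ancestral_entry_flagged(self, balanced_four_species):
        # S->C exists only while tauS < tauT; otherwise it is reported
        st, mig = balanced_four_species
        tau = np.zeros(st.n_nodes)
        tau[st.node("S")] = 0.015
        tau[st.node("T")] = 0.010
        tau[st.node("R")] = 0.020
        params = ParamSet(tau, np.full(st.n_nodes, 0.01), np.array([0.1]))
        problems = validate_model(st, mig, params)
        assert len(problems) == 1 and "inactive" in problems[0]

    def test_zero_theta_flagged(self, three_species, three_species_params):
        st, mig = three_species
        bad = three_species_params.copy()
        bad.theta[st.node("A")] = 0.0
        assert any("theta" in p for p in validate_model(st, mig, bad))


class TestActiveEntries:
    def test_ancestral_entry_follows_tau_order(self, balanced_four_species):
        st, mig = balanced_four_species
        tau = np.zeros(st.n_nodes)
        tau[st.node("T")] = 0.010
        tau[st.node("R")] = 0.020
        tau[st.node("S")] = 0.005
        assert active_migration_entries(st, mig, tau) == {("S", "C")}
        tau[st.node("S")] = 0.015
        assert active_migration_entries(st, mig, tau) == set()

    def test_tip_pair_always_active(self, three_species):
        st, _ = three_species
        mig = MigrationSpec(st, [("A", "B")])
        tau = np.zeros(st.n_nodes)
        tau[st.node("S")] = 1e-6
        tau[st.node("R")] = 2e-6
        assert active_migration_entries(st, mig, tau) == {("A", "B")}

    @settings(max_examples=30, deadline=None)
    @given(scale=hst.floats(0.05, 1.0))
    def test_shrinking_lifespans_never_adds_entries(self,
                                                    balanced_four_species,
                                                    scale):
        # shrinking tauS's distance to tauT can only deactivate S->C
        st, mig = balanced_four_species
        tau = np.zeros(st.n_nodes)
        tau[st.node("T")] = 0.010
        tau[st.node("R")] = 0.020
        tau[st.node("S")] = 0.009
        base = active_migration_entries(st, mig, tau)
        tau2 = tau.copy()
        tau2[st.node("S")] = 0.009 + (1 - scale) * 0.002  # move toward tauT
        assert active_migration_entries(st, mig, tau2) <= base


class TestPriors:
    def test_exponential_case_closed_form(self, three_species):
        # gamma(1, 100) at theta = 0.01 is 100 * exp(-1)
        assert gamma_logpdf(0.01, 1.0, 100.0) == pytest.approx(
            math.log(100.0) - 1.0)

    def test_negative_rate_is_minus_inf(self, three_species,
                                        default_priors):
        st, mig = three_species
        tau = np.zeros(st.n_nodes)
        tau[st.node("S")], tau[st.node("R")] = 0.01, 0.02
        p = ParamSet(tau, np.full(st.n_nodes, 0.01), np.array([-0.1, 0.2]))
        assert log_prior(p, default_priors, st, mig) == -math.inf

    def test_joint_prior_is_sum_of_marginals(self, three_species,
                                             three_species_params,
                                             default_priors):
        st, mig = three_species
        p, pri = three_species_params, default_priors
        expected = sum(gamma_logpdf(float(th), pri.theta_shape,
                                    pri.theta_rate) for th in p.theta)
        expected += gamma_logpdf(float(p.tau[st.root]), pri.tau_shape,
                                 pri.tau_rate)
        # one non-root age, uniform on (0, tau_root)
        expected += log_order_constant(st) - math.log(p.tau[st.root])
        expected += sum(gamma_logpdf(float(m), pri.mig_shape, pri.mig_rate)
                        for m in p.M)
        assert log_prior(p, pri, st, mig) == pytest.approx(expected)

    def test_sampling_matches_gamma_mean_and_is_deterministic(
            self, three_species, default_priors):
        st, mig = three_species
        rng = np.random.default_rng(0)
        draws = np.array([sample_prior(default_priors, st, mig, rng)
                          .theta[0] for _ in range(20000)])
        assert draws.mean() == pytest.approx(0.02, rel=0.02)
        a = sample_prior(default_priors, st, mig,
                         np.random.default_rng(42))
        b = sample_prior(default_priors, st, mig,
                         np.random.default_rng(42))
        assert np.array_equal(a.tau, b.tau) and np.array_equal(a.M, b.M)

    def test_prior_draw_log_density_round_trip(self, three_species,
                                               default_priors):
        st, mig = three_species
        rng = np.random.default_rng(1)
        for _ in range(500):
            p = sample_prior(default_priors, st, mig, rng)
            assert math.isfinite(log_prior(p, default_priors, st, mig))

    def test_order_constant_ladder_tree(self):
        # ladder ((((A,B)S,C)T,D)U,E)R: the non-root internal nodes
        # S < T < U form a chain, so only 1 of the 3! orderings of iid
        # uniforms is admissible: the constant is 3! (hook lengths 1,2,3)
        st = SpeciesTree.from_newick("((((A,B)S,C)T,D)U,E)R;")
        assert log_order_constant(st) == pytest.approx(math.log(6.0))

    def test_invalid_gamma_raises(self):
        with pytest.raises(ValueError):
            PriorSpec(theta_shape=0.0)


class TestGeneTreeInvariants:
    def test_simulated_trees_all_pass_checker(self, three_species,
                                              three_species_params):
        st, mig = three_species
        rng = np.random.default_rng(7)
        for _ in range(1000):
            g = simulate_gene_tree(st, mig, three_species_params, 2, rng)
            assert g.validate(st, three_species_params.tau, mig) == []

    def test_checker_catches_bad_event_population(self, three_species,
                                                  three_species_params,
                                                  fig_times):
        from conftest import build_fig_tree
        st, mig = three_species
        times, s_times = fig_times
        g = build_fig_tree(st, times, s_times)
        # relabel the first event to claim the lineage leaves A instead of B
        g.edge_events[3][0][2] = float(st.node("A"))
        assert g.validate(st, three_species_params.tau, mig) != []
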