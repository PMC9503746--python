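"""Tests for the ligation/scission network builder, filter and Gillespie simulator."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyquench.equilibrium import EnsembleConfig, solve_bath_monomer_density
from polyquench.errors import FeasibilityError
from polyquench.quench_theory import KineticParams, p_effective
from polyquench.reaction_network import (
    QuenchProtocol,
    build_network,
    enumerate_species,
    expected_reaction_count,
    filter_kinetic_traps,
    length_histogram,
    simulate,
    simulate_quench,
    state_summary,
)
from polyquench.synthetic_data import generate_sim_fixture

FAST_KINETICS = KineticParams(delta_a_mean=500.0, sigma=100.0, fa=1.0, texpt=1e12, T=600.0)


def _small_network(b=2, lmax=3, seed=1, delta=-600.0, kin=FAST_KINETICS, rho=1e-3):
    cfg = EnsembleConfig(b=b, lmax=lmax, delta=delta)
    return cfg, build_network(cfg, kin, seed, reference_beta_delta=-1.0, reference_rho_vp=rho)


class TestNetworkConstruction:
    def test_single_letter_dimer_network(self):
        cfg, net = _small_network(b=1, lmax=2)
        assert net.species == ["A", "AA"]
        assert net.n_reactions == 1

    def test_reaction_count_matches_enumeration_oracle(self):
        """Σ b^L(L-1) against a from-scratch itertools enumeration."""
        cfg, net = _small_network(b=2, lmax=3)
        oracle = sum(
            len(s) - 1
            for L in range(2, 4)
            for s in map("".join, itertools.product("AC", repeat=L))
        )
        assert oracle == 20
        assert net.n_reactions == oracle == expected_reaction_count(2, 3)

    def test_fragments_concatenate_to_parent(self):
        _, net = _small_network(b=3, lmax=4)
        for r in net.iter_reactions():
            assert "".join(r.fragments) == r.parent
            assert 1 <= r.cut_index <= len(r.parent) - 1
            assert r.delta_a >= 0 and r.kd > 0

    def test_activation_energies_deterministic_per_seed(self):
        _, a = _small_network(seed=11)
        _, b = _small_network(seed=11)
        _, c = _small_network(seed=12)
        np.testing.assert_array_equal(a.delta_a, b.delta_a)
        assert not np.array_equal(a.delta_a, c.delta_a)

    def test_enumeration_guard(self):
        with pytest.raises(FeasibilityError, match="guard"):
            enumerate_species(20, 10)

    def test_kd_depends_only_on_fragment_lengths(self):
        """Equal-energy coarse graining: k_d² = n̄_{L2}n̄_{L3}/n̄_{L1} with the
        b^L sequence factors cancelling exactly."""
        cfg, net = _small_network(b=2, lmax=4)
        ref = net.reference.occupancies
        lengths = net.lengths
        for i in range(net.n_reactions):
            L1 = lengths[net.parent_idx[i]]
            L2 = lengths[net.frag1_idx[i]]
            L3 = lengths[net.frag2_idx[i]]
            assert net.kd[i] == pytest.approx(
                np.sqrt(ref[L2 - 1] * ref[L3 - 1] / ref[L1 - 1]), rel=1e-12
            )


class TestKineticTrapFilter:
    def test_zero_temperature_freezes_everything(self, peptide_kinetics):
        _, net = _small_network(b=2, lmax=4, kin=peptide_kinetics)
        frozen = filter_kinetic_traps(net, 0.0, peptide_kinetics)
        assert frozen.n_reactions == 0
        assert frozen.realized_p == 0.0

    def test_narrow_disorder_above_tc_keeps_everything(self):
        kin = KineticParams(delta_a_mean=1.2e4, sigma=1.0, fa=1.3e7, texpt=9.468e6)
        _, net = _small_network(b=2, lmax=4, kin=kin, delta=-1200.0)
        kept = filter_kinetic_traps(net, 1.2 * kin.tc, kin)
        assert kept.realized_p == 1.0

    def test_retained_fraction_matches_p_eff_on_large_network(self):
        """≥1e4 reactions at T=T_c, ξ=2: realized p within 3 binomial SE of
        erf(2)/(erf(2)+1)."""
        kin = KineticParams(delta_a_mean=1.2e4, sigma=6000.0, fa=1.3e7, texpt=9.468e6)
        cfg = EnsembleConfig(b=4, lmax=6, delta=-1200.0)
        net = build_network(cfg, kin, seed=3, reference_beta_delta=-2.0)
        assert net.n_reactions >= 10_000
        kept = filter_kinetic_traps(net, kin.tc, kin)
        target = p_effective(kin.tc, kin)
        se = np.sqrt(target * (1 - target) / net.n_reactions)
        assert abs(kept.realized_p - target) < 3 * se


class TestSimulate:
    def test_fully_filtered_network_is_frozen(self, peptide_kinetics):
        _, net = _small_network(b=2, lmax=3, kin=peptide_kinetics, delta=-1200.0)
        frozen = filter_kinetic_traps(net, 0.0, peptide_kinetics)
        init = generate_sim_fixture(2, 3, 500, seed=0, omega=1e3)
        traj = simulate(frozen, init, peptide_kinetics, 300.0, t_end=10.0, seed=0)
        assert traj.n_events == 0
        np.testing.assert_array_equal(traj.final_state.copy_numbers, init.copy_numbers)
        assert traj.final_state.time == 10.0

    def test_dimerization_toy_matches_mean_field_fixed_point(self):
        """b=1, lmax=2 (A ⇌ AA): the long-run ⟨N_A⟩ must sit at the root of
        k_d·c_AA = c_A²/k_d with 2c_AA + c_A = c_tot."""
        cfg = EnsembleConfig(b=1, lmax=2, delta=-600.0)
        bath = solve_bath_monomer_density(-1.0, 0.05, cfg)
        omega, m_vp = 1e4, 0.05
        net = build_network(
            cfg, FAST_KINETICS, seed=2,
            reference_beta_delta=-1.0, reference_rho_vp=bath.rho_vp,
        )
        init = generate_sim_fixture(1, 2, int(omega * m_vp), seed=2, omega=omega)
        traj = simulate(
            net, init, FAST_KINETICS, 600.0, t_end=1e9, seed=5,
            max_events=150_000, average_after=30.0,
        )
        kd = float(net.kd[0])
        a = 2.0 / kd**2
        c_a = (-1 + np.sqrt(1 + 4 * a * m_vp)) / (2 * a)
        sd = np.sqrt(omega * c_a)  # Poisson scale of the stationary count
        assert abs(traj.mean_histogram[0] - omega * c_a) < 3 * sd / np.sqrt(10)

    def test_long_run_histogram_matches_bath_equilibrium(self):
        """Detailed balance across modules: unfiltered b=2, lmax=4 network at
        fixed T relaxes to the equilibrium solver's bath distribution."""
        cfg = EnsembleConfig(b=2, lmax=4, delta=-600.0)
        omega, m_vp = 3e5, 0.04
        bath = solve_bath_monomer_density(-1.0, m_vp, cfg)
        net = build_network(
            cfg, FAST_KINETICS, seed=7,
            reference_beta_delta=-1.0, reference_rho_vp=bath.rho_vp,
        )
        init = generate_sim_fixture(2, 4, int(round(omega * m_vp)), seed=7, omega=omega)
        traj = simulate(
            net, init, FAST_KINETICS, 600.0, t_end=1e9, seed=11,
            max_events=350_000, average_after=40.0,
        )
        theory = omega * bath.occupancies
        rel = np.abs(traj.mean_histogram / theory - 1.0)
        assert rel.max() < 0.05

    @given(
        b=st.integers(1, 3),
        lmax=st.integers(2, 4),
        seed=st.integers(0, 10**6),
    )
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_monomer_content_conserved_at_every_event(self, b, lmax, seed):
        """Property: random small networks, random seeds — the per-event
        conservation assertion never trips and the final content is exact."""
        cfg = EnsembleConfig(b=b, lmax=lmax, delta=-600.0)
        net = build_network(cfg, FAST_KINETICS, seed, reference_beta_delta=-1.0)
        init = generate_sim_fixture(b, lmax, 300, seed=seed, omega=500.0)
        traj = simulate(
            net, init, FAST_KINETICS, 600.0, t_end=1e9, seed=seed,
            max_events=2_000, check_conservation=True,
        )
        assert traj.final_state.monomer_content() == 300


class TestQuenchProtocol:
    def test_inverted_protocol_rejected(self):
        with pytest.raises(FeasibilityError):
            QuenchProtocol(T_hot=300.0, t_hot=1.0, T_cold=600.0, t_cold=1.0)

    def test_cold_phase_freezes_hot_distribution(self, peptide_kinetics):
        """After the switch the cold phase fires (essentially) no reactions,
        so the hot-phase histogram survives."""
        cfg = EnsembleConfig(b=2, lmax=4, delta=-1200.0)
        net = build_network(cfg, peptide_kinetics, seed=4, reference_beta_delta=-2.0)
        init = generate_sim_fixture(2, 4, 1000, seed=4, omega=4e3)
        protocol = QuenchProtocol(T_hot=600.0, t_hot=500.0, T_cold=300.0, t_cold=500.0)
        out = simulate_quench(
            net, init, peptide_kinetics, protocol, cfg, seed=4, max_events=60_000
        )
        assert out["realized_p"]["hot"] > 0.9
        assert out["realized_p"]["cold"] < 0.1
        hot_end = out["hot"].final_state
        np.testing.assert_array_equal(
            length_histogram(hot_end, 4), length_histogram(out["final_state"], 4)
        )


class TestStateSummary:
    def test_single_polymer_entropy_is_log_degeneracy(self):
        cfg = EnsembleConfig(b=2, lmax=3, delta=-600.0)
        state = generate_sim_fixture(2, 3, 3, seed=0, omega=100.0)
        state.copy_numbers[:] = 0
        state.copy_numbers[-1] = 1  # one trimer
        s = state_summary(state, cfg)
        expected = cfg.log_degeneracy(3)[2] + np.log(100.0)
        assert s["entropy"] == pytest.approx(expected, rel=1e-9)

    def test_even_odd_index_cancels_for_symmetric_histogram(self):
        cfg = EnsembleConfig(b=2, lmax=4, delta=-600.0)
        state = generate_sim_fixture(2, 4, 100, seed=0, omega=100.0)
        state.copy_numbers[:] = 0
        state.copy_numbers[2] = 5   # one dimer species (L=2)
        state.copy_numbers[6] = 5   # one trimer species (L=3)
        s = state_summary(state, cfg)
        assert s["even_odd_index"] == 0.0

    def test_simulated_entropy_below_equilibrium_maximum(self):
        """The solver's distribution maximizes S at fixed (e, ρ); any simulated
        state with the same moments can only do worse."""
        from scipy.special import gammaln

        from polyquench.equilibrium import solve_isolated_from_moments

        cfg = EnsembleConfig(b=2, lmax=4, delta=-600.0)
        net = build_network(cfg, FAST_KINETICS, seed=9, reference_beta_delta=-1.0)
        init = generate_sim_fixture(2, 4, 2000, seed=9, omega=5e4)
        traj = simulate(net, init, FAST_KINETICS, 600.0, 1e9, seed=9, max_events=30_000)
        s_sim = state_summary(traj.final_state, cfg)["entropy"]
        hist = length_histogram(traj.final_state, 4)
        bonds = (np.arange(4) * hist).sum()
        sol = solve_isolated_from_moments(
            cfg.log_degeneracy() + np.log(5e4), hist.sum(), bonds
        )
        G = np.exp(cfg.log_degeneracy() + np.log(5e4))
        s_max = sum(
            gammaln(n + g) - gammaln(n + 1) - gammaln(g)
            for n, g in zip(sol.occupancies, G)
        )
        assert s_sim <= s_max + 1e-6 * abs(s_max)
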