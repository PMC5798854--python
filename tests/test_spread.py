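import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import norm

from nexosim.network import NetworkConfig, build_network
from nexosim.spread import (active_transport_fractions, boundary_fraction,
                            build_spread_operators, build_z_matrix, cap_rows,
                            diffusion_matrix, geodesic_coefficients,
                            neighbour_fraction, settle_flows,
                            synaptic_transfer_flows)


class TestBoundaryFraction:
    def test_half_mass_for_zero_length(self):
        assert boundary_fraction(0.0, 50.0) == pytest.approx(0.5)

    def test_matches_normal_cdf(self):
        # L=100, sigma=50 -> Phi(-1)
        assert boundary_fraction(100.0, 50.0) == pytest.approx(0.158655, abs=1e-6)
        assert boundary_fraction(100.0, 50.0) == pytest.approx(norm.cdf(-1))

    def test_increases_with_diffusion_speed(self):
        speeds = [10.0, 50.0, 200.0, 1000.0]
        ys = [boundary_fraction(100.0, s) for s in speeds]
        assert all(a < b for a, b in zip(ys, ys[1:]))

    def test_rejects_nonpositive_speed(self):
        with pytest.raises(ValueError):
            boundary_fraction(10.0, 0.0)


class TestNeighbourFraction:
    def test_equal_areas_unit_weights(self):
        assert neighbour_fraction(0.3, 5.0, 5.0, 1.0, 1.0) == pytest.approx(0.3)

    def test_selectivity_scales_linearly(self):
        z1 = neighbour_fraction(0.3, 5.0, 5.0, 1.0, 1.0)
        z001 = neighbour_fraction(0.3, 5.0, 5.0, 1.0, 0.01)
        assert z001 == pytest.approx(z1 / 100)

    def test_small_target_limits_by_area_ratio(self):
        z = neighbour_fraction(0.4, 100.0, 1.0, 1.0, 1.0)
        assert z == pytest.approx(0.4 * 0.01)


def _push_oracle(Z, t_sig, source, tol=1e-9):
    """Brute-force scalar propagation: synchronous waves of pushes.

    Each wave, the amount a section received is compared against ``t_sig``;
    amounts at or below it settle, larger ones re-push (keeping the
    ``1 - sum(z)`` remainder).
    """
    n = Z.shape[0]
    Zd = Z.toarray()
    retain = 1.0 - Zd.sum(axis=1)
    settled = np.zeros(n)
    active = {source: 1.0}
    for _ in range(100_000):
        if not active:
            break
        incoming: dict = {}
        for sec, mass in active.items():
            if mass <= t_sig:
                settled[sec] += mass
                continue
            settled[sec] += mass * retain[sec]
            for dst in range(n):
                if Zd[sec, dst] > 0:
                    incoming[dst] = incoming.get(dst, 0.0) + mass * Zd[sec, dst]
        active = incoming
    assert abs(settled.sum() - 1.0) < tol
    return settled


class TestGeodesicCoefficients:
    def test_isolated_section_keeps_everything(self):
        Z = sp.csr_matrix((3, 3))
        d = geodesic_coefficients(Z)
        assert d[0, 0] == pytest.approx(1.0)

    def test_two_section_chain_matches_bruteforce(self):
        Z = sp.csr_matrix(np.array([[0.0, 0.1], [0.1, 0.0]]))
        d = geodesic_coefficients(Z, t_sig=1e-6).toarray()
        for src in range(2):
            oracle = _push_oracle(Z, 1e-6, src)
            assert np.allclose(d[src], oracle, atol=1e-9)

    def test_high_threshold_reduces_to_one_hop(self):
        Z = sp.csr_matrix(np.array([[0.0, 0.2, 0.05],
                                    [0.0, 0.0, 0.3],
                                    [0.0, 0.0, 0.0]]))
        d = geodesic_coefficients(Z, t_sig=0.5).toarray()
        # recursion never triggers: one-hop z plus remainder at source
        assert d[0, 1] == pytest.approx(0.2)
        assert d[0, 2] == pytest.approx(0.05)
        assert d[0, 0] == pytest.approx(0.75)

    def test_five_section_toy_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(0, 0.4, (5, 5))
        np.fill_diagonal(raw, 0.0)
        Z = cap_rows(sp.csr_matrix(raw), 0.9)
        d = geodesic_coefficients(Z, t_sig=1e-4).toarray()
        for src in range(5):
            oracle = _push_oracle(Z, 1e-4, src)
            assert np.allclose(d[src], oracle, atol=1e-6)

    def test_rows_are_distributions(self, small_net):
        Z = build_z_matrix(small_net, sigma_z=500.0)
        d = geodesic_coefficients(Z)
        sums = np.asarray(d.sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert d.min() >= 0


class TestDiffusionMatrix:
    def test_zero_mobile_fraction_is_identity(self, small_net):
        Z = build_z_matrix(small_net, sigma_z=50.0)
        d = geodesic_coefficients(Z)
        M = diffusion_matrix(d, 0.0)
        x = np.linspace(1, 2, small_net.n_sections)
        assert np.allclose(M.T @ x, x)

    def test_rows_sum_to_one(self, small_net):
        Z = build_z_matrix(small_net, sigma_z=500.0)
        M = diffusion_matrix(geodesic_coefficients(Z), 0.05)
        assert np.allclose(np.asarray(M.sum(axis=1)).ravel(), 1.0)

    def test_amount_conserved_under_pure_diffusion(self, small_net):
        Z = build_z_matrix(small_net, sigma_z=500.0)
        M = diffusion_matrix(geodesic_coefficients(Z), 0.05)
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, small_net.n_sections) * small_net.sec_volume * 1e-3
        total = x.sum()
        for _ in range(100):
            x = M.T @ x
        assert x.sum() == pytest.approx(total, rel=1e-12)

    def test_impulse_equals_push_procedure(self):
        """Applying M to a unit impulse reproduces the brute-force push."""
        rng = np.random.default_rng(7)
        raw = rng.uniform(0, 0.3, (5, 5))
        np.fill_diagonal(raw, 0.0)
        Z = cap_rows(sp.csr_matrix(raw), 0.9)
        f_pd = 0.05
        M = diffusion_matrix(geodesic_coefficients(Z, t_sig=1e-8), f_pd)
        for src in range(5):
            impulse = np.zeros(5)
            impulse[src] = 1.0
            got = M.T @ impulse
            oracle = _push_oracle(Z, 1e-8, src)
            expect = (1 - f_pd) * impulse + f_pd * oracle
            assert np.allclose(got, expect, atol=1e-6)


class TestSettleFlows:
    def test_plain_flow_when_no_overflow(self):
        F = sp.csr_matrix(np.array([[0.0, 0.5], [0.0, 0.0]]))
        V = np.array([1.0, 10.0])
        xn, xp, sat = settle_flows(np.array([0.4, 0.0]),
                                   np.array([0.2, 0.0]), F, V)
        assert sat == 0
        assert xn == pytest.approx([0.2, 0.2])
        assert xp == pytest.approx([0.1, 0.1])

    def test_overflow_scaled_back_and_returned(self):
        # destination volume 0.1 already half full; inflow must be capped
        F = sp.csr_matrix(np.array([[0.0, 0.9], [0.0, 0.0]]))
        V = np.array([10.0, 0.1])
        x = np.array([1.0, 0.05])
        xn, xp, sat = settle_flows(x.copy(), np.zeros(2), F, V)
        assert sat == 1
        assert xn.sum() == pytest.approx(1.05)     # mass conserved
        assert xn[1] <= V[1] + 1e-12               # cap respected
        assert xn[0] > 0.1                         # residue returned to source

    def test_two_species_share_capacity(self):
        F = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 0.0]]))
        V = np.array([1.0, 0.5])
        xn, xp, sat = settle_flows(np.array([0.6, 0.0]),
                                   np.array([0.6, 0.0]), F, V)
        assert sat == 1
        assert xn[1] + xp[1] <= V[1] + 1e-12
        assert xn[1] == pytest.approx(xp[1])  # proportional scale-back
        assert xn.sum() + xp.sum() == pytest.approx(1.2)


class TestActiveTransport:
    def test_zero_fraction_moves_nothing(self, tiny_net):
        F = active_transport_fractions(tiny_net, 0.0)
        assert F.nnz == 0

    def test_direction_probabilities_normalized(self):
        from nexosim.spread import ANTEROGRADE_P, RETROGRADE_P, STAY_P
        assert ANTEROGRADE_P + STAY_P + RETROGRADE_P == pytest.approx(1.0)

    def test_intraneuron_mass_conserved(self, tiny_net):
        F = active_transport_fractions(tiny_net, 0.001)
        V = tiny_net.sec_volume
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 0.5, tiny_net.n_sections) * V
        per_neuron = x.reshape(-1, 3).sum(axis=1)
        xn, xp, _ = settle_flows(x, np.zeros_like(x), F, V)
        assert np.allclose(xn.reshape(-1, 3).sum(axis=1), per_neuron,
                           rtol=1e-12)

    def test_rejects_invalid_fraction(self, tiny_net):
        with pytest.raises(ValueError):
            active_transport_fractions(tiny_net, 1.5)


class TestSynapticTransfer:
    def test_no_transfer_without_spikes_or_fst(self, small_net):
        ops = build_spread_operators(small_net, sigma_z=None, f_pd=0.05,
                                     f_at=0.0, f_st=1.0)
        none = synaptic_transfer_flows(
            ops, np.zeros(small_net.n_neurons, bool), small_net.n_sections)
        assert none is None
        ops0 = build_spread_operators(small_net, sigma_z=None, f_pd=0.05,
                                      f_at=0.0, f_st=0.0)
        spikes = np.ones(small_net.n_neurons, bool)
        assert synaptic_transfer_flows(ops0, spikes, small_net.n_sections) is None

    def test_single_synapse_release_fraction(self):
        cfg = NetworkConfig(n_columns=1,
                            composition=((2, "RS", 2),),
                            densities={"RS": 1.0})
        net = build_network(cfg, 0)
        # keep only one outgoing synapse for neuron 0
        keep = net.pre == 0
        net.pre, net.post_neuron = net.pre[keep], net.post_neuron[keep]
        net.post_section, net.strength = net.post_section[keep], net.strength[keep]
        net.selectivity = net.selectivity[keep]
        ops = build_spread_operators(net, sigma_z=None, f_pd=0.05,
                                     f_at=0.0, f_st=1.0)
        # normalization cancels: g = 0.154 * f_st
        assert ops.g[0] == pytest.approx(0.154)

    def test_release_fractions_sum_to_budget(self, small_net):
        ops = build_spread_operators(small_net, sigma_z=None, f_pd=0.05,
                                     f_at=0.0, f_st=1.0)
        per_neuron = np.zeros(small_net.n_neurons)
        np.add.at(per_neuron, ops.syn_pre, ops.g)
        has_out = np.zeros(small_net.n_neurons, bool)
        has_out[ops.syn_pre] = True
        assert np.allclose(per_neuron[has_out], 0.154)


class TestSelectivityDirection:
    def test_selectivity_accelerates_escape_from_seed_column(self):
        """With p favouring intercolumnar routes, protein leaves the seed
        column faster than with no selectivity (common random numbers)."""
        times = {}
        for p in (1.0, 100.0):
            from nexosim import SeedSpec, Simulation, SimulationConfig
            from nexosim.network import test_network_config
            cfg = SimulationConfig(
                network=test_network_config(), solubility="insoluble",
                seed=SeedSpec(kind="single", layer=2, cell_type="RS"),
                R_M=0.0, sigma_z=500.0, f_at=0.0,
                transfer_mode="off_increase", p_intercolumnar=p,
                horizon=4000, stop_when_all_dead=False)
            sim = Simulation(cfg, 11)
            outside = np.repeat(sim.net.column != 0, 3)
            level = 0.001
            t_hit = None
            for _ in range(cfg.horizon):
                sim.step()
                if (sim.Cp[outside].max() >= level):
                    t_hit = sim.t
                    break
            times[p] = t_hit
        assert times[100.0] is not None
        assert times[1.0] is None or times[100.0] < times[1.0]
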