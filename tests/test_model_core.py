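"""Reaction-network parsing, propensities and continuous-state derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import isophase as ip
from isophase.model_core import ModelParseError


BRUSS_K = dict(k1=0.025, k2=1.0, k3=1.0, k4=0.01)


class TestParsing:
    def test_brusselator_stoichiometry(self, brusselator):
        assert brusselator.species_names == ["X", "Y"]
        assert np.array_equal(brusselator.stoich,
                              [[1, -1, 1, -1], [0, 1, -1, 0]])

    @pytest.mark.parametrize("mutation, key", [
        (lambda d: d[:d.index("reactions:")] + "reactions: []\n", "reactions"),
        (lambda d: d.replace("volume: 250.0", "volume: -5"), "volume"),
        (lambda d: d.replace("{A: 1}", "{Qx: 1}"), "Qx"),
        (lambda d: d.replace("X: 2", "X: 1.5"), "stoichiometry"),
    ])
    def test_malformed_configs_name_the_offender(self, mutation, key):
        cfg = mutation(ip.fixtures.brusselator_config())
        with pytest.raises(ModelParseError, match=key):
            ip.parse_model(cfg)

    def test_serialize_round_trip(self, brusselator, oregonator):
        for net in (brusselator, oregonator):
            rt = ip.parse_model(ip.serialize_model(net))
            assert rt.species_names == net.species_names
            assert np.array_equal(rt.stoich, net.stoich)
            assert rt.constant_counts == net.constant_counts
            assert rt.volume == net.volume
            x = np.abs(net.initial_state) + 3
            assert np.allclose(rt.propensities(x), net.propensities(x))


class TestPropensities:
    def test_second_order_self_interaction_vanishes_at_one_molecule(self):
        net = ip.brusselator_model()
        a = net.propensities(np.array([1.0, 50.0]))
        assert a[2] == 0.0  # a3 = k3*Y*X*(X-1)/W^2 with X=1

    def test_printed_forms(self):
        net = ip.brusselator_model(volume=250.0, A_count=100.0, B_count=300.0)
        X, Y, W = 100.0, 50.0, 250.0
        a = net.propensities(np.array([X, Y]))
        assert a[0] == pytest.approx(BRUSS_K["k1"] * 100.0)
        assert a[1] == pytest.approx(BRUSS_K["k2"] * 300.0 * X / W)
        assert a[2] == pytest.approx(BRUSS_K["k3"] * Y * X * (X - 1) / W ** 2)
        assert a[3] == pytest.approx(BRUSS_K["k4"] * X)  # = 1 s^-1 at X=100

    def test_volume_scaling_of_bimolecular_rate(self):
        x = np.array([100.0, 50.0])
        a1 = ip.brusselator_model(volume=250.0).propensities(x)
        a2 = ip.brusselator_model(volume=500.0).propensities(x)
        assert a2[1] == pytest.approx(a1[1] / 2.0)   # a2 ~ 1/W
        assert a2[2] == pytest.approx(a1[2] / 4.0)   # a3 ~ 1/W^2

    def test_negative_state_rejected(self, brusselator):
        with pytest.raises(ValueError):
            brusselator.propensities(np.array([-1.0, 5.0]))
        # continuous mode tolerates and clamps
        a = brusselator.propensities(np.array([-1e-9, 5.0]), continuous=True)
        assert np.all(a >= 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(x=st.tuples(st.floats(0, 1e4), st.floats(0, 1e4)))
    def test_nonnegative_on_nonnegative_orthant(self, x):
        net = ip.brusselator_model()
        # X in [0,1] makes X(X-1) negative: the discrete combinatorial factor
        # is only meaningful at integer occupancy, so clamp-free evaluation
        # is checked away from that sliver
        xa = np.asarray(x)
        if 0 < xa[0] < 1:
            xa[0] = 0.0
        assert np.all(net.propensities(xa) >= 0.0)


class TestDerivatives:
    def test_drift_is_stoichiometry_weighted_sum(self, oregonator):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.uniform(0, 500, size=3)
            a = oregonator.propensities(x, continuous=True)
            expected = sum(a[j] * oregonator.stoich[:, j]
                           for j in range(oregonator.n_reactions))
            assert np.allclose(oregonator.drift(x), expected, rtol=1e-12)

    def test_drift_at_origin(self):
        net = ip.brusselator_model(A_count=100.0, B_count=300.0)
        np.testing.assert_allclose(net.drift(np.zeros(2)),
                                   [BRUSS_K["k1"] * 100.0, 0.0])

    @pytest.mark.parametrize("model", ["brusselator", "oregonator"])
    def test_jacobian_matches_finite_differences(self, model, request):
        net = request.getfixturevalue(model)
        rng = np.random.default_rng(2)
        N = net.n_species
        for _ in range(50):
            x = rng.uniform(10, 500, size=N)
            J = net.jacobian(x)
            h = 1e-4 * (1 + np.abs(x))
            Jfd = np.empty((N, N))
            for i in range(N):
                e = np.zeros(N)
                e[i] = h[i]
                Jfd[:, i] = (net.drift(x + e) - net.drift(x - e)) / (2 * h[i])
            assert np.allclose(J, Jfd, rtol=1e-6, atol=1e-8 * np.abs(J).max())

    def test_brusselator_cross_derivative(self):
        net = ip.brusselator_model(volume=250.0)
        X, Y = 120.0, 80.0
        J = net.jacobian(np.array([X, Y]))
        assert J[0, 1] == pytest.approx(BRUSS_K["k3"] * X * (X - 1) / 250.0 ** 2)

    @pytest.mark.parametrize("model", ["brusselator", "oregonator"])
    def test_hessian_tensor_matches_finite_differences(self, model, request):
        net = request.getfixturevalue(model)
        rng = np.random.default_rng(3)
        N = net.n_species
        for _ in range(10):
            x = rng.uniform(10, 300, size=N)
            T = net.hessian_tensor(x)
            assert np.allclose(T, np.transpose(T, (0, 2, 1)))
            h = 1e-3 * (1 + np.abs(x))
            for l in range(N):
                e = np.zeros(N)
                e[l] = h[l]
                Tfd = (net.jacobian(x + e) - net.jacobian(x - e)) / (2 * h[l])
                assert np.allclose(T[:, :, l], Tfd, rtol=1e-5,
                                   atol=1e-6 * (1 + np.abs(T).max()))

    def test_linear_network_has_constant_jacobian_zero_hessian(self):
        cfg = """
name: linear
volume: 2.0
species:
  - {name: X, initial: 5}
  - {name: A, constant: true, count: 3}
reactions:
  - {reactants: {A: 1}, products: {X: 1, A: 1}, rate: 4.0}
  - {reactants: {X: 1}, products: {}, rate: 0.5}
"""
        net = ip.parse_model(cfg)
        J1 = net.jacobian(np.array([1.0]))
        J2 = net.jacobian(np.array([100.0]))
        assert np.allclose(J1, J2)
        assert np.allclose(net.hessian_tensor(np.array([7.0])), 0.0)

    def test_oracle_derivative_chain(self, oracle):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.uniform(-1.5, 1.5, size=2)
            h = 1e-6
            for i in range(2):
                e = np.zeros(2)
                e[i] = h
                fd = (oracle.drift(x + e) - oracle.drift(x - e)) / (2 * h)
                assert np.allclose(oracle.jacobian(x)[:, i], fd, atol=1e-7)
                fdJ = (oracle.jacobian(x + e) - oracle.jacobian(x - e)) / (2 * h)
                assert np.allclose(oracle.hessian_tensor(x)[:, :, i], fdJ,
                                   atol=1e-6)


class TestDiffusion:
    def test_zero_propensities_give_zero_matrix(self, brusselator):
        B = brusselator.diffusion(np.zeros(2))
        # only the zeroth-order feed reaction is active at the origin
        assert np.allclose(B[:, 1:], 0.0)
        net = ip.parse_model("""
name: idle
volume: 1.0
species:
  - {name: X, initial: 0}
reactions:
  - {reactants: {X: 1}, products: {}, rate: 1.0}
""")
        assert np.allclose(net.diffusion(np.zeros(1)), 0.0)

    def test_single_reaction_column(self):
        net = ip.parse_model("""
name: birth
volume: 1.0
species:
  - {name: X, initial: 0}
  - {name: A, constant: true, count: 4}
reactions:
  - {reactants: {A: 1}, products: {X: 1, A: 1}, rate: 2.0}
""")
        B = net.diffusion(np.array([9.0]))
        assert B.shape == (1, 1)
        assert B[0, 0] == pytest.approx(np.sqrt(8.0))

    def test_product_recovers_s_diag_s(self, oregonator):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.uniform(0, 400, size=3)
            B = oregonator.diffusion(x)
            a = oregonator.propensities(x, continuous=True)
            S = oregonator.stoich
            assert np.allclose(B @ B.T, S @ np.diag(a) @ S.T, rtol=1e-12)


def test_constant_species_rows_are_zero_and_counts_never_change(oregonator):
    # constant species are excluded from the dynamic state entirely
    assert set(oregonator.constant_counts) == {"A", "B", "R"}
    assert oregonator.stoich.shape[0] == 3
    path = ip.simulate_ssa(oregonator, t_end=500.0, seed=9)
    states = path.states(oregonator.stoich)
    assert states.shape[1] == 3  # A, B, R have no state rows at all
    assert np.all(states >= 0)
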