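"""Structural indicators, trophic levels, and flow-network cycling indices."""

import numpy as np
import pytest

from trophostab import (
    FlowNetwork,
    FoodWebModel,
    Group,
    build_flow_network,
    connectance_index,
    finn_cycling_index,
    finn_mean_path_length,
    indicator_table,
    nlg,
    predatory_cycling_index,
    resolution_index,
    system_omnivory_index,
    trophic_levels,
)
from conftest import make_chain3, make_omnivore_web
from trophostab.core import solve_mass_balance


def _fn(names, t, imports, exports, detritus=None, respiration=None):
    n = len(names)
    return FlowNetwork(
        names=list(names), t=np.asarray(t, dtype=float),
        imports=np.asarray(imports, dtype=float),
        exports=np.asarray(exports, dtype=float),
        respiration=(np.zeros(n) if respiration is None
                     else np.asarray(respiration, dtype=float)),
        detritus=(np.zeros(n, dtype=bool) if detritus is None
                  else np.asarray(detritus, dtype=bool)),
    )


class TestTrophicLevels:
    def test_chain_levels(self, balanced_chain):
        tl = trophic_levels(balanced_chain)
        np.testing.assert_allclose(tl, [1.0, 2.0, 3.0], rtol=1e-12)

    def test_omnivore_level(self):
        m = solve_mass_balance(make_omnivore_web())
        tl = trophic_levels(m)
        assert tl[2] == pytest.approx(2.5, rel=1e-12)

    def test_defining_system_residual(self, ensemble12):
        for m in ensemble12[:4]:
            tl = trophic_levels(m)
            for j, g in enumerate(m.groups):
                if g.is_living and (g.qb or 0) > 0:
                    want = 1.0 + float(m.diet[:, j] @ tl)
                    assert tl[j] == pytest.approx(want, abs=1e-10)
            assert np.all(tl >= 1.0 - 1e-12)


class TestCountsAndConnectance:
    def test_nlg_excludes_detritus(self, ensemble12):
        m = ensemble12[0]
        assert nlg(m) == sum(g.is_living for g in m.groups)

    def test_resolution_mean(self):
        m = make_chain3()
        for g, r in zip(m.groups, (1.0, 0.7, 0.4)):
            g.resolution = r
        assert resolution_index(m) == pytest.approx(0.7, rel=1e-12)

    def test_connectance_chain(self, balanced_chain):
        assert connectance_index(balanced_chain) == pytest.approx(2 / 9)

    def test_connectance_no_links(self):
        groups = [
            Group("p1", biomass=5.0, pb=2.0, qb=0.0, ee=0.0),
            Group("p2", biomass=3.0, pb=1.0, qb=0.0, ee=0.0),
        ]
        m = FoodWebModel(groups, np.zeros((2, 2)), "bay")
        assert connectance_index(m) == 0.0

    def test_fully_connected_two_consumers(self):
        # both consumers eat each other and themselves: L = 4, S = 2
        groups = [
            Group("c1", biomass=1.0, pb=1.0, qb=5.0, ee=0.5),
            Group("c2", biomass=1.0, pb=1.0, qb=5.0, ee=0.5),
            Group("det", is_living=False, biomass=1.0),
        ]
        diet = np.zeros((3, 3))
        diet[:2, :2] = 0.5
        m = FoodWebModel(groups, diet, "bay")
        assert connectance_index(m) == 1.0

    def test_threshold_drops_weak_links(self, balanced_chain):
        assert connectance_index(balanced_chain, threshold=1.0) == 0.0


class TestOmnivory:
    def test_specialist_has_zero_soi(self):
        m = solve_mass_balance(make_chain3())
        # both consumers are strict specialists: diet variance is zero
        assert system_omnivory_index(m) == pytest.approx(0.0, abs=1e-12)

    def test_omnivore_oi(self):
        m = solve_mass_balance(make_omnivore_web())
        # OI = 0.5 (1 - 1.5)^2 + 0.5 (2 - 1.5)^2 = 0.25 and the herbivore
        # contributes OI = 0 with its own weight
        herb_q = 10.0 * 10.0
        omni_q = 1.0 * 2.5
        want = 0.25 * np.log(omni_q) / (np.log(herb_q) + np.log(omni_q))
        assert system_omnivory_index(m) == pytest.approx(want, rel=1e-9)

    def test_unweighted_dialect_is_plain_mean(self):
        m = solve_mass_balance(make_omnivore_web())
        # herbivore OI = 0, omnivore OI = 0.25
        assert system_omnivory_index(m, weighting="unweighted") == \
            pytest.approx(0.125, rel=1e-9)


class TestFlowNetwork:
    def test_steady_state_on_ensemble(self, ensemble12):
        for m in ensemble12:
            fn = build_flow_network(m)
            fn.check_steady_state()
            assert np.all(fn.t >= 0)

    def test_acyclic_chain_fci_zero(self):
        t = [[0, 1, 0], [0, 0, 0.5], [0, 0, 0]]
        fn = _fn("abc", t, [1, 0, 0], [0, 0.5, 0.5])
        assert finn_cycling_index(fn) == pytest.approx(0.0, abs=1e-12)

    def test_two_node_loop_is_half(self):
        fn = _fn("ab", [[0, 1], [0.5, 0]], [0.5, 0], [0, 0.5])
        assert finn_cycling_index(fn) == pytest.approx(0.5, rel=1e-12)

    def test_pass_through_node_keeps_fci_zero(self):
        t = [[0, 1, 0, 0], [0, 0, 0.5, 0.5], [0, 0, 0, 0], [0, 0, 0, 0]]
        fn = _fn("abcd", t, [1, 0, 0, 0], [0, 0, 0.5, 0.5])
        assert finn_cycling_index(fn) == pytest.approx(0.0, abs=1e-12)

    def test_pci_removes_detrital_cycle(self):
        # a -> detritus -> a is the only cycle
        t = [[0, 0.5], [0.5, 0]]
        fn = _fn(["a", "det"], t, [0.5, 0], [0.5, 0],
                 detritus=[False, True])
        assert finn_cycling_index(fn) > 0
        assert predatory_cycling_index(fn) == pytest.approx(0.0, abs=1e-12)

    def test_pci_equals_fci_without_detritus(self):
        fn = _fn("ab", [[0, 1], [0.5, 0]], [0.5, 0], [0, 0.5])
        assert predatory_cycling_index(fn) == finn_cycling_index(fn)

    def test_fml_single_compartment(self):
        fn = _fn("a", [[0]], [1.0], [1.0])
        assert finn_mean_path_length(fn) == pytest.approx(1.0)

    def test_fml_chain_of_two(self):
        fn = _fn("ab", [[0, 1], [0, 0]], [1, 0], [0, 1])
        assert finn_mean_path_length(fn) == pytest.approx(2.0)

    def test_recycling_raises_fml(self):
        chain = _fn("ab", [[0, 1], [0, 0]], [1, 0], [0, 1])
        loop = _fn("ab", [[0, 1], [0.5, 0]], [1, 0], [0, 1])
        assert finn_mean_path_length(loop) > finn_mean_path_length(chain)

    def test_fci_brute_force_particles(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            fn = _random_flow_network(rng, n=rng.integers(2, 7))
            want = finn_cycling_index(fn)
            got, se = _particle_fci(fn, 20000, rng)
            assert abs(got - want) <= max(3 * se, 1e-3)


class TestIndicatorTable:
    def test_row_count_and_log_columns(self, ensemble12):
        df = indicator_table(ensemble12[:5])
        assert len(df) == 5
        np.testing.assert_allclose(df["log_NLG"], np.log(df["NLG"]), rtol=1e-12)
        np.testing.assert_allclose(
            df["log_FCI"], np.log(df["FCI"] + 1e-6), rtol=1e-12)

    def test_zero_index_uses_epsilon(self, balanced_chain):
        df = indicator_table([balanced_chain])
        assert df.loc[0, "SOI"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc[0, "log_SOI"] == pytest.approx(np.log(1e-6), rel=1e-9)


def _random_flow_network(rng, n):
    """Random dissipative steady-state network built from output fractions."""
    imports = rng.uniform(0.5, 2.0, n)
    frac = rng.dirichlet(np.ones(n + 1), size=n)  # last column = export
    frac[:, -1] = np.maximum(frac[:, -1], 0.1)    # guarantee dissipation
    frac /= frac.sum(axis=1, keepdims=True)
    p = frac[:, :n].copy()
    np.fill_diagonal(p, 0.0)
    row = p.sum(axis=1) + frac[:, -1]
    p /= row[:, None]
    export_frac = frac[:, -1] / row
    tau = np.linalg.solve(np.eye(n) - p.T, imports)
    t = tau[:, None] * p
    exports = tau * export_frac
    return _fn([f"n{i}" for i in range(n)], t, imports, exports)


def _particle_fci(fn, n_particles, rng):
    """Monte Carlo oracle: fraction of throughflow that returns to its
    compartment, estimated from random walks on the output fractions."""
    tau = fn.throughflow
    n = len(tau)
    out_frac = fn.t / tau[:, None]  # row i: where a unit leaving i goes
    est = np.zeros(n)
    se2 = 0.0
    weights = tau / tau.sum()
    for i in range(n):
        k = max(200, int(n_particles * weights[i]))
        returned = 0
        state = np.full(k, i)
        alive = np.ones(k, dtype=bool)
        for _ in range(500):
            if not alive.any():
                break
            u = rng.uniform(size=alive.sum())
            cum = np.cumsum(out_frac[state[alive]], axis=1)
            nxt = (u[:, None] < cum).argmax(axis=1)
            exited = u >= cum[:, -1]
            came_back = ~exited & (nxt == i)  # first return only
            returned += int(came_back.sum())
            idx = np.where(alive)[0]
            cont = ~exited & ~came_back
            state[idx[cont]] = nxt[cont]
            alive[idx[exited | came_back]] = False
        p_ret = returned / k
        est[i] = p_ret
        se2 += (weights[i] ** 2) * p_ret * (1 - p_ret) / k
    fci = float(np.dot(weights, est))
    return fci, float(np.sqrt(se2))
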