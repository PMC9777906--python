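import numpy as np
import pytest
from scipy import stats

from hivecrit import ising


def _state(spins):
    return ising.LatticeState(np.asarray(spins, dtype=np.int8))


class TestLatticeEnergy:
    def test_all_up_torus(self):
        assert ising.lattice_energy(_state(np.ones((10, 10)))) == -200.0

    def test_checkerboard_even_side(self):
        s = np.indices((6, 6)).sum(axis=0) % 2 * 2 - 1
        assert ising.lattice_energy(_state(s)) == +2 * 36

    def test_matches_bond_enumeration_oracle(self, rng):
        s = rng.choice([-1, 1], size=(4, 4)).astype(np.int8)
        # enumerate all 32 toroidal bonds explicitly
        e = 0
        for r in range(4):
            for c in range(4):
                e -= s[r, c] * s[(r + 1) % 4, c]
                e -= s[r, c] * s[r, (c + 1) % 4]
        assert ising.lattice_energy(_state(s)) == e

    def test_global_flip_symmetry(self, rng):
        s = rng.choice([-1, 1], size=(5, 5)).astype(np.int8)
        assert ising.lattice_energy(_state(s)) == ising.lattice_energy(_state(-s))
        assert ising.magnetization(_state(-s)) == -ising.magnetization(_state(s))


class TestMagnetization:
    def test_all_up(self):
        assert ising.magnetization(_state(np.ones((3, 3)))) == 1.0

    def test_half_half(self):
        s = np.ones((4, 4), dtype=np.int8)
        s[:2] = -1
        assert ising.magnetization(_state(s)) == 0.0

    def test_matches_sum_oracle(self, rng):
        s = rng.choice([-1, 1], size=(5, 5)).astype(np.int8)
        assert ising.magnetization(_state(s)) == pytest.approx(s.sum() / 25.0)


class TestMetropolisStep:
    def test_frozen_at_tiny_temperature(self):
        state = _state(np.ones((8, 8)))
        rng = np.random.default_rng(0)
        for _ in range(100):
            state = ising.metropolis_step(state, T=0.01, rng=rng)
        assert ising.magnetization(state) == 1.0

    def test_input_not_mutated(self, rng):
        state = _state(np.ones((4, 4)))
        before = state.spins.copy()
        ising.metropolis_step(state, T=5.0, rng=rng)
        np.testing.assert_array_equal(state.spins, before)

    def test_energy_bookkeeping_over_a_sweep(self):
        # replay a sweep attempt-by-attempt with explicit dE accumulation
        rng = np.random.default_rng(3)
        spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=(5, 5))
        L, N = 5, 25
        sites = rng.integers(0, N, size=N)
        uniforms = rng.random(N)
        work = spins.copy()
        acc = 0
        for idx, u in zip(sites, uniforms):
            r, c = divmod(int(idx), L)
            nn = (
                work[(r - 1) % L, c] + work[(r + 1) % L, c]
                + work[r, (c - 1) % L] + work[r, (c + 1) % L]
            )
            dE = 2 * int(work[r, c]) * int(nn)
            if dE <= 0 or u < np.exp(-dE / 2.3):
                work[r, c] = -work[r, c]
                acc += dE
        e0 = ising.lattice_energy(_state(spins))
        e1 = ising.lattice_energy(_state(work))
        assert e1 - e0 == acc


class TestRunSimulation:
    def test_shapes_and_magnetization_consistency(self):
        cfg = ising.SimulationConfig(L=8, T=2.3, n_therm=50, n_record=40, seed=5)
        run = ising.run_simulation(cfg)
        assert run.configurations.shape == (40, 8, 8)
        assert run.magnetization.shape == (40,)
        for k in (0, 17, 39):
            assert run.magnetization[k] == pytest.approx(run.configurations[k].mean())

    def test_zero_record_is_valid(self):
        run = ising.run_simulation(ising.SimulationConfig(L=4, T=2.3, n_therm=5, n_record=0))
        assert run.configurations.shape[0] == 0

    def test_same_seed_reproduces_exactly(self):
        cfg = ising.SimulationConfig(L=10, T=2.3, n_therm=100, n_record=50, seed=77)
        a = ising.run_simulation(cfg)
        b = ising.run_simulation(cfg)
        np.testing.assert_array_equal(a.magnetization, b.magnetization)
        np.testing.assert_array_equal(a.configurations, b.configurations)

    def test_phase_behaviour_low_and_high_temperature(self):
        low = ising.run_simulation(ising.SimulationConfig(L=20, T=2.0, n_therm=2000,
                                                          n_record=1000, seed=11))
        assert np.abs(low.magnetization).mean() > 0.9
        high = ising.run_simulation(ising.SimulationConfig(L=20, T=3.0, n_therm=2000,
                                                           n_record=1000, seed=11))
        assert abs(high.magnetization.mean()) < 0.1


class TestSiteSeries:
    def test_single_record_length_one(self):
        run = ising.run_simulation(ising.SimulationConfig(L=4, T=2.3, n_therm=5, n_record=1))
        assert ising.site_series(run).shape == (16, 1)

    def test_reshaping_roundtrip(self):
        run = ising.run_simulation(ising.SimulationConfig(L=6, T=2.5, n_therm=10, n_record=9,
                                                          seed=2))
        s = ising.site_series(run)
        back = s.T.reshape(9, 6, 6)
        np.testing.assert_array_equal(back, run.configurations)


def test_onsager_value():
    assert ising.onsager_critical_temperature() == pytest.approx(2.269185314, abs=1e-8)


def _boltzmann_expected(L, T):
    """Exact Boltzmann distribution over all 2^(L*L) states."""
    n = L * L
    energies = np.empty(2**n)
    for code in range(2**n):
        bits = np.array([(code >> i) & 1 for i in range(n)], dtype=np.int8)
        s = (2 * bits - 1).reshape(L, L)
        energies[code] = ising.lattice_energy(ising.LatticeState(s))
    w = np.exp(-(energies - energies.min()) / T)
    return w / w.sum(), energies


def test_detailed_balance_against_exact_enumeration_2x2():
    """Long-run state frequencies match exp(-E/T)/Z on the 2x2 torus.

    Consecutive sweeps are autocorrelated, so recorded configurations are
    thinned before the chi-square comparison.
    """
    T = 2.3
    probs, _ = _boltzmann_expected(2, T)
    run = ising.run_simulation(
        ising.SimulationConfig(L=2, T=T, n_therm=500, n_record=1_000_000, seed=123)
    )
    bits = (run.configurations.reshape(-1, 4) > 0).astype(np.int64)
    codes = bits @ (1 << np.arange(4))
    codes = codes[::10]  # thin for approximate independence
    counts = np.bincount(codes, minlength=16)
    chi2, p = stats.chisquare(counts, probs * counts.sum())
    assert p > 0.01


def test_detailed_balance_against_exact_enumeration_3x3():
    """Energy-level occupation matches the exact 3x3 Boltzmann weights."""
    T = 2.3
    probs, energies = _boltzmann_expected(3, T)
    run = ising.run_simulation(
        ising.SimulationConfig(L=3, T=T, n_therm=500, n_record=1_000_000, seed=321)
    )
    bits = (run.configurations.reshape(-1, 9) > 0).astype(np.int64)
    codes = bits @ (1 << np.arange(9))
    codes = codes[::10]
    # group by energy level, merging rare levels so expected counts are >= 5
    levels = np.unique(energies)
    level_idx = {e: i for i, e in enumerate(levels)}
    state_level = np.array([level_idx[e] for e in energies])
    exp_level = np.bincount(state_level, weights=probs)
    obs_level = np.bincount(state_level[codes], minlength=levels.size)
    order = np.argsort(exp_level)
    exp_m, obs_m, acc_e, acc_o = [], [], 0.0, 0.0
    for i in order:
        acc_e += exp_level[i] * codes.size
        acc_o += obs_level[i]
        if acc_e >= 5:
            exp_m.append(acc_e)
            obs_m.append(acc_o)
            acc_e = acc_o = 0.0
    exp_m[-1] += acc_e
    obs_m[-1] += acc_o
    chi2, p = stats.chisquare(obs_m, np.array(exp_m) * (sum(obs_m) / sum(exp_m)))
    assert p > 0.01
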