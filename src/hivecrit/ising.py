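"""2D Ising model on a torus with Metropolis single-site dynamics.

The model lives on an L x L square lattice with periodic boundaries; each site
carries a spin s_i = +/-1.  Units are J = k_B = 1 and there is no external
field.  The Hamiltonian counts each nearest-neighbour bond once,

    E = -J * sum_<ij> s_i s_j,

so the ground state (all spins aligned) has E = -2 N J with N = L*L.  A flip
of spin i changes the energy by dE = 2 J s_i * (sum of its 4 neighbours),
which is all the dynamics needs.

One *step* of the algorithm is N single-site update attempts at uniformly
random sites, each accepted with the Metropolis probability
min(1, exp(-dE / T)).  A run thermalizes for ``n_therm`` steps from a hot
(uniform random) start and then records ``n_record`` consecutive
configurations separated by one step each, together with the magnetization
M = mean(s_i) of each recorded configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SimulationConfig",
    "LatticeState",
    "SimulationRun",
    "lattice_energy",
    "magnetization",
    "metropolis_step",
    "run_simulation",
    "site_series",
    "onsager_critical_temperature",
]


def onsager_critical_temperature() -> float:
    """Exact critical temperature of the infinite 2D Ising model, 2/ln(1+sqrt(2))."""
    return 2.0 / np.log(1.0 + np.sqrt(2.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one Metropolis run (J = k_B = 1, zero field)."""

    L: int
    T: float
    n_therm: int = 10_000
    n_record: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError(f"lattice side L must be >= 2, got {self.L}")
        if not (self.T > 0):
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.n_therm < 0 or self.n_record < 0:
            raise ValueError("n_therm and n_record must be non-negative")


@dataclass
class LatticeState:
    """An L x L grid of spins in {-1, +1} (int8)."""

    spins: np.ndarray

    def __post_init__(self) -> None:
        self.spins = np.asarray(self.spins, dtype=np.int8)
        if self.spins.ndim != 2 or self.spins.shape[0] != self.spins.shape[1]:
            raise ValueError("spins must be a square 2D array")
        if not np.all(np.abs(self.spins) == 1):
            raise ValueError("every spin must be +1 or -1")

    @property
    def L(self) -> int:
        return self.spins.shape[0]


@dataclass
class SimulationRun:
    """Recorded configurations and magnetization series of one run."""

    config: SimulationConfig
    configurations: np.ndarray  # (n_record, L, L) int8
    magnetization: np.ndarray  # (n_record,) float64
    final_state: LatticeState = field(repr=False)


def lattice_energy(state: LatticeState) -> float:
    """Energy -J * sum over bonds of s_i s_j, each toroidal bond counted once."""
    s = state.spins.astype(np.int64)
    e = -(s * np.roll(s, 1, axis=0)).sum() - (s * np.roll(s, 1, axis=1)).sum()
    return float(e)


def magnetization(state: LatticeState) -> float:
    """Mean spin M, in [-1, 1]."""
    return float(state.spins.mean(dtype=np.float64))


@njit(cache=True)
def _sweep(spins, L, T, sites, uniforms):  # pragma: no cover - jitted
    for a in range(sites.shape[0]):
        idx = sites[a]
        r = idx // L
        c = idx - r * L
        s = spins[r, c]
        nn = (
            spins[r - 1 if r > 0 else L - 1, c]
            + spins[r + 1 if r < L - 1 else 0, c]
            + spins[r, c - 1 if c > 0 else L - 1]
            + spins[r, c + 1 if c < L - 1 else 0]
        )
        dE = 2.0 * s * nn
        if dE <= 0.0 or uniforms[a] < np.exp(-dE / T):
            spins[r, c] = -s


def metropolis_step(state: LatticeState, T: float, rng: np.random.Generator) -> LatticeState:
    """One step: N = L*L single-site Metropolis attempts at random sites.

    The input state is not mutated; the updated lattice is returned.
    """
    if not (T > 0):
        raise ValueError("temperature must be positive")
    L = state.L
    N = L * L
    spins = state.spins.copy()
    sites = rng.integers(0, N, size=N, dtype=np.int64)
    uniforms = rng.random(N)
    _sweep(spins, L, T, sites, uniforms)
    return LatticeState(spins)


def _random_state(L: int, rng: np.random.Generator) -> LatticeState:
    spins = rng.choice(np.array([-1, 1], dtype=np.int8), size=(L, L))
    return LatticeState(spins)


def run_simulation(config: SimulationConfig) -> SimulationRun:
    """Thermalize from a hot start, then record consecutive configurations.

    Fully reproducible from ``config.seed``: the same config yields the same
    magnetization series element for element.
    """
    rng = np.random.default_rng(config.seed)
    L, T, N = config.L, config.T, config.L * config.L
    spins = _random_state(L, rng).spins.copy()

    for _ in range(config.n_therm):
        sites = rng.integers(0, N, size=N, dtype=np.int64)
        uniforms = rng.random(N)
        _sweep(spins, L, T, sites, uniforms)

    configs = np.empty((config.n_record, L, L), dtype=np.int8)
    mags = np.empty(config.n_record, dtype=np.float64)
    for k in range(config.n_record):
        sites = rng.integers(0, N, size=N, dtype=np.int64)
        uniforms = rng.random(N)
        _sweep(spins, L, T, sites, uniforms)
        configs[k] = spins
        mags[k] = spins.mean(dtype=np.float64)
    return SimulationRun(
        config=config,
        configurations=configs,
        magnetization=mags,
        final_state=LatticeState(spins.copy()),
    )


def site_series(run: SimulationRun) -> np.ndarray:
    """Per-site spin time-series, shape (N, n_record), sites in row-major order.

    Row j is the spin of lattice site j (row-major flattening) across the
    recorded configurations, so ``site_series(run)[j, t]`` equals
    ``run.configurations[t].ravel()[j]``.
    """
    if run.configurations.shape[0] < 1:
        raise ValueError("run has no recorded configurations")
    n_record = run.configurations.shape[0]
    return np.ascontiguousarray(run.configurations.reshape(n_record, -1).T)
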