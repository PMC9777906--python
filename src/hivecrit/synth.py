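"""Synthetic data generators: fractional Gaussian noise and hive-like trajectories.

Two generators make the whole pipeline testable with known ground truth:

* :func:`generate_fgn` draws stationary fractional Gaussian noise with a
  prescribed Hurst exponent by circulant embedding (Davies–Harte), the
  standard exact spectral construction.  It validates the Hurst estimator.

* :func:`generate_hive` emulates the raw trajectory tables of a tracked
  colony: ~10^3 individuals at 1 s resolution in a bounded rectangular
  arena, organized into groups whose activity alternates between bursts and
  quiescence via a latent two-state Markov signal; a fraction of individuals
  is inactive and a fraction of detections is dropped to exercise
  interpolation and coverage filtering.  The generator deliberately does NOT
  implement a critical system — it provides controllable correlation
  structure (within-group vs cross-group) so the pipeline's discrimination
  is testable; the Ising module supplies the genuinely critical signal.

All generators are pure functions of their config + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FgnConfig",
    "HiveConfig",
    "generate_fgn",
    "fgn_autocovariance",
    "generate_hive",
    "fixture_suite",
]


@dataclass(frozen=True)
class FgnConfig:
    n: int
    H: float
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.H < 1.0):
            raise ValueError("H must be in (0, 1)")
        if self.n < 256 or (self.n & (self.n - 1)) != 0:
            raise ValueError("n must be a power of two >= 256 for the spectral generator")


def fgn_autocovariance(lags, H: float, sigma: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k) = (sigma^2/2)(|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=np.float64))
    h2 = 2.0 * H
    return 0.5 * sigma**2 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def generate_fgn(config: FgnConfig) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (Davies–Harte).

    The circulant embedding of the autocovariance is diagonalized by FFT; its
    eigenvalues are non-negative for fGn autocovariances, which is checked
    explicitly, and independent complex normals are colored accordingly.
    """
    n, H, sigma = config.n, config.H, config.sigma
    gamma = fgn_autocovariance(np.arange(n + 1), H, sigma)
    first_row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    eigs = np.fft.fft(first_row).real
    if eigs.min() < -1e-8 * eigs.max():
        raise ValueError("circulant embedding not positive semi-definite for this config")
    eigs = np.maximum(eigs, 0.0)

    m = 2 * n
    rng = np.random.default_rng(config.seed)
    v = np.zeros(m, dtype=np.complex128)
    v[0] = np.sqrt(eigs[0]) * rng.standard_normal()
    v[n] = np.sqrt(eigs[n]) * rng.standard_normal()
    re = rng.standard_normal(n - 1)
    im = rng.standard_normal(n - 1)
    v[1:n] = np.sqrt(eigs[1:n] / 2.0) * (re + 1j * im)
    v[n + 1 :] = np.conj(v[n - 1 : 0 : -1])
    x = np.fft.fft(v) / np.sqrt(m)
    return x[:n].real


@dataclass(frozen=True)
class HiveConfig:
    """Conditions emulating a sealed-colony tracking session.

    Defaults follow the shape of the study data: ~1200 individuals recorded
    at 1 s resolution in a bounded rectangular arena, with minute-scale
    burst/quiescence alternation, a tenth of individuals inactive and a few
    percent of detections lost.
    """

    n_bees: int = 1200
    n_groups: int = 4
    duration: float = 3600.0
    dt: float = 1.0
    burst_on_rate: float = 1.0 / 120.0  # quiescent -> burst, per second
    burst_off_rate: float = 1.0 / 60.0  # burst -> quiescent, per second
    active_speed: float = 2.0  # position units per interval while bursting
    rest_speed: float = 0.05
    noise_sd: float = 0.1
    inactive_fraction: float = 0.1
    dropout_fraction: float = 0.05
    arena: tuple = (60.0, 35.0)
    t0: float = 1_600_000_000.0  # arbitrary epoch origin
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees > 0 and self.n_groups > self.n_bees:
            raise ValueError("n_groups must not exceed n_bees")
        if self.burst_on_rate <= 0 or self.burst_off_rate <= 0:
            raise ValueError("switching rates must be positive")
        for frac in (self.inactive_fraction, self.dropout_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


def generate_hive(config: HiveConfig) -> pd.DataFrame:
    """Detections table with columns individual_id, timestamp, x, y.

    Each group carries a latent burst/quiescent telegraph signal; a bee's
    step length is rest_speed + (active_speed - rest_speed) * state plus
    Gaussian noise, its heading follows a bounded random walk, and positions
    reflect off the arena walls.  Rows are emitted in global time order
    (individual order within a timestamp is stable), with a seeded fraction
    of detections deleted.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration / config.dt))
    nb = config.n_bees
    if nb == 0 or n_steps < 1:
        return pd.DataFrame(columns=["individual_id", "timestamp", "x", "y"])

    # latent two-state Markov signal per group (1 = burst); groups start quiescent
    p_on = 1.0 - np.exp(-config.burst_on_rate * config.dt)
    p_off = 1.0 - np.exp(-config.burst_off_rate * config.dt)
    states = np.zeros((config.n_groups, n_steps), dtype=np.int8)
    s = np.zeros(config.n_groups, dtype=np.int8)
    for t in range(n_steps):
        u = rng.random(config.n_groups)
        s = np.where(s == 1, (u >= p_off).astype(np.int8), (u < p_on).astype(np.int8))
        states[:, t] = s

    group = rng.integers(0, config.n_groups, size=nb)
    inactive = rng.random(nb) < config.inactive_fraction

    w, h = config.arena
    x = rng.uniform(0, w, size=nb)
    y = rng.uniform(0, h, size=nb)
    theta = rng.uniform(0, 2 * np.pi, size=nb)

    xs = np.empty((n_steps, nb))
    ys = np.empty((n_steps, nb))
    for t in range(n_steps):
        burst = states[group, t].astype(np.float64)
        burst[inactive] = 0.0
        speed = config.rest_speed + (config.active_speed - config.rest_speed) * burst
        theta = theta + rng.normal(0.0, 0.5, size=nb)
        x = x + speed * np.cos(theta) + rng.normal(0.0, config.noise_sd, size=nb)
        y = y + speed * np.sin(theta) + rng.normal(0.0, config.noise_sd, size=nb)
        # reflect at the arena walls
        x = np.abs(x)
        x = w - np.abs(w - x)
        y = np.abs(y)
        y = h - np.abs(h - y)
        xs[t] = x
        ys[t] = y

    times = config.t0 + config.dt * np.arange(n_steps)
    df = pd.DataFrame(
        {
            "individual_id": np.tile([f"bee{i:04d}" for i in range(nb)], n_steps),
            "timestamp": np.repeat(times, nb),
            "x": xs.ravel(),
            "y": ys.ravel(),
        }
    )
    if config.dropout_fraction > 0:
        keep = rng.random(len(df)) >= config.dropout_fraction
        df = df[keep].reset_index(drop=True)
    return df


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    """Write detections in the CSV dialect the trajectories module consumes."""
    df.to_csv(path, index=False, columns=["individual_id", "timestamp", "x", "y"])


def fixture_suite(seed: int = 1, out_dir: str | Path | None = None) -> dict:
    """Small deterministic datasets used across the test surface.

    Returns a dict of named in-memory fixtures; when ``out_dir`` is given the
    same fixtures are also written as text files, byte-stable for a fixed
    seed.
    """
    rng = np.random.default_rng(seed)

    # hand-checkable series: cumulative deviations of (1, 3, 2) are (-1, 0, 0)
    toy_series = np.array([1.0, 3.0, 2.0])

    # toy tracks: one stationary, one moving on a line
    toy_tracks = pd.DataFrame(
        {
            "individual_id": ["a"] * 3 + ["b"] * 3,
            "timestamp": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
            "x": [5.0, 5.0, 5.0, 0.0, 2.0, 4.0],
            "y": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        }
    )

    # 6-node correlation matrix with a planted 2-block structure
    base = rng.standard_normal((2, 60))
    noise = 0.4 * rng.standard_normal((6, 60))
    series6 = np.vstack([base[i // 3] for i in range(6)]) + noise
    corr6 = np.corrcoef(series6)

    # tiny lattice
    lattice4 = rng.choice(np.array([-1, 1], dtype=np.int8), size=(4, 4))

    # disjoint 5-clique + 3-clique edge list (nodes 0-4 and 5-7)
    cliques = [(i, j) for i in range(5) for j in range(i + 1, 5)] + [
        (i, j) for i in range(5, 8) for j in range(i + 1, 8)
    ]

    bundle = {
        "toy_series": toy_series,
        "toy_tracks": toy_tracks,
        "series6": series6,
        "corr6": corr6,
        "lattice4": lattice4,
        "cliques_edges": cliques,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "toy_series.csv", toy_series, fmt="%.6f")
        toy_tracks.to_csv(out / "toy_tracks.csv", index=False)
        np.savetxt(out / "corr6.csv", corr6, delimiter=",", fmt="%.12f")
        np.savetxt(out / "series6.csv", series6, delimiter=",", fmt="%.12f")
        np.savetxt(out / "lattice4.csv", lattice4, delimiter=",", fmt="%d")
        with open(out / "cliques_edges.tsv", "w") as fh:
            for i, j in cliques:
                fh.write(f"{i}\t{j}\n")
        (out / "manifest.json").write_text(json.dumps({"seed": seed}, indent=2))
    return bundle
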