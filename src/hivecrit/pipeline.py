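"""End-to-end orchestration of the Ising-side and trajectory-side analyses.

Both analyses share the same downstream stack: node time-series -> Pearson
correlation matrix -> threshold matched to a target mean degree -> binary
network -> degree-distribution MLE + small-world metrics; plus a Hurst
estimate (with shuffle control) on the scalar activity series (magnetization
for the model, hive mean kinetic energy for trajectories).

All randomness flows from one top-level seed: each stage derives its own
seed by hashing the stage name into the master seed, so stages are
independently reproducible.  When an output directory is given, expensive
simulations are cached on disk keyed by their config, and every run writes a
manifest (config snapshot, package version, per-stage wall time, output
checksums).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from hivecrit import __version__
from hivecrit import corrnet, hurst, ising, netstats, trajectories
from hivecrit.degreefit import DegenerateDegreesError, fit_degree_distribution

__all__ = [
    "IsingPipelineConfig",
    "TrajectoryPipelineConfig",
    "derive_seed",
    "analyze_series_network",
    "run_ising_pipeline",
    "run_trajectory_pipeline",
]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed: stable hash of the stage name folded into the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass(frozen=True)
class IsingPipelineConfig:
    L: int = 100
    temperatures: tuple = (2.0, 2.3, 3.0)
    n_therm: int = 10_000
    n_record: int = 2_000
    target_k: float = 110.0
    er_graphs: int = 10
    exact_limit: int = 2_000
    n_sources: int = 1_000
    seed: int = 0
    out_dir: str | None = None


@dataclass(frozen=True)
class TrajectoryPipelineConfig:
    dt: float = 1.0
    min_coverage: float = 0.8
    min_total_displacement: float = 1e-9
    target_k: float = 110.0
    er_graphs: int = 10
    exact_limit: int = 2_000
    n_sources: int = 1_000
    windows: tuple = ()  # DayNightWindow instances; empty = one window over the span
    seed: int = 0
    out_dir: str | None = None


def analyze_series_network(
    series: np.ndarray,
    target_k: float,
    node_ids=None,
    er_graphs: int = 10,
    exact_limit: int = 2_000,
    n_sources: int = 1_000,
    seed: int | None = None,
) -> dict:
    """Correlation network at matched mean degree: fits + metrics for node series.

    The shared downstream stack of both analyses; returns a JSON-able dict and
    keeps the constructed network under the ``"_network"`` key.
    """
    if series.shape[0] < 2:
        raise ValueError("need at least 2 node series for a correlation network")
    corr = corrnet.pearson_matrix(series, node_ids=node_ids)
    choice = corrnet.choose_threshold(corr, target_k=target_k)
    net = corrnet.build_network(corr, choice.p)
    report: dict = {
        "n_nodes": net.n,
        "threshold": choice.p,
        "k_mean": choice.k_mean,
        "n_zero_variance": len(corr.zero_variance_nodes),
    }
    degrees = netstats.degree_sequence(net)
    try:
        fits, comparison = fit_degree_distribution(degrees)
        report["degree_fits"] = {
            fam: {"xmin": f.xmin, "loglik": f.loglik, "n_tail": f.n_tail, "ks": f.ks, **f.params()}
            for fam, f in fits.items()
        }
        report["best_family"] = comparison.best_family
        report["fit_pairwise"] = {
            f"{a}_vs_{b}": {"R_norm": r, "p_value": p}
            for (a, b), (r, p) in comparison.pairwise.items()
        }
    except DegenerateDegreesError as exc:
        report["degree_fits"] = None
        report["best_family"] = None
        report["fit_error"] = str(exc)
    metrics = netstats.metrics_report(
        net,
        er_graphs=er_graphs,
        seed=seed,
        exact_limit=exact_limit,
        n_sources=n_sources,
    )
    report["metrics"] = metrics.to_dict()
    report["_network"] = net
    return report


def _cached_simulation(config: ising.SimulationConfig, out_dir: str | None) -> ising.SimulationRun:
    if out_dir is None:
        return ising.run_simulation(config)
    cache = Path(out_dir) / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    key = hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]
    path = cache / f"ising_{key}.npz"
    if path.exists():
        data = np.load(path)
        return ising.SimulationRun(
            config=config,
            configurations=data["configurations"],
            magnetization=data["magnetization"],
            final_state=ising.LatticeState(data["final_state"]),
        )
    run = ising.run_simulation(config)
    np.savez_compressed(
        path,
        configurations=run.configurations,
        magnetization=run.magnetization,
        final_state=run.final_state.spins,
    )
    return run


def run_ising_pipeline(config: IsingPipelineConfig) -> dict:
    """Simulate -> correlate -> threshold -> fit + metrics + Hurst per temperature."""
    if config.n_record < 3:
        raise ValueError("n_record must be >= 3 to compute correlations")
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "stages": [],
        "seed": config.seed,
    }
    reports = {}
    for T in config.temperatures:
        t_start = time.perf_counter()
        sim_seed = derive_seed(config.seed, f"ising_T{T}")
        sim_cfg = ising.SimulationConfig(
            L=config.L, T=T, n_therm=config.n_therm, n_record=config.n_record, seed=sim_seed
        )
        run = _cached_simulation(sim_cfg, config.out_dir)
        series = ising.site_series(run)
        report = analyze_series_network(
            series,
            target_k=config.target_k,
            er_graphs=config.er_graphs,
            exact_limit=config.exact_limit,
            n_sources=config.n_sources,
            seed=derive_seed(config.seed, f"metrics_T{T}"),
        )
        net = report.pop("_network")
        est = hurst.estimate_hurst(run.magnetization, min_len=min(256, config.n_record))
        report["hurst"] = est.to_dict()
        report["T"] = T
        report["sim_seed"] = sim_seed
        report["abs_magnetization_mean"] = float(np.abs(run.magnetization).mean())
        reports[f"T={T}"] = report
        manifest["stages"].append(
            {
                "stage": f"T={T}",
                "wall_s": time.perf_counter() - t_start,
                "magnetization_checksum": _checksum(run.magnetization),
                "configurations_checksum": _checksum(run.configurations),
            }
        )
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            net.save_edgelist(out / f"network_T{T}.tsv")
            with open(out / f"report_T{T}.json", "w") as fh:
                json.dump(report, fh, indent=2)

    summary = {
        "temperatures": list(config.temperatures),
        "best_families": {k: v["best_family"] for k, v in reports.items()},
        "clustering": {k: v["metrics"]["C"] for k, v in reports.items()},
        "hurst": {k: v["hurst"]["H"] for k, v in reports.items()},
    }
    result = {"reports": reports, "summary": summary, "manifest": manifest}
    if config.out_dir is not None:
        with open(Path(config.out_dir) / "summary.json", "w") as fh:
            json.dump({"summary": summary, "manifest": manifest}, fh, indent=2)
    return result


def run_trajectory_pipeline(
    config: TrajectoryPipelineConfig,
    detections: pd.DataFrame | str | Path,
) -> dict:
    """Resample -> filter -> kinetic energy -> network + fits per window; Hurst on Kmean."""
    if not isinstance(detections, pd.DataFrame):
        detections = trajectories.read_detections(detections)
    manifest = {"config": asdict(config), "version": __version__, "stages": [], "seed": config.seed}

    t_start = time.perf_counter()
    span_lo = float(detections["timestamp"].min())
    span_hi = float(detections["timestamp"].max())
    tracks = []
    for bee_id, grp in detections.groupby("individual_id", sort=True):
        try:
            tracks.append(
                trajectories.resample_track(
                    grp, dt=config.dt, t_start=span_lo, t_end=span_hi, individual_id=str(bee_id)
                )
            )
        except trajectories.TrackUnusableError:
            continue
    kept = trajectories.filter_inactive(
        tracks,
        min_coverage=config.min_coverage,
        min_total_displacement=config.min_total_displacement,
    )
    if not kept:
        raise ValueError("no tracks survive the inactivity filters")
    energies = [trajectories.kinetic_energy(tr) for tr in kept]
    manifest["stages"].append(
        {
            "stage": "preprocess",
            "wall_s": time.perf_counter() - t_start,
            "n_tracks_raw": len(tracks),
            "n_tracks_kept": len(kept),
            "coverages": {tr.individual_id: tr.coverage for tr in kept},
        }
    )

    if config.windows:
        windows = list(config.windows)
    else:
        windows = [trajectories.DayNightWindow("all", span_lo, span_hi + config.dt)]

    reports = {}
    for w in windows:
        segs = [trajectories.partition_windows(e, [w])[0] for e in energies]
        series = np.vstack([s.values for s in segs])
        if series.shape[1] < 3:
            reports[w.label] = {"error": "window too short for correlations"}
            continue
        report = analyze_series_network(
            series,
            target_k=config.target_k,
            node_ids=[e.individual_id for e in energies],
            er_graphs=config.er_graphs,
            exact_limit=config.exact_limit,
            n_sources=config.n_sources,
            seed=derive_seed(config.seed, f"metrics_{w.label}"),
        )
        net = report.pop("_network")
        report["window"] = {"label": w.label, "start": w.start, "end": w.end}
        reports[w.label] = report
        if config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            net.save_edgelist(out / f"network_{w.label}.tsv")

    activity = trajectories.hive_activity(energies, aggregate="mean")
    est = hurst.estimate_hurst(activity.k, min_len=min(256, activity.k.size))
    ctrl = hurst.shuffle_control(activity.k, seed=derive_seed(config.seed, "shuffle"))
    result = {
        "reports": reports,
        "hurst": est.to_dict(),
        "hurst_shuffled": ctrl.to_dict(),
        "n_individuals": len(kept),
        "manifest": manifest,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trajectories.write_series(activity, out / "hive_activity.csv")
        with open(out / "trajectory_report.json", "w") as fh:
            json.dump(result, fh, indent=2)
    return result
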