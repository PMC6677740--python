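"""Run orchestration: config -> lattice -> dynamics -> pattern readouts.

Also hosts the cross-regime comparison used to mimic the genetic
perturbations (template loss, reduced late-onset inhibition, complete
inhibition loss) and the CSV/JSON writers with reproducible manifests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_to_dict
from .dynamics import GradientParams, ModelParams, Trajectory, simulate
from .fates import (
    FateCall,
    PatternStats,
    call_fates,
    count_stripes_in_window,
    detect_stripes,
    pattern_stats,
    stripe_profile,
)
from .geometry import CellLattice, CouplingMatrix, build_disordered_lattice, compute_coupling

__all__ = ["RunResult", "build_lattice", "run_config", "compare_regimes", "write_run"]


def _subseed(seed: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(stream,))


def build_lattice(cfg: RunConfig, seed: int | None = None) -> CellLattice:
    """Lattice from the config's geometry section (seeded)."""
    lat = cfg.lattice
    s = cfg.simulation.seed if seed is None else seed
    return build_disordered_lattice(
        n_cells=lat.n_cells,
        box_width=lat.box_width,
        box_height=lat.box_height,
        disorder=lat.disorder,
        seed=s,
        lloyd_iterations=lat.lloyd_iterations,
    )


@dataclass(frozen=True)
class RunResult:
    config: RunConfig
    lattice: CellLattice
    trajectory: Trajectory
    fates: FateCall
    stats: PatternStats
    n_stripes_template: int
    n_stripes_pattern: int
    n_stripes_central: int
    stripe_centers: list


def run_config(
    cfg: RunConfig,
    seed: int | None = None,
    lattice: CellLattice | None = None,
) -> RunResult:
    """Execute one seeded run of the configured regime and analyze it.

    The integrator seed is ``seed`` (default: the config's); the lattice,
    unless supplied, is generated from an independent stream of the same
    seed so paired regime comparisons can share geometry.
    """
    cfg.validate()
    s = cfg.simulation.seed if seed is None else seed
    if lattice is None:
        # independent stream for geometry, derived from the run seed
        lat_seed = int(_subseed(s, 0).generate_state(1)[0] % (2**31))
        lattice = build_lattice(cfg, seed=lat_seed)
    coupling = compute_coupling(
        lattice,
        signaling_range=cfg.coupling.signaling_range,
        strength=cfg.coupling.strength,
        cutoff_factor=cfg.coupling.cutoff_factor,
        normalized=cfg.coupling.normalized,
    )
    params = cfg.model.to_params()
    gradient = cfg.gradient.to_params(period=lattice.box_width)
    traj = simulate(
        lattice,
        coupling,
        params,
        gradient,
        u0=None,
        t_end=cfg.simulation.t_end,
        dt=cfg.simulation.dt,
        record_every=cfg.simulation.record_every,
        seed=s,
    )
    fates = call_fates(traj, params)
    stats = pattern_stats(fates, lattice)

    ana = cfg.analysis
    prof_template = stripe_profile(
        traj.snapshot(ana.template_snapshot_time).u, lattice, ana.stripe_bin_width
    )
    prof_pattern = stripe_profile(
        traj.snapshot(ana.pattern_snapshot_time).u, lattice, ana.stripe_bin_width
    )
    stripes_t = detect_stripes(prof_template)
    stripes_p = detect_stripes(prof_pattern)
    lo, hi = ana.central_region
    return RunResult(
        config=cfg,
        lattice=lattice,
        trajectory=traj,
        fates=fates,
        stats=stats,
        n_stripes_template=len(stripes_t),
        n_stripes_pattern=len(stripes_p),
        n_stripes_central=count_stripes_in_window(stripes_p, lo, hi),
        stripe_centers=[s_["center"] for s_ in stripes_p],
    )


# ---------------------------------------------------------------------------
# regime comparison

_METRICS = (
    "n_sop",
    "sop_density",
    "sop_fraction",
    "spacing_cv",
    "adjacent_sop_pairs",
    "n_stripes_template",
    "n_stripes_pattern",
    "n_stripes_central",
)


def _metrics_row(res: RunResult) -> dict:
    return {
        "n_sop": res.stats.n_sop,
        "sop_density": res.stats.sop_density,
        "sop_fraction": res.stats.sop_fraction,
        "spacing_cv": res.stats.spacing_cv,
        "adjacent_sop_pairs": res.stats.adjacent_sop_pairs,
        "n_stripes_template": res.n_stripes_template,
        "n_stripes_pattern": res.n_stripes_pattern,
        "n_stripes_central": res.n_stripes_central,
    }


def compare_regimes(
    regimes: Mapping[str, RunConfig],
    seeds: Sequence[int],
    share_lattice: bool = True,
) -> pd.DataFrame:
    """Replicated pattern statistics per regime.

    Runs every regime once per seed (same seed list for all regimes; with
    ``share_lattice`` the regimes of a given seed run on identical
    geometry, giving paired comparisons) and returns a table with one row
    per regime and ``<metric>_mean`` / ``<metric>_sd`` columns.
    """
    if len(regimes) < 2:
        raise ValueError("compare_regimes needs at least 2 regimes")
    if len(seeds) < 1:
        raise ValueError("compare_regimes needs at least one seed")
    per_run = []
    for seed in seeds:
        shared = None
        if share_lattice:
            first = next(iter(regimes.values()))
            lat_seed = int(_subseed(int(seed), 0).generate_state(1)[0] % (2**31))
            shared = build_lattice(first, seed=lat_seed)
        for name, cfg in regimes.items():
            res = run_config(cfg, seed=int(seed), lattice=shared)
            per_run.append({"regime": name, "seed": int(seed), **_metrics_row(res)})
    runs = pd.DataFrame(per_run)
    rows = []
    for name in regimes:
        sub = runs[runs["regime"] == name]
        row: dict = {"regime": name, "n_replicates": len(sub)}
        for m in _METRICS:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.attrs["per_run"] = runs
    return summary


# ---------------------------------------------------------------------------
# output writers

def write_run(res: RunResult, out_dir: str | Path) -> dict:
    """Write trajectory, fate and pattern files plus a manifest.

    Output is deterministic for a given (config, seed): no timestamps, and
    a stable column order.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj = res.trajectory
    n = res.lattice.n_cells
    T = len(traj.times)
    frame = pd.DataFrame(
        {
            "time": np.repeat(traj.times, n),
            "cell": np.tile(np.arange(n), T),
            "u": traj.u.ravel(),
            "s": traj.s.ravel(),
            "s_extrinsic": traj.s_extrinsic.ravel(),
        }
    )
    frame.to_csv(out / "trajectory.csv", index=False)
    fate_frame = pd.DataFrame(
        {
            "cell": np.arange(n),
            "x": res.lattice.positions[:, 0],
            "y": res.lattice.positions[:, 1],
            "u_final": traj.u[-1],
            "is_sop": res.fates.is_sop.astype(int),
        }
    )
    fate_frame.to_csv(out / "fates.csv", index=False)
    res.lattice.to_json(out / "lattice.json")
    manifest = {
        "package_version": __version__,
        "config": config_to_dict(res.config),
        "seed": traj.seed,
        "lattice_seed": res.lattice.seed,
        "fate_threshold": res.fates.threshold,
        "stats": {
            "n_sop": res.stats.n_sop,
            "sop_density": res.stats.sop_density,
            "sop_fraction": res.stats.sop_fraction,
            "spacing_cv": None if np.isnan(res.stats.spacing_cv) else res.stats.spacing_cv,
            "adjacent_sop_pairs": res.stats.adjacent_sop_pairs,
            "n_stripes_template": res.n_stripes_template,
            "n_stripes_pattern": res.n_stripes_pattern,
            "n_stripes_central": res.n_stripes_central,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return manifest
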