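"""Bistable lateral-inhibition dynamics on a cell lattice.

Each cell carries a scalar proneural activity ``u`` obeying

    tau du_i/dt = f(u_i - s_i) - u_i + eta_i(t)

where ``f`` is a steep logistic sigmoid in (0, 1) balancing self-activation
against inhibition, ``eta`` is Gaussian white noise, and the inhibitory
signal combines an extrinsic, time-interpolated spatial gradient with
instantaneous cell-cell signaling:

    s_i = s0(x_i, t) + sum_{j != i} c_ij D*(u_j)

``D*(u)`` is the (saturating, monotone) active-ligand output of a cell at
state ``u``.  For intermediate ``s`` a cell is bistable between a high-u
(precursor) and a low-u (epidermal) state; patterning emerges from the
competition of cells through ``s``.  Integration is explicit
Euler-Maruyama with a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .geometry import CellLattice, CouplingMatrix

__all__ = [
    "ModelParams",
    "SpatialProfile",
    "GradientParams",
    "CellStateField",
    "SignalField",
    "Trajectory",
    "activation",
    "ligand_activity",
    "extrinsic_signal",
    "total_signal",
    "simulate",
    "single_cell_fixed_points",
    "bistability_window",
    "resolve_fate_threshold",
]


@dataclass(frozen=True)
class ModelParams:
    """Single-cell model parameters.

    tau : characteristic relaxation time (time units).
    f_steepness : width epsilon of the sigmoid transition (state units);
        smaller is steeper.
    f_threshold : offset of the sigmoid midpoint of ``f``.
    noise_sigma : white-noise amplitude (state units per sqrt(time)).
    ligand_midpoint, ligand_steepness : shape of the ligand output D*(u),
        a logistic in u rescaled to D*(0) = 0 and D*(1) = 1.
    fate_threshold : u value separating precursor from epidermal calls;
        ``None`` means "midpoint of the stable branches at the center of
        the bistability window" (see :func:`resolve_fate_threshold`).
    """

    tau: float = 1.0
    f_steepness: float = 0.05
    f_threshold: float = 0.0
    noise_sigma: float = 0.02
    ligand_midpoint: float = 0.5
    ligand_steepness: float = 0.1
    fate_threshold: float | None = None

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.f_steepness <= 0:
            raise ValueError(f"f_steepness must be positive, got {self.f_steepness}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.ligand_steepness <= 0:
            raise ValueError("ligand_steepness must be positive")


def activation(v, params: ModelParams):
    """Sigmoidal activation f(v): logistic from 0 to 1, midpoint at
    ``f_threshold``, slope 1/(4*f_steepness) there."""
    return expit((np.asarray(v, dtype=float) - params.f_threshold) / params.f_steepness)


def ligand_activity(u, params: ModelParams):
    """Active ligand output D*(u): monotone, D*(0)=0, D*(1)=1, clipped to
    [0, 1] outside the unit interval."""
    lo = expit((0.0 - params.ligand_midpoint) / params.ligand_steepness)
    hi = expit((1.0 - params.ligand_midpoint) / params.ligand_steepness)
    raw = expit((np.asarray(u, dtype=float) - params.ligand_midpoint) / params.ligand_steepness)
    return np.clip((raw - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# extrinsic gradient

@dataclass(frozen=True)
class SpatialProfile:
    """Periodic-in-x signal profile: baseline plus signed Gaussian bumps.

    ``bumps`` is a sequence of (center, amplitude, width) triples; negative
    amplitudes carve permissive notches out of an inhibitory plateau.
    Distances to bump centers use the minimum image with period ``period``.
    Values are floored at 0 (an inhibitory signal cannot be negative).
    """

    baseline: float = 0.0
    bumps: tuple = ()
    period: float = 20.0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        for c, a, w in self.bumps:
            if w <= 0:
                raise ValueError(f"bump width must be positive, got {w}")

    def value(self, x):
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, self.baseline)
        for c, a, w in self.bumps:
            dx = x - c
            dx -= self.period * np.round(dx / self.period)
            out = out + a * np.exp(-0.5 * (dx / w) ** 2)
        return np.maximum(out, 0.0)


@dataclass(frozen=True)
class GradientParams:
    """Time-dependent extrinsic signaling gradient s0(x, t).

    Interpolates linearly in time between an early profile (the
    proneural-independent negative template) and a late profile (the
    inhibitory signal emanating from the flanking stripes) over
    ``[t_start, t_end]``.
    """

    early: SpatialProfile
    late: SpatialProfile
    t_start: float = 8.0
    t_end: float = 16.0

    def __post_init__(self):
        if self.t_start > self.t_end:
            raise ValueError(
                f"t_start ({self.t_start}) must not exceed t_end ({self.t_end})"
            )

    def weight(self, t: float) -> float:
        if t <= self.t_start:
            return 0.0
        if t >= self.t_end:
            return 1.0
        return (t - self.t_start) / (self.t_end - self.t_start)


def extrinsic_signal(x, t: float, g: GradientParams):
    """Evaluate s0(x, t)."""
    w = g.weight(t)
    if w == 0.0:
        return g.early.value(x)
    if w == 1.0:
        return g.late.value(x)
    return (1.0 - w) * g.early.value(x) + w * g.late.value(x)


# ---------------------------------------------------------------------------
# fields

@dataclass(frozen=True)
class CellStateField:
    """Per-cell proneural activity at a time point."""

    u: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class SignalField:
    """Per-cell inhibitory signal with its extrinsic / cell-cell split."""

    extrinsic: np.ndarray
    cell_cell: np.ndarray

    @property
    def s(self) -> np.ndarray:
        return self.extrinsic + self.cell_cell


def total_signal(
    state: CellStateField,
    lattice: CellLattice,
    coupling: CouplingMatrix,
    g: GradientParams,
    params: ModelParams,
    t: float | None = None,
) -> SignalField:
    """Instantaneous signal s_i = s0(x_i, t) + sum_j c_ij D*(u_j)."""
    u = np.asarray(state.u, dtype=float)
    if u.shape != (lattice.n_cells,):
        raise ValueError(
            f"state has {u.shape} values for a lattice of {lattice.n_cells} cells"
        )
    if coupling.weights.shape != (lattice.n_cells, lattice.n_cells):
        raise ValueError("coupling matrix does not match lattice size")
    tt = state.t if t is None else t
    ext = np.asarray(extrinsic_signal(lattice.positions[:, 0], tt, g), dtype=float)
    cc = coupling.weights @ ligand_activity(u, params)
    return SignalField(extrinsic=ext, cell_cell=np.asarray(cc).ravel())


@dataclass(frozen=True)
class Trajectory:
    """Recorded time series of a seeded simulation."""

    times: np.ndarray
    u: np.ndarray          # (T, n)
    s: np.ndarray          # (T, n)
    s_extrinsic: np.ndarray  # (T, n)
    params: ModelParams
    seed: int
    lattice: CellLattice = field(repr=False, default=None)

    @property
    def final_state(self) -> CellStateField:
        return CellStateField(u=self.u[-1], t=float(self.times[-1]))

    def snapshot(self, t: float) -> CellStateField:
        """State at the recorded time nearest to ``t``."""
        k = int(np.argmin(np.abs(self.times - t)))
        return CellStateField(u=self.u[k], t=float(self.times[k]))


# ---------------------------------------------------------------------------
# integration

def simulate(
    lattice: CellLattice,
    coupling: CouplingMatrix,
    params: ModelParams,
    g: GradientParams,
    u0: CellStateField | np.ndarray | None = None,
    t_end: float = 30.0,
    dt: float = 0.02,
    record_every: int = 25,
    seed: int = 0,
) -> Trajectory:
    """Integrate the lattice dynamics by explicit Euler-Maruyama.

    ``u0=None`` draws independent uniform initial states on [0, 0.1] from
    the same seeded generator as the noise, so a (lattice, params, seed)
    triple fully determines the trajectory.  Snapshots of ``u`` and ``s``
    are stored every ``record_every`` steps (plus the initial and final
    states).

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite, naming the first offending step.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > params.tau / 10:
        raise ValueError(
            f"dt={dt} too coarse for tau={params.tau}; need dt <= tau/10"
        )
    if record_every < 1:
        raise ValueError("record_every must be >= 1")
    n = lattice.n_cells
    rng = np.random.default_rng(seed)
    if u0 is None:
        u = rng.uniform(0.0, 0.1, size=n)
    elif isinstance(u0, CellStateField):
        u = np.array(u0.u, dtype=float, copy=True)
    else:
        u = np.array(u0, dtype=float, copy=True)
    if u.shape != (n,):
        raise ValueError(f"u0 has shape {u.shape}, expected ({n},)")

    n_steps = int(round(t_end / dt))
    x = lattice.positions[:, 0]
    early = np.asarray(g.early.value(x), dtype=float)
    late = np.asarray(g.late.value(x), dtype=float)
    W = coupling.weights
    inv_tau = dt / params.tau
    noise_scale = params.noise_sigma * np.sqrt(dt)

    times, u_snaps, s_snaps, ext_snaps = [], [], [], []

    def record(step: int, u_now: np.ndarray):
        t = step * dt
        w = g.weight(t)
        ext = (1.0 - w) * early + w * late
        s = ext + W @ ligand_activity(u_now, params)
        times.append(t)
        u_snaps.append(u_now.copy())
        s_snaps.append(np.asarray(s).ravel())
        ext_snaps.append(ext)

    record(0, u)
    for step in range(n_steps):
        t = step * dt
        w = g.weight(t)
        ext = (1.0 - w) * early + w * late
        s = ext + W @ ligand_activity(u, params)
        du = inv_tau * (activation(u - s, params) - u)
        if noise_scale > 0:
            du = du + noise_scale * rng.standard_normal(n)
        u = u + du
        if not np.all(np.isfinite(u)):
            bad = int(np.flatnonzero(~np.isfinite(u))[0])
            raise FloatingPointError(
                f"non-finite state at step {step + 1} (t={t + dt:.4f}), "
                f"first offending cell {bad}"
            )
        if (step + 1) % record_every == 0 or step + 1 == n_steps:
            if not times or times[-1] != (step + 1) * dt:
                record(step + 1, u)

    return Trajectory(
        times=np.asarray(times),
        u=np.asarray(u_snaps),
        s=np.asarray(s_snaps),
        s_extrinsic=np.asarray(ext_snaps),
        params=params,
        seed=seed,
        lattice=lattice,
    )


# ---------------------------------------------------------------------------
# single-cell analysis

def single_cell_fixed_points(
    s: float, params: ModelParams, u_min: float = -0.5, u_max: float = 1.5
) -> list[tuple[float, bool]]:
    """Fixed points of du/dt = f(u - s) - u at clamped signal ``s``.

    Roots are bracketed by a sign-change scan on a fine grid and refined
    with Brent's method; a root is stable when d/du [f(u-s) - u] < 0.
    Returns (u*, stable) pairs sorted by u*.
    """
    F = lambda u: activation(u - s, params) - u
    grid = np.linspace(u_min, u_max, 4001)
    vals = F(grid)
    roots: list[float] = []
    for k in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        roots.append(brentq(F, grid[k], grid[k + 1], xtol=1e-12))
    for k in np.flatnonzero(vals == 0):
        roots.append(float(grid[k]))
    roots = sorted(roots)
    out = []
    eps = 1e-7
    for r in roots:
        if out and abs(r - out[-1][0]) < 1e-9:
            continue
        slope = (F(r + eps) - F(r - eps)) / (2 * eps)
        out.append((float(r), bool(slope < 0)))
    return out


def bistability_window(
    params: ModelParams, s_min: float = -1.0, s_max: float = 2.0, n: int = 601
) -> tuple[float, float]:
    """Interval of clamped signal s over which the cell is bistable.

    Scans ``n`` values of s and returns (s_lo, s_hi), the extremes at which
    two stable fixed points coexist.  Raises if no bistable s exists.
    """
    ss = np.linspace(s_min, s_max, n)
    bistable = [
        s for s in ss
        if sum(st for _, st in single_cell_fixed_points(s, params)) == 2
    ]
    if not bistable:
        raise ValueError("no bistable signal range for these parameters")
    return float(min(bistable)), float(max(bistable))


def resolve_fate_threshold(params: ModelParams) -> float:
    """Fate-call threshold on terminal u.

    Explicit ``fate_threshold`` wins; otherwise the midpoint of the two
    stable branches at the center of the bistability window, a scale-free
    proxy for the separatrix between the precursor and epidermal states.
    """
    if params.fate_threshold is not None:
        return params.fate_threshold
    s_lo, s_hi = bistability_window(params)
    s_mid = 0.5 * (s_lo + s_hi)
    stable = [u for u, st in single_cell_fixed_points(s_mid, params) if st]
    return 0.5 * (stable[0] + stable[-1])
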