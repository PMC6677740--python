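"""Seeded generators for synthetic test inputs.

Two kinds of inputs are produced here: synthetic segmented-nucleus tables
that mimic the structure of confocal images of the pupal notum around
proneural stripe 3 (a central proneural channel, an early-onset reporter
peaking on the stripe flanks, a late-onset reporter expressed in
low/intermediate proneural cells but depleted in the precursors
themselves), and regime presets that map genetic perturbations onto
parameter changes of the simulation config.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import RunConfig
from .dynamics import CellStateField
from .geometry import CellLattice
from .profiles import Centerline

__all__ = [
    "FieldSpec",
    "REGIME_NAMES",
    "generate_nucleus_field",
    "make_regime_config",
    "planted_stripe_field",
]


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and intensity model of a synthetic nucleus field.

    The image is ``width x height`` um with the stripe running
    horizontally through ``stripe_center_y``.  Nuclei are placed by a
    hard-core (dart-throwing) point process with a minimum center spacing.
    Channel means are functions of the signed distance ``d`` to the stripe
    centerline:

    - proneural channel: Gaussian peak at d = 0, boosted in precursors;
    - early-onset reporter: two Gaussian flanks at ``+-flank_offset``;
    - late-onset reporter: broad central bump, zeroed in precursors.

    Precursors (SOPs) sit along the centerline at regular spacing plus
    jitter; the nucleus nearest each anchor is marked.  Raw intensity is
    ``gain * mean(d) + noise`` clipped at zero, with a lognormal per-image,
    per-channel gain and additive Gaussian noise.
    """

    width: float = 80.0
    height: float = 60.0
    n_nuclei: int = 400
    min_spacing: float = 2.0
    stripe_center_y: float = 30.0
    stripe_width: float = 8.0        # ~2 sigma of the proneural peak
    flank_offset: float = 7.0
    flank_width: float = 2.5
    late_width: float = 4.0
    sop_spacing: float = 6.0
    sop_jitter: float = 1.0
    sop_boost: float = 1.6
    gain_sigma: float = 0.3          # lognormal sigma of per-image gain
    noise_sd: float = 0.05
    channels: tuple = ("ac", "m3", "m7")
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height, self.min_spacing, self.stripe_width,
               self.flank_width, self.late_width, self.sop_spacing) <= 0:
            raise ValueError("all lengths in FieldSpec must be positive")
        if self.noise_sd < 0 or self.gain_sigma < 0:
            raise ValueError("noise_sd and gain_sigma must be >= 0")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")

    def centerline(self) -> Centerline:
        return Centerline(
            np.array([[0.0, self.stripe_center_y], [self.width, self.stripe_center_y]])
        )

    def channel_mean(self, channel: str, d: np.ndarray, is_sop: np.ndarray) -> np.ndarray:
        """Noise-free mean intensity of ``channel`` at signed distance d."""
        d = np.asarray(d, dtype=float)
        sig = self.stripe_width / 2.0
        if channel == "ac":
            base = np.exp(-0.5 * (d / sig) ** 2)
            return np.where(is_sop, self.sop_boost * base, base)
        if channel == "m3":
            return (
                np.exp(-0.5 * ((d - self.flank_offset) / self.flank_width) ** 2)
                + np.exp(-0.5 * ((d + self.flank_offset) / self.flank_width) ** 2)
            )
        if channel == "m7":
            return np.exp(-0.5 * (d / self.late_width) ** 2) * (~is_sop)
        raise ValueError(f"unknown channel {channel!r}")


def _hard_core_points(
    rng: np.random.Generator, n: int, w: float, h: float, spacing: float
) -> np.ndarray:
    coverage = n * np.pi * (spacing / 2) ** 2 / (w * h)
    if coverage > 0.45:
        raise ValueError(
            f"requested density is infeasible under min_spacing={spacing} "
            f"(disc coverage {coverage:.2f} > 0.45); reduce n_nuclei or spacing"
        )
    pts: list[np.ndarray] = []
    cell = spacing / np.sqrt(2)
    grid: dict[tuple[int, int], list[int]] = {}
    attempts = 0
    max_attempts = 2000 * n
    while len(pts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("hard-core sampling failed to converge")
        p = rng.uniform([0, 0], [w, h])
        gx, gy = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for ix in range(gx - 2, gx + 3):
            for iy in range(gy - 2, gy + 3):
                for k in grid.get((ix, iy), ()):
                    if np.hypot(*(pts[k] - p)) < spacing:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(pts))
            pts.append(p)
    return np.asarray(pts)


def generate_nucleus_field(spec: FieldSpec, n_images: int = 1) -> pd.DataFrame:
    """Generate one or more synthetic images of segmented nuclei.

    Returns a table in the dialect consumed by the profiling pipeline:
    columns ``image_id, nucleus_id, x_um, y_um`` plus one raw-intensity
    column per channel.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    streams = np.random.SeedSequence(spec.seed).spawn(n_images)
    frames = []
    for img, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pts = _hard_core_points(rng, spec.n_nuclei, spec.width, spec.height, spec.min_spacing)
        d = pts[:, 1] - spec.stripe_center_y

        # precursor anchors along the centerline, regular spacing + jitter
        n_sops = max(1, int(spec.width // spec.sop_spacing))
        anchors_x = (np.arange(n_sops) + 0.5) * spec.width / n_sops
        anchors_x = anchors_x + rng.normal(scale=spec.sop_jitter, size=n_sops)
        anchors_y = spec.stripe_center_y + rng.normal(scale=spec.sop_jitter, size=n_sops)
        is_sop = np.zeros(len(pts), dtype=bool)
        for ax, ay in zip(anchors_x, anchors_y):
            is_sop[np.argmin(np.hypot(pts[:, 0] - ax, pts[:, 1] - ay))] = True

        data = {
            "image_id": np.full(len(pts), img),
            "nucleus_id": np.arange(len(pts)),
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
        }
        for ch in spec.channels:
            gain = float(np.exp(rng.normal(scale=spec.gain_sigma))) if spec.gain_sigma > 0 else 1.0
            mean = spec.channel_mean(ch, d, is_sop)
            noise = rng.normal(scale=spec.noise_sd, size=len(pts)) if spec.noise_sd > 0 else 0.0
            data[ch] = np.maximum(gain * mean + noise, 0.0)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# regime presets

REGIME_NAMES = ("wild_type", "no_template", "reduced_late_inhibition", "no_inhibition")


def make_regime_config(name: str, base: RunConfig) -> RunConfig:
    """Apply a named perturbation preset to a base config.

    - ``wild_type``: the base config unchanged.
    - ``no_template``: flattens the early-profile notches (loss of the
      proneural-independent Notch template); the late profile still drives
      the flank stripes.
    - ``reduced_late_inhibition``: scales the cell-state-dependent
      contribution to inhibition (the coupling strength) by
      ``base.regimes.late_inhibition_factor`` (default 0.6), mimicking
      loss of the late-onset repressors.
    - ``no_inhibition``: zero coupling strength and a flat late profile
      (complete loss of mutual inhibition).
    """
    if name not in REGIME_NAMES:
        raise ValueError(
            f"unknown regime {name!r}; valid names: {', '.join(REGIME_NAMES)}"
        )
    cfg = copy.deepcopy(base)
    cfg.regime = name
    if name == "wild_type":
        return cfg
    if name == "no_template":
        cfg.gradient.early_bumps = []
        return cfg
    if name == "reduced_late_inhibition":
        cfg.coupling.strength *= cfg.regimes.late_inhibition_factor
        return cfg
    # no_inhibition
    cfg.coupling.strength = 0.0
    cfg.gradient.late_baseline = 0.0
    cfg.gradient.late_bumps = []
    return cfg


def planted_stripe_field(
    lattice: CellLattice,
    centers: "list[float]",
    widths: "list[float] | float",
    high: float = 1.0,
    low: float = 0.0,
) -> CellStateField:
    """Ground-truth state field: ``high`` inside periodic x-stripes."""
    if high <= low:
        raise ValueError("high must exceed low")
    if np.isscalar(widths):
        widths = [float(widths)] * len(centers)
    if len(widths) != len(centers):
        raise ValueError("centers and widths must have equal length")
    x = lattice.positions[:, 0]
    u = np.full(lattice.n_cells, float(low))
    for c, w in zip(centers, widths):
        dx = x - c
        dx -= lattice.box_width * np.round(dx / lattice.box_width)
        u[np.abs(dx) <= w / 2] = high
    return CellStateField(u=u, t=0.0)
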