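"""Disordered periodic cell lattices and distance-decaying signaling kernels.

The tissue is modeled as a fixed arrangement of cell centers on a 2-D torus
(periodic box).  Cell positions are generated by jittering a regular
hexagonal packing and relaxing it toward a centroidal Voronoi tessellation
(Lloyd iterations), which yields near-uniform cell areas with disordered
neighbor topology -- a lightweight stand-in for a mechanical vertex model,
of which only the static geometry is needed here.  Cell-cell signaling
weights decay with the minimum-image periodic distance between cell centers.

Lengths are expressed in mean cell diameters, defined as
``sqrt(box_area / n_cells)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.spatial import Delaunay, Voronoi, cKDTree

__all__ = [
    "CellLattice",
    "CouplingMatrix",
    "build_disordered_lattice",
    "compute_coupling",
    "periodic_distance",
]

_HEX_ASPECT = 2.0 / np.sqrt(3.0)  # ideal dx/dy of a hexagonal packing


@dataclass(frozen=True)
class CellLattice:
    """Fixed cell positions on a periodic box with Voronoi areas and
    Delaunay adjacency.

    Attributes
    ----------
    positions : (n, 2) array
        Cell centers in ``[0, box_width) x [0, box_height)``.
    box_width, box_height : float
        Periodic box dimensions (cell diameters).
    areas : (n,) array
        Voronoi cell areas; they tile the torus exactly.
    neighbor_pairs : frozenset of (i, j)
        Unordered periodic-Delaunay adjacency, ``i < j``.
    seed : int
        Seed used at generation (-1 for hand-built lattices).
    """

    positions: np.ndarray
    box_width: float
    box_height: float
    areas: np.ndarray
    neighbor_pairs: frozenset = field(repr=False)
    seed: int = -1

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def box_area(self) -> float:
        return self.box_width * self.box_height

    @property
    def cell_diameter(self) -> float:
        return float(np.sqrt(self.box_area / self.n_cells))

    def degree(self) -> np.ndarray:
        """Number of Delaunay neighbors per cell."""
        deg = np.zeros(self.n_cells, dtype=int)
        for i, j in self.neighbor_pairs:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_json(self, path: str | Path) -> None:
        payload = {
            "box_width": self.box_width,
            "box_height": self.box_height,
            "seed": self.seed,
            "positions": self.positions.tolist(),
            "areas": self.areas.tolist(),
            "neighbor_pairs": sorted(map(list, self.neighbor_pairs)),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CellLattice":
        d = json.loads(Path(path).read_text())
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            box_width=float(d["box_width"]),
            box_height=float(d["box_height"]),
            areas=np.asarray(d["areas"], dtype=float),
            neighbor_pairs=frozenset(tuple(p) for p in d["neighbor_pairs"]),
            seed=int(d["seed"]),
        )


@dataclass(frozen=True)
class CouplingMatrix:
    """Sparse symmetric nonnegative signaling kernel c_ij over cell pairs."""

    weights: sparse.csr_matrix
    signaling_range: float
    cutoff_radius: float
    strength: float
    normalized: bool = False

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def to_edge_csv(self, lattice: CellLattice, path: str | Path) -> None:
        coo = self.weights.tocoo()
        lines = ["i,j,distance,weight"]
        order = np.lexsort((coo.col, coo.row))
        for k in order:
            i, j = int(coo.row[k]), int(coo.col[k])
            if i < j:
                d = periodic_distance(lattice, i, j)
                lines.append(f"{i},{j},{d!r},{coo.data[k]!r}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# lattice construction

def _hex_factorization(n_cells: int, box_width: float, box_height: float):
    """Best (n_cols, n_rows) split of n_cells for a periodic hex packing.

    Rows must come in even number so the half-column offset wraps
    consistently in y.  Returns None when no admissible split exists.
    """
    best, best_score = None, np.inf
    for nc in range(1, n_cells + 1):
        if n_cells % nc:
            continue
        nr = n_cells // nc
        if nr > 1 and nr % 2:
            continue
        dx = box_width / nc
        dy = box_height / nr
        score = abs(np.log(dx / dy / _HEX_ASPECT))
        if score < best_score:
            best, best_score = (nc, nr), score
    # a grossly anisotropic "hexagonal" packing is not one; refuse > ~2x
    if best is not None and best_score > np.log(2.0):
        return None
    return best


def _hex_positions(n_cols: int, n_rows: int, w: float, h: float) -> np.ndarray:
    dx, dy = w / n_cols, h / n_rows
    cols = np.arange(n_cols)
    rows = np.arange(n_rows)
    xx = (cols[None, :] + 0.5 * (rows[:, None] % 2) + 0.25) * dx
    yy = np.broadcast_to((rows[:, None] + 0.5) * dy, xx.shape)
    pts = np.column_stack([xx.ravel() % w, yy.ravel()])
    return pts


def _tiled(points: np.ndarray, w: float, h: float) -> np.ndarray:
    """3x3 periodic tiling with the central copy first."""
    shifts = [(0.0, 0.0)]
    shifts += [
        (i * w, j * h)
        for j in (-1, 0, 1)
        for i in (-1, 0, 1)
        if not (i == 0 and j == 0)
    ]
    return np.concatenate([points + np.asarray(s) for s in shifts])


def _polygon_area_centroid(verts: np.ndarray) -> tuple[float, np.ndarray]:
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return abs(a), np.array([cx, cy])


def _voronoi_cells(points: np.ndarray, w: float, h: float):
    """Areas and centroids of the periodic Voronoi cells of ``points``."""
    vor = Voronoi(_tiled(points, w, h))
    n = len(points)
    areas = np.empty(n)
    centroids = np.empty((n, 2))
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        areas[i], centroids[i] = _polygon_area_centroid(verts)
    return areas, centroids


def _delaunay_pairs(points: np.ndarray, w: float, h: float) -> frozenset:
    n = len(points)
    if n == 1:
        return frozenset()
    tri = Delaunay(_tiled(points, w, h))
    pairs = set()
    simplices = tri.simplices
    for a, b in ((0, 1), (0, 2), (1, 2)):
        p, q = simplices[:, a], simplices[:, b]
        mask = (p < n) | (q < n)
        for pi, qi in zip(p[mask] % n, q[mask] % n):
            if pi != qi:
                pairs.add((int(min(pi, qi)), int(max(pi, qi))))
    return frozenset(pairs)


def build_disordered_lattice(
    n_cells: int,
    box_width: float,
    box_height: float,
    disorder: float = 0.3,
    seed: int = 0,
    lloyd_iterations: int = 20,
) -> CellLattice:
    """Generate a fixed, periodic, disordered cell-center arrangement.

    Starts from a regular hexagonal packing, applies seeded Gaussian jitter
    of standard deviation ``disorder`` cell diameters, then runs
    ``lloyd_iterations`` steps of centroidal-Voronoi relaxation on the torus.
    ``disorder=0`` returns the regular packing unchanged.

    Raises
    ------
    ValueError
        For non-positive sizes, or when ``disorder=0`` and ``n_cells`` does
        not admit a hexagonal packing commensurate with the box.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    if box_width <= 0 or box_height <= 0:
        raise ValueError(
            f"box dimensions must be positive, got {box_width} x {box_height}"
        )
    if not 0.0 <= disorder <= 1.0:
        raise ValueError(f"disorder must lie in [0, 1], got {disorder}")
    w, h = float(box_width), float(box_height)

    if n_cells == 1:
        return CellLattice(
            positions=np.array([[w / 2, h / 2]]),
            box_width=w,
            box_height=h,
            areas=np.array([w * h]),
            neighbor_pairs=frozenset(),
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    split = _hex_factorization(n_cells, w, h)
    if split is None:
        if disorder == 0:
            raise ValueError(
                f"no hexagonal packing of {n_cells} cells is commensurate "
                f"with a {w} x {h} box; choose n_cells = n_cols * n_rows "
                "with an even number of rows, or set disorder > 0"
            )
        pts = rng.uniform([0, 0], [w, h], size=(n_cells, 2))
    else:
        pts = _hex_positions(*split, w, h)

    if disorder > 0:
        diam = np.sqrt(w * h / n_cells)
        pts = pts + rng.normal(scale=disorder * diam, size=pts.shape)
        pts[:, 0] %= w
        pts[:, 1] %= h
        for _ in range(lloyd_iterations):
            _, centroids = _voronoi_cells(pts, w, h)
            pts = centroids
            pts[:, 0] %= w
            pts[:, 1] %= h

    areas, _ = _voronoi_cells(pts, w, h)
    return CellLattice(
        positions=pts,
        box_width=w,
        box_height=h,
        areas=areas,
        neighbor_pairs=_delaunay_pairs(pts, w, h),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# distances and coupling

def periodic_displacement(lattice: CellLattice, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Minimum-image displacement q - p on the torus (broadcasting)."""
    box = np.array([lattice.box_width, lattice.box_height])
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - box * np.round(d / box)


def periodic_distance(lattice: CellLattice, i: int, j: int) -> float:
    """Minimum-image distance between cells ``i`` and ``j``."""
    n = lattice.n_cells
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"cell index out of range: ({i}, {j}) for n={n}")
    d = periodic_displacement(lattice, lattice.positions[i], lattice.positions[j])
    return float(np.hypot(*d))


def _sinkhorn_balance(w: sparse.csr_matrix, target: float) -> sparse.csr_matrix:
    """Symmetric diagonal balancing so every row sums to ``target``."""
    n = w.shape[0]
    d = np.ones(n)

    def scaled(dv: np.ndarray) -> sparse.csr_matrix:
        dm = sparse.diags(dv)
        return sparse.csr_matrix(dm @ w @ dm)

    for _ in range(10_000):
        rs = np.asarray(scaled(d).sum(axis=1)).ravel()
        if np.any(rs <= 0):
            raise ValueError(
                "cannot normalize coupling: some cell has no neighbor "
                "within the cutoff radius"
            )
        err = np.max(np.abs(rs - target))
        if err < 1e-12 * max(target, 1.0):
            break
        d = d * np.sqrt(target / rs)
    return scaled(d)


def compute_coupling(
    lattice: CellLattice,
    signaling_range: float,
    strength: float = 1.0,
    cutoff_factor: float = 3.0,
    normalized: bool = False,
) -> CouplingMatrix:
    """Distance-decaying signaling kernel on the lattice.

    ``weights[i, j] = strength * exp(-(d_ij / l)^2 / 2)`` for minimum-image
    distance ``d_ij <= cutoff_factor * l``, with zero diagonal.  When
    ``normalized`` is true the matrix is symmetrically balanced so every row
    sums to ``strength`` (signal received is the same for every cell).
    """
    if signaling_range <= 0:
        raise ValueError(f"signaling_range must be positive, got {signaling_range}")
    if cutoff_factor < 1:
        raise ValueError(f"cutoff_factor must be >= 1, got {cutoff_factor}")
    if strength < 0:
        raise ValueError(f"strength must be >= 0, got {strength}")
    n = lattice.n_cells
    cutoff = cutoff_factor * signaling_range
    box = (lattice.box_width, lattice.box_height)
    tree = cKDTree(lattice.positions, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        disp = periodic_displacement(
            lattice, lattice.positions[pairs[:, 0]], lattice.positions[pairs[:, 1]]
        )
        dist = np.hypot(disp[:, 0], disp[:, 1])
        vals = strength * np.exp(-0.5 * (dist / signaling_range) ** 2)
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.concatenate([vals, vals])
        w = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
    else:
        w = sparse.csr_matrix((n, n))
    if normalized:
        w = _sinkhorn_balance(w, strength)
    return CouplingMatrix(
        weights=w,
        signaling_range=signaling_range,
        cutoff_radius=cutoff,
        strength=strength,
        normalized=normalized,
    )
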