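"""Synthetic inputs: irregular domain masks, planted hexagonal lattices and
five-time-point protein abundance tables.

These generators stand in for the study's raw inputs (EM-derived inter-cellular
space outlines, manually picked fibril centers, and LCM-MS abundance tables) so
the whole pipeline runs and is testable offline. Every generator is seeded and
bit-reproducible.

The planted-lattice ground truth is computed by a deliberately slow,
self-contained empty-circumcircle Delaunay oracle (`reference_delaunay_edges`),
independent of the Qhull-based production pipeline in :mod:`fibrilpfc.defects`,
so tests comparing the two are not self-confirming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DomainMask, GridSpec

TIMEPOINTS = ("E12.5", "E13.0", "E13.5", "E14.0", "E14.5")

# Noiseless trend profiles (multiples of the E12.5 baseline). "peak" mirrors
# the soluble collagen-I signature: rise to a maximum at E13.5 as protomer
# accumulates, then decline as it is incorporated into insoluble fibrils.
TREND_PROFILES = {
    "peak": np.array([1.0, 2.5, 5.0, 2.5, 1.2]),
    "rise": np.array([1.0, 1.6, 2.6, 4.2, 6.8]),
    "flat": np.array([1.0, 1.0, 1.0, 1.0, 1.0]),
}


# ---------------------------------------------------------------------------
# Irregular domain masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticDomainSpec:
    """Star-convex blob with a seeded Fourier-perturbed boundary.

    The radius is ``mean_radius * (1 + p(theta))`` where ``p`` is a random
    cosine series over angular modes 2..n_modes+1, normalized so that
    ``|p| <= boundary_roughness`` everywhere.
    """

    mean_radius: float  # nm
    boundary_roughness: float = 0.3
    n_modes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.boundary_roughness < 1.0):
            raise ValueError("boundary_roughness must be in [0, 1)")
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")


def gen_domain_mask(grid: GridSpec, spec: SyntheticDomainSpec) -> DomainMask:
    """Rasterize a seeded star-convex blob as a binary domain mask.

    Pixels are inside when their center lies within the perturbed radius.
    Raises if the blob cannot fit inside the grid or if the rasterized mask
    touches the grid border (the masked solver needs room for its boundary
    treatment).
    """
    r_max = spec.mean_radius * (1.0 + spec.boundary_roughness)
    half_w = grid.width_nm / 2.0
    half_h = grid.height_nm / 2.0
    if r_max >= min(half_w, half_h):
        raise ValueError(
            f"blob max radius {r_max:.1f} nm does not fit in grid "
            f"({grid.width_nm:.0f} x {grid.height_nm:.0f} nm)"
        )
    rng = np.random.default_rng(spec.seed)
    modes = np.arange(2, spec.n_modes + 2)
    amps = rng.standard_normal(spec.n_modes)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.n_modes)

    x, y = grid.pixel_centers()
    cx, cy = half_w, half_h
    dx_, dy_ = x - cx, y - cy
    rho = np.hypot(dx_, dy_)
    theta = np.arctan2(dy_, dx_)

    # Normalize so the perturbation magnitude is bounded by the roughness.
    denom = np.abs(amps).sum()
    if denom == 0.0:
        pert = np.zeros_like(theta)
    else:
        pert = (
            spec.boundary_roughness
            * np.sum(
                amps[:, None, None]
                * np.cos(modes[:, None, None] * theta[None] + phases[:, None, None]),
                axis=0,
            )
            / denom
        )
    inside = rho <= spec.mean_radius * (1.0 + pert)
    if not inside.any():
        raise ValueError("generated mask is empty")
    mask = DomainMask(inside, grid)
    if mask.touches_border():
        raise ValueError("mask touches the grid border; enlarge the grid")
    if mask.n_components() != 1:
        raise ValueError(
            "mask is not a single 4-connected component; "
            "reduce boundary_roughness or n_modes"
        )
    return mask


# ---------------------------------------------------------------------------
# Reference Delaunay oracle (independent of scipy.spatial.Delaunay)
# ---------------------------------------------------------------------------


def reference_delaunay(
    points: np.ndarray, chunk: int = 20000
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force Delaunay triangles and edges by the empty-circumcircle test.

    For every point triple, the circumcircle is tested for strict emptiness;
    empty-circumcircle triples are the Delaunay triangles and their sides the
    Delaunay edges. O(n^4) work overall — intended as an independent oracle
    for n <= ~200, not for production use. Exactly cocircular quadruples are
    not handled specially (tests avoid them).

    Returns ``(triangles, edges)`` as int arrays of shape (t, 3) and (m, 2).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    scale = max(pts.max(axis=0).max() - pts.min(axis=0).min(), 1e-300)
    tol = 1e-9 * scale

    idx = np.array(
        [(i, j, k) for i in range(n) for j in range(i + 1, n) for k in range(j + 1, n)]
    )
    edges: set[tuple[int, int]] = set()
    triangles: list[tuple[int, int, int]] = []
    for start in range(0, len(idx), chunk):
        tri = idx[start : start + chunk]
        a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
        d = 2.0 * (
            a[:, 0] * (b[:, 1] - c[:, 1])
            + b[:, 0] * (c[:, 1] - a[:, 1])
            + c[:, 0] * (a[:, 1] - b[:, 1])
        )
        ok = np.abs(d) > 1e-12 * scale**2  # drop (near-)collinear triples
        if not ok.any():
            continue
        tri, a, b, c, d = tri[ok], a[ok], b[ok], c[ok], d[ok]
        a2 = (a**2).sum(axis=1)
        b2 = (b**2).sum(axis=1)
        c2 = (c**2).sum(axis=1)
        ux = (
            a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])
        ) / d
        uy = (
            a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])
        ) / d
        center = np.stack([ux, uy], axis=1)
        r = np.linalg.norm(a - center, axis=1)
        # distance from every point to every circumcenter
        d2 = ((pts[None, :, :] - center[:, None, :]) ** 2).sum(axis=2)
        inside = d2 < (r[:, None] - tol) ** 2
        empty = ~inside.any(axis=1)
        for t in tri[empty]:
            i, j, k = int(t[0]), int(t[1]), int(t[2])
            triangles.append((i, j, k))
            edges.add((i, j))
            edges.add((i, k))
            edges.add((j, k))
    if not edges:
        raise ValueError("no Delaunay triangle found (points may be collinear)")
    return np.array(sorted(triangles), dtype=int), np.array(sorted(edges), dtype=int)


def _prune_edges(
    points: np.ndarray, edges: np.ndarray, prune_factor: float
) -> np.ndarray:
    lengths = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
    cutoff = prune_factor * np.median(lengths)
    return edges[lengths <= cutoff]


def reference_analysis(
    points: np.ndarray, prune_factor: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oracle neighbor counts and interior flags for a point set.

    Returns ``(edges, neighbor_counts, interior)`` using the same rules as the
    production pipeline — Delaunay edges pruned at ``prune_factor`` x median
    edge length; a point is peripheral when incident to a pruned-graph edge
    bounding at most one surviving triangle — but computed entirely from the
    brute-force triangulation above.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    triangles, edges = reference_delaunay(pts)
    kept = _prune_edges(pts, edges, prune_factor)
    edge_set = {(int(i), int(j)) for i, j in kept}

    counts = np.zeros(n, dtype=int)
    for i, j in kept:
        counts[i] += 1
        counts[j] += 1

    # a triangle survives pruning iff all three of its edges survive
    tri_count: dict[tuple[int, int], int] = {e: 0 for e in edge_set}
    for i, j, k in triangles:
        tri_edges = [(i, j), (i, k), (j, k)]
        if all(e in edge_set for e in tri_edges):
            for e in tri_edges:
                tri_count[e] += 1

    interior = np.zeros(n, dtype=bool)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in kept:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    for i in range(n):
        if counts[i] == 0:
            continue  # isolated after pruning: peripheral
        on_boundary = any(
            tri_count[(min(i, j), max(i, j))] <= 1 for j in adj[i]
        )
        interior[i] = not on_boundary
    return kept, counts, interior


# ---------------------------------------------------------------------------
# Planted lattices
# ---------------------------------------------------------------------------


@dataclass
class PlantedLattice:
    """Point set with oracle-computed ground truth for the defect pipeline."""

    points: np.ndarray  # (n, 2) nm
    ground_truth_neighbor_counts: np.ndarray  # (n,) int
    ground_truth_interior: np.ndarray  # (n,) bool
    spacing: float
    planted_defects: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.points)

    def defect_proportion(self) -> float:
        """Ground-truth defect proportion over interior points."""
        interior = self.ground_truth_interior
        if interior.sum() == 0:
            return float("nan")
        bad = self.ground_truth_neighbor_counts[interior] != 6
        return float(bad.mean())


def gen_hex_lattice(
    spacing: float,
    extent: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    prune_factor: float = 2.0,
) -> PlantedLattice:
    """Triangular (hexagonal-packing) lattice patch spanning ``extent``.

    The patch is a parallelogram aligned with the lattice vectors
    (a1 = (spacing, 0), a2 = (spacing/2, spacing*sqrt(3)/2)) so that its
    edges are commensurate with the lattice and every geometrically interior
    site keeps its full six-neighbor shell — a square clip would leave
    ragged-edge sites that are interior to the hull but five-coordinated.
    Positions are jittered by seeded isotropic Gaussian noise of standard
    deviation ``jitter_sd`` (nm). Ground truth comes from the brute-force
    oracle; with ``jitter_sd=0`` every interior point has exactly 6 neighbors.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if extent < 4 * spacing:
        raise ValueError("extent must be at least 4 * spacing")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dy = spacing * math.sqrt(3.0) / 2.0
    rows = int(math.floor(extent / dy)) + 1
    cols = int(math.floor(extent / spacing)) + 1
    pts = []
    for i in range(rows):
        for j in range(cols):
            pts.append((i * spacing / 2.0 + j * spacing, i * dy))
    points = np.array(pts, dtype=float)
    if jitter_sd > 0:
        points = points + rng.normal(0.0, jitter_sd, size=points.shape)
    _, counts, interior = reference_analysis(points, prune_factor)
    return PlantedLattice(points, counts, interior, spacing)


def plant_defects(
    lattice: PlantedLattice,
    vacancies: int = 0,
    interstitials: int = 0,
    void_radius: float = 0.0,
    seed: int = 0,
    prune_factor: float = 2.0,
) -> PlantedLattice:
    """Insert vacancies, interstitials and/or a circular void into a lattice.

    Vacancies remove random interior points; interstitials are inserted at the
    midpoint between an interior point and the center of one of its lattice
    cells (spacing/sqrt(3) away, the hollow site of a triangular lattice); a
    void removes all points within ``void_radius`` of a randomly chosen
    interior point. Ground truth is recomputed with the brute-force oracle.
    """
    rng = np.random.default_rng(seed)
    points = lattice.points.copy()
    interior_idx = np.flatnonzero(lattice.ground_truth_interior)
    planted = list(lattice.planted_defects)

    if vacancies >= len(interior_idx):
        raise ValueError("requested removals exceed interior point count")

    keep = np.ones(len(points), dtype=bool)
    if vacancies > 0:
        removed = rng.choice(interior_idx, size=vacancies, replace=False)
        keep[removed] = False
        planted.extend(("vacancy", tuple(points[i])) for i in removed)

    if void_radius > 0:
        center_i = int(rng.choice(interior_idx))
        center = points[center_i]
        within = np.linalg.norm(points - center, axis=1) <= void_radius
        if within.all():
            raise ValueError("void would cover the entire lattice")
        keep &= ~within
        planted.append(("void", tuple(center)))

    new_points = [points[keep]]
    if interstitials > 0:
        hosts = rng.choice(interior_idx, size=interstitials, replace=False)
        # hollow site: one lattice-cell center adjacent to the host point
        angle = rng.uniform(0.0, 2.0 * np.pi, size=interstitials)
        offs = (lattice.spacing / math.sqrt(3.0)) * np.stack(
            [np.cos(angle), np.sin(angle)], axis=1
        )
        extra = points[hosts] + offs
        new_points.append(extra)
        planted.extend(("interstitial", tuple(p)) for p in extra)

    all_points = np.vstack(new_points)
    if len(all_points) < 3:
        raise ValueError("too few points left after planting defects")
    _, counts, interior = reference_analysis(all_points, prune_factor)
    return PlantedLattice(all_points, counts, interior, lattice.spacing, planted)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticAbundanceSpec:
    """Protein x time-point abundance table emulating the LCM-MS time series.

    ``trend_fractions`` splits proteins between profile families (see
    ``TREND_PROFILES``); noise is multiplicative log-normal with coefficient
    of variation ``noise_cv``; each cell is independently missing with
    probability ``missing_rate``.
    """

    n_proteins: int = 500
    trend_fractions: tuple = (("peak", 0.4), ("rise", 0.3), ("flat", 0.3))
    noise_cv: float = 0.2
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        for name, _ in self.trend_fractions:
            if name not in TREND_PROFILES:
                raise ValueError(f"unknown trend family {name!r}")


@dataclass
class SyntheticAbundance:
    table: pd.DataFrame  # proteins x TIMEPOINTS, NaN = missing
    trends: pd.Series  # ground-truth trend family per protein


def gen_abundance_table(spec: SyntheticAbundanceSpec) -> SyntheticAbundance:
    """Seeded abundance table with known per-protein trend families.

    With ``noise_cv=0`` the rows follow the noiseless profiles exactly, so
    every "peak" protein has its maximum at E13.5.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    names = [name for name, _ in spec.trend_fractions]
    fracs = np.array([f for _, f in spec.trend_fractions], dtype=float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * n).astype(int)
    counts[0] += n - counts.sum()
    trend_labels = np.repeat(names, counts)

    baseline = np.exp(rng.normal(math.log(1e6), 1.0, size=n))
    profiles = np.stack([TREND_PROFILES[t] for t in trend_labels])
    values = baseline[:, None] * profiles

    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
        noise = np.exp(rng.normal(0.0, sigma, size=values.shape) - sigma**2 / 2.0)
        values = values * noise

    if spec.missing_rate > 0:
        missing = rng.uniform(size=values.shape) < spec.missing_rate
        values = np.where(missing, np.nan, values)

    ids = [f"P{i:05d}" for i in range(n)]
    table = pd.DataFrame(values, index=pd.Index(ids, name="protein"), columns=list(TIMEPOINTS))
    trends = pd.Series(trend_labels, index=table.index, name="trend")
    return SyntheticAbundance(table, trends)
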