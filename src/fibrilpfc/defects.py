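"""Lattice-defect quantification of fibril point patterns.

Pipeline: Delaunay triangulation of the fibril centers; pruning of edges
longer than ``prune_factor`` x the median edge length (suppresses spurious
adjacency across voids and domain concavities); vertex degrees of the pruned
graph as neighbor counts; periphery exclusion; and the defect proportion

    d = (# interior fibrils with neighbor count != 6) / (# interior fibrils).

A point is peripheral when it is incident to a pruned-graph edge that bounds
at most one surviving triangle (the boundary of the pruned triangulation);
on convex, void-free bundles this coincides with the convex hull. Interior
fibrils with five neighbors are disclinations (colored red in renderings),
seven neighbors blue; bound 5-7 pairs are dislocations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi

from .points import FibrilSet

LABELS = ("five", "six", "seven", "other", "peripheral")


@dataclass
class PrunedTriangulation:
    """Delaunay triangulation after long-edge pruning."""

    points: np.ndarray  # (n, 2)
    edges: np.ndarray  # (m, 2) int, i < j, sorted
    edge_lengths: np.ndarray  # (m,)
    simplices: np.ndarray  # surviving (all-edges-kept) simplices, (t, 3)
    median_raw_edge: float  # median edge length before pruning

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class DefectReport:
    """Per-point neighbor statistics and the scalar defect proportion."""

    points: np.ndarray
    edges: np.ndarray
    interior: np.ndarray  # bool per point
    neighbor_counts: np.ndarray  # int per point
    labels: np.ndarray  # str per point, from LABELS
    defect_proportion: float  # NaN when no interior point exists
    edge_lengths: np.ndarray  # lengths of interior-interior edges

    @property
    def n_interior(self) -> int:
        return int(self.interior.sum())

    def median_edge_length(self) -> float:
        if len(self.edge_lengths) == 0:
            return float("nan")
        return float(np.median(self.edge_lengths))


def _as_points(fibrils) -> np.ndarray:
    if isinstance(fibrils, FibrilSet):
        return fibrils.points
    return np.atleast_2d(np.asarray(fibrils, dtype=float))


def triangulate(fibrils, prune_factor: float = 2.0) -> PrunedTriangulation:
    """Delaunay triangulation with long-edge pruning.

    Raises ``ValueError`` for fewer than 3 points or a degenerate
    (all-collinear) configuration.
    """
    pts = _as_points(fibrils)
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points, got {len(pts)}")
    if prune_factor <= 0:
        raise ValueError("prune_factor must be positive")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    if len(tri.simplices) == 0:
        raise ValueError("degenerate point configuration (no triangle)")

    edge_set = set()
    for a, b, c in tri.simplices:
        for i, j in ((a, b), (a, c), (b, c)):
            edge_set.add((min(int(i), int(j)), max(int(i), int(j))))
    edges = np.array(sorted(edge_set), dtype=int)
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    med = float(np.median(lengths))
    keep = lengths <= prune_factor * med
    kept_edges = edges[keep]
    kept_set = {tuple(e) for e in kept_edges}

    surv = []
    for a, b, c in np.sort(tri.simplices, axis=1):
        a, b, c = int(a), int(b), int(c)
        if ((a, b) in kept_set) and ((a, c) in kept_set) and ((b, c) in kept_set):
            surv.append((a, b, c))
    simplices = np.array(surv, dtype=int).reshape(-1, 3)
    return PrunedTriangulation(pts, kept_edges, lengths[keep], simplices, med)


def neighbor_counts(tri: PrunedTriangulation) -> np.ndarray:
    """Vertex degree of every point in the pruned graph."""
    counts = np.zeros(tri.n, dtype=int)
    np.add.at(counts, tri.edges[:, 0], 1)
    np.add.at(counts, tri.edges[:, 1], 1)
    return counts


def classify_interior(tri: PrunedTriangulation) -> np.ndarray:
    """Interior flags: a point is peripheral iff it touches the boundary of
    the pruned triangulation (an edge bounding <= 1 surviving triangle), or
    is isolated after pruning."""
    tri_per_edge: dict[tuple[int, int], int] = {tuple(e): 0 for e in map(tuple, tri.edges)}
    for a, b, c in tri.simplices:
        for e in ((a, b), (a, c), (b, c)):
            tri_per_edge[e] += 1

    interior = np.zeros(tri.n, dtype=bool)
    degree = neighbor_counts(tri)
    boundary_pts = set()
    for (i, j), cnt in tri_per_edge.items():
        if cnt <= 1:
            boundary_pts.add(i)
            boundary_pts.add(j)
    for i in range(tri.n):
        interior[i] = degree[i] > 0 and i not in boundary_pts
    return interior


def _labels(counts: np.ndarray, interior: np.ndarray) -> np.ndarray:
    labels = np.empty(len(counts), dtype=object)
    for i, (cnt, inn) in enumerate(zip(counts, interior)):
        if not inn:
            labels[i] = "peripheral"
        elif cnt == 5:
            labels[i] = "five"
        elif cnt == 6:
            labels[i] = "six"
        elif cnt == 7:
            labels[i] = "seven"
        else:
            labels[i] = "other"
    return labels


def defect_report(fibrils, prune_factor: float = 2.0) -> DefectReport:
    """Full defect analysis of a fibril point set.

    ``defect_proportion`` counts every interior fibril whose neighbor count
    differs from 6 (five, seven and all other counts alike); it is NaN when
    the periphery exclusion leaves no interior fibril.
    """
    tri = triangulate(fibrils, prune_factor)
    counts = neighbor_counts(tri)
    interior = classify_interior(tri)
    labels = _labels(counts, interior)

    n_int = int(interior.sum())
    if n_int == 0:
        d = float("nan")
    else:
        d = float((counts[interior] != 6).mean())

    both_interior = interior[tri.edges[:, 0]] & interior[tri.edges[:, 1]]
    edge_lengths = tri.edge_lengths[both_interior]
    return DefectReport(
        tri.points, tri.edges, interior, counts, labels, d, edge_lengths
    )


def distributions(
    report: DefectReport,
    edge_bins: int | np.ndarray = 30,
    max_count: int = 12,
) -> dict:
    """Unit-mass histograms of interior edge lengths and neighbor counts.

    Returns ``edge_hist``/``edge_bin_edges`` (masses summing to 1),
    ``median_edge``, and ``count_hist`` over 0..max_count.
    """
    out: dict = {}
    el = report.edge_lengths
    if len(el) > 0:
        if np.ptp(el) <= 1e-9 * np.median(el):  # degenerate: all edges equal
            m = float(np.median(el))
            edge_bins = np.array([m * (1 - 1e-6), m * (1 + 1e-6)])
        hist, edges = np.histogram(el, bins=edge_bins)
        out["edge_hist"] = hist / hist.sum()
        out["edge_bin_edges"] = edges
        out["median_edge"] = float(np.median(el))
    else:
        out["edge_hist"] = np.array([])
        out["edge_bin_edges"] = np.array([])
        out["median_edge"] = float("nan")
    counts = report.neighbor_counts[report.interior]
    ch = np.bincount(counts, minlength=max_count + 1)[: max_count + 1]
    total = ch.sum()
    out["count_hist"] = ch / total if total > 0 else ch.astype(float)
    out["count_values"] = np.arange(max_count + 1)
    return out


def modal_neighbor_count(report: DefectReport) -> int:
    """Most frequent neighbor count among interior fibrils."""
    counts = report.neighbor_counts[report.interior]
    if len(counts) == 0:
        raise ValueError("no interior fibrils")
    return int(np.bincount(counts).argmax())


def report_to_frame(report: DefectReport):
    """Per-point table (x, y, neighbor_count, interior, label)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x_nm": report.points[:, 0],
            "y_nm": report.points[:, 1],
            "neighbor_count": report.neighbor_counts,
            "interior": report.interior,
            "label": report.labels,
        }
    )


def voronoi_plot(report: DefectReport, ax=None, show_points: bool = True):
    """Voronoi rendering with the standard color code: five -> red,
    seven -> blue, six -> clear, other counts -> gray; peripheral cells are
    left unfilled."""
    import matplotlib.pyplot as plt

    colors = {"five": "#d62728", "seven": "#1f77b4", "six": "none", "other": "#999999"}
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    if len(report.points) >= 4:
        vor = Voronoi(report.points)
        for i, region_idx in enumerate(vor.point_region):
            label = report.labels[i]
            if label == "peripheral":
                continue
            region = vor.regions[region_idx]
            if -1 in region or len(region) == 0:
                continue
            poly = vor.vertices[region]
            ax.fill(
                poly[:, 0], poly[:, 1],
                facecolor=colors[label], edgecolor="black", linewidth=0.5,
            )
    if show_points:
        ax.plot(report.points[:, 0], report.points[:, 1], "k.", markersize=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    return ax
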