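"""Fibril center points: detection from simulated fields and CSV round-trip.

Fibril cross-sections appear as compact blobs of the concentration proxy
c >= 1/2. The primary detector labels 4-connected components of the in-mask
fibrillar region and reports the c-weighted centroid of every component whose
area passes ``min_area``; a local-maximum detector is kept as an independent
cross-check. Coordinates are physical (same unit as grid.dx, nominally nm),
with pixel centers at (index + 1/2) * dx.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import DomainMask, PhaseField
from .observables import concentration


@dataclass
class FibrilSet:
    """Planar fibril centers in physical units.

    ``source`` is "simulation" for detected points, "annotation" for points
    read from a file.
    """

    points: np.ndarray  # (n, 2) float, columns (x, y)
    source: str = "simulation"
    domain: DomainMask | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must have shape (n, 2)")

    @property
    def n(self) -> int:
        return len(self.points)


def default_min_area(spacing: float) -> float:
    """Detector area threshold: 25% of a disk of radius spacing/4.

    Excludes boundary slivers while keeping every genuine fibril
    cross-section (which has area comparable to the full disk).
    """
    return 0.25 * math.pi * (spacing / 4.0) ** 2


def _periodic_label(blob: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected component labels on a torus (wrap-around merged)."""
    labels, n = ndimage.label(blob)
    if n == 0:
        return labels, 0
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for col in range(blob.shape[1]):
        if blob[0, col] and blob[-1, col]:
            union(int(labels[0, col]), int(labels[-1, col]))
    for row in range(blob.shape[0]):
        if blob[row, 0] and blob[row, -1]:
            union(int(labels[row, 0]), int(labels[row, -1]))

    roots = np.array([find(i) for i in range(n + 1)])
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=int)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]], len(uniq)


def _circular_centroid(indices: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Weighted mean pixel position along a periodic axis of length n."""
    theta = 2.0 * np.pi * (indices + 0.5) / n
    s = np.sum(weights * np.sin(theta))
    c = np.sum(weights * np.cos(theta))
    pos = np.arctan2(s, c) / (2.0 * np.pi) * n
    return float(pos % n)


def detect_fibrils(
    field: PhaseField,
    mask: DomainMask | None = None,
    min_area: float | None = None,
    spacing: float | None = None,
) -> FibrilSet:
    """Detect fibril centers as c-weighted centroids of fibrillar components.

    ``min_area`` is in squared coordinate units; if omitted it is derived
    from ``spacing`` (expected inter-fibril distance) via
    :func:`default_min_area`, or set to 0 when neither is given. On full
    (periodic) domains, components wrapping the box edges are merged and
    their centroids computed circularly.
    """
    if min_area is None:
        min_area = default_min_area(spacing) if spacing is not None else 0.0
    grid = field.grid
    c = concentration(field)
    periodic = mask is None or mask.is_full
    inside = np.ones(grid.shape, bool) if mask is None else mask.inside
    blob = inside & (c >= 0.5)
    if periodic:
        labels, n_lab = _periodic_label(blob)
    else:
        labels, n_lab = ndimage.label(blob)  # 4-connectivity
    if n_lab == 0:
        return FibrilSet(np.empty((0, 2)), "simulation", mask)

    idx = np.arange(1, n_lab + 1)
    areas = ndimage.sum_labels(np.ones_like(c), labels, idx) * grid.dx**2
    keep = idx[areas >= min_area]
    if len(keep) == 0:
        return FibrilSet(np.empty((0, 2)), "simulation", mask)
    if periodic:
        pts = []
        for lab in keep:
            rows, cols = np.nonzero(labels == lab)
            w = c[rows, cols]
            x = _circular_centroid(cols, w, grid.nx) * grid.dx
            y = _circular_centroid(rows, w, grid.ny) * grid.dx
            pts.append([x, y])
        pts = np.array(pts)
    else:
        centers = ndimage.center_of_mass(c, labels, keep)  # (row, col)
        pts = np.array(
            [[(col + 0.5) * grid.dx, (row + 0.5) * grid.dx] for row, col in centers]
        )
    return FibrilSet(pts, "simulation", mask)


def detect_fibrils_maxima(
    field: PhaseField,
    mask: DomainMask | None = None,
    spacing: float | None = None,
) -> FibrilSet:
    """Independent cross-check detector: local maxima of smoothed c.

    Smooths c with a Gaussian of sigma = spacing/6 and keeps in-mask local
    maxima of the fibrillar region separated by at least spacing/2.
    """
    grid = field.grid
    c = concentration(field)
    inside = np.ones(grid.shape, bool) if mask is None else mask.inside
    if spacing is None:
        spacing = 8.0 * grid.dx
    sigma_px = spacing / 6.0 / grid.dx
    smooth = ndimage.gaussian_filter(c, sigma_px, mode="wrap")
    size = max(3, int(round(spacing / 2.0 / grid.dx)) | 1)
    local_max = smooth == ndimage.maximum_filter(smooth, size=size, mode="wrap")
    cand = local_max & inside & (smooth >= 0.5)
    rows, cols = np.nonzero(cand)
    pts = np.stack([(cols + 0.5) * grid.dx, (rows + 0.5) * grid.dx], axis=1)
    return FibrilSet(pts, "simulation", mask)


def write_points(fibrils: FibrilSet, path) -> None:
    """Write points as CSV with header ``x_nm,y_nm``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_nm", "y_nm"])
        for x, y in fibrils.points:
            w.writerow([repr(float(x)), repr(float(y))])


def read_points(path) -> FibrilSet:
    """Read fibril centers from a CSV with columns ``x_nm,y_nm``.

    Extra columns are ignored. Malformed rows and exact duplicate points are
    reported with their line numbers.
    """
    pts: list[tuple[float, float]] = []
    bad: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        cols = [h.strip().lower() for h in header]
        if "x_nm" not in cols or "y_nm" not in cols:
            raise ValueError(f"{path}: header must contain x_nm and y_nm, got {header}")
        ix, iy = cols.index("x_nm"), cols.index("y_nm")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) <= max(ix, iy):
                bad.append(f"line {lineno}: too few columns")
                continue
            try:
                pts.append((float(row[ix]), float(row[iy])))
            except ValueError:
                bad.append(f"line {lineno}: non-numeric value {row[ix]!r},{row[iy]!r}")
    if bad:
        raise ValueError(f"{path}: malformed rows: " + "; ".join(bad))
    arr = np.array(pts, dtype=float).reshape(-1, 2)
    if len(arr) > 1:
        _, inv, counts = np.unique(arr, axis=0, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            dup_lines = [
                str(i + 2) for i in range(len(arr)) if counts[inv[i]] > 1
            ]
            raise ValueError(
                f"{path}: duplicate points at lines {', '.join(dup_lines)}"
            )
    return FibrilSet(arr, "annotation")
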