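"""Regular grids, domain masks and the phase field container.

The simulation lattice is a regular isotropic grid. Physical coordinates
(nanometres) are attached through ``GridSpec.dx``; the PFC solver itself works
in dimensionless model units (see :mod:`fibrilpfc.pfc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GridSpec:
    """A regular ``nx`` x ``ny`` pixel grid with isotropic spacing ``dx`` (nm/px)."""

    nx: int
    ny: int
    dx: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError(f"grid must be at least 16x16, got {self.nx}x{self.ny}")
        if not self.dx > 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape, row-major ``(ny, nx)``."""
        return (self.ny, self.nx)

    @property
    def width_nm(self) -> float:
        return self.nx * self.dx

    @property
    def height_nm(self) -> float:
        return self.ny * self.dx

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centers, each shaped (ny, nx)."""
        x = (np.arange(self.nx) + 0.5) * self.dx
        y = (np.arange(self.ny) + 0.5) * self.dx
        return np.meshgrid(x, y)


class DomainMask:
    """Indicator of the inter-cellular space on a grid.

    ``inside`` is the binary indicator (True = inside the domain); ``smoothed``
    is a tanh-profiled version used by the boundary treatment of the masked
    PFC solver. The smoothing width is measured in pixels.
    """

    def __init__(self, inside: np.ndarray, grid: GridSpec, smoothing_px: float = 2.0):
        inside = np.asarray(inside, dtype=bool)
        if inside.shape != grid.shape:
            raise ValueError(f"mask shape {inside.shape} != grid shape {grid.shape}")
        self.inside = inside
        self.grid = grid
        self.smoothing_px = float(smoothing_px)
        self._smoothed: np.ndarray | None = None
        self._dist: np.ndarray | None = None

    @classmethod
    def full(cls, grid: GridSpec) -> "DomainMask":
        """Mask covering the whole (periodic) rectangle."""
        return cls(np.ones(grid.shape, dtype=bool), grid)

    @property
    def is_full(self) -> bool:
        return bool(self.inside.all())

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    @property
    def area_nm2(self) -> float:
        return self.n_inside * self.grid.dx**2

    @property
    def signed_distance_px(self) -> np.ndarray:
        """Signed Euclidean distance to the mask boundary in pixels (>0 inside)."""
        if self._dist is None:
            if self.is_full:
                self._dist = np.full(self.grid.shape, np.inf)
            else:
                d_in = ndimage.distance_transform_edt(self.inside)
                d_out = ndimage.distance_transform_edt(~self.inside)
                self._dist = d_in - d_out
        return self._dist

    @property
    def smoothed(self) -> np.ndarray:
        """Smoothed indicator psi in [0, 1] (tanh profile across the boundary)."""
        if self._smoothed is None:
            if self.is_full:
                self._smoothed = np.ones(self.grid.shape)
            else:
                self._smoothed = 0.5 * (
                    1.0 + np.tanh(self.signed_distance_px / self.smoothing_px)
                )
        return self._smoothed

    def touches_border(self) -> bool:
        m = self.inside
        return bool(m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any())

    def n_components(self, connectivity: int = 1) -> int:
        structure = ndimage.generate_binary_structure(2, connectivity)
        _, n = ndimage.label(self.inside, structure=structure)
        return int(n)


@dataclass
class PhaseField:
    """Scalar PFC order parameter phi(x, t) on a grid.

    phi ≈ -1 marks dense fibrillar collagen, phi ≈ +1 protomer-rich medium.
    ``time`` is dimensionless simulation time.
    """

    values: np.ndarray
    grid: GridSpec
    time: float = 0.0
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def copy(self) -> "PhaseField":
        return PhaseField(self.values.copy(), self.grid, self.time, dict(self.attrs))
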