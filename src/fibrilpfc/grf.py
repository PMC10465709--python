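"""Gaussian-random-field initial conditions for the phase field.

The initial state is a roughly uniform field phi0 plus a small spatially
correlated fluctuation: seeded white noise filtered in Fourier space with a
Gaussian kernel, then rescaled so the in-mask sample variance equals m2
exactly and shifted so the in-mask mean equals phi0 exactly.

The correlation length ``lam`` is in grid units (pixels). The filter is
chosen so the resulting autocorrelation is exp(-r^2 / lam^2), i.e. lam is the
e-folding distance of the correlation function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft

from .grid import DomainMask, GridSpec, PhaseField


@dataclass(frozen=True)
class GRFParams:
    """Mean phi0, fluctuation variance m2, correlation length lam (pixels)."""

    phi0: float
    m2: float = 0.01
    lam: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.phi0) < 1:
            raise ValueError("|phi0| must be < 1")
        if self.m2 < 0:
            raise ValueError("m2 must be non-negative")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")


def sample_grf(
    grid: GridSpec, mask: DomainMask | None, params: GRFParams
) -> PhaseField:
    """Sample the seeded Gaussian-random-field initial condition.

    Outside the mask the field is held at phi0 (the pinned value of the
    boundary treatment). With ``m2=0`` the field is identically phi0.
    """
    if mask is None:
        mask = DomainMask.full(grid)
    inside = mask.inside
    values = np.full(grid.shape, params.phi0, dtype=float)
    if params.m2 == 0.0:
        return PhaseField(values, grid, 0.0, {"grf": params})
    if inside.sum() < 2:
        raise ValueError("mask has fewer than 2 pixels; variance is undefined")

    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(grid.shape)
    if params.lam > 0:
        kx = 2.0 * np.pi * fft.fftfreq(grid.nx)
        ky = 2.0 * np.pi * fft.fftfreq(grid.ny)
        k2 = ky[:, None] ** 2 + kx[None, :] ** 2
        # |filter|^2 = exp(-k^2 lam^2 / 4)  =>  C(r) = exp(-r^2 / lam^2)
        noise = fft.ifft2(fft.fft2(noise) * np.exp(-k2 * params.lam**2 / 8.0)).real

    # taper the fluctuation with the smoothed mask so no sharp step is
    # written at the domain edge (the solver's high-order operator amplifies
    # pixel-scale discontinuities), then standardize over the mask interior
    if not mask.is_full:
        noise = noise * mask.smoothed
    z = noise[inside]
    sd = z.std()
    if sd == 0.0:
        raise ValueError("degenerate noise sample (zero variance)")
    field_z = (noise - z.mean()) * (np.sqrt(params.m2) / sd)
    values[inside] += field_z[inside]
    return PhaseField(values, grid, 0.0, {"grf": params})
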