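"""Scalar diagnostics of a phase field: concentration proxy, protomer
availability, crystallized fraction, and their time series.

The concentration proxy is c = (1 - phi)/2, so c in [0, 1] with c ~ 1 in
dense fibrillar regions (phi ~ -1) and c ~ 0 in dilute medium (phi ~ 1).
Regions with c < 1/2 are protomer-occupied; c >= 1/2 marks fibrillar
(crystallized) material. The integral of c over the protomer region estimates
the relative availability of free collagen protomer, which falls as protomer
is incorporated into fibrils.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DomainMask, PhaseField


@dataclass
class ObservableSeries:
    """Per-snapshot scalar series recorded along a trajectory."""

    times: np.ndarray
    free_energy: np.ndarray
    protomer_availability: np.ndarray
    crystallized_fraction: np.ndarray
    defect_proportion: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("free_energy", "protomer_availability", "crystallized_fraction"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} length != times length")
        if self.defect_proportion is not None and len(self.defect_proportion) != n:
            raise ValueError("defect_proportion length != times length")

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time": self.times,
            "free_energy": self.free_energy,
            "availability": self.protomer_availability,
            "crystallized_fraction": self.crystallized_fraction,
        }
        if self.defect_proportion is not None:
            data["defect_proportion"] = self.defect_proportion
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def concentration(field: PhaseField) -> np.ndarray:
    """Concentration proxy c = (1 - phi)/2."""
    return 0.5 * (1.0 - field.values)


def protomer_availability(field: PhaseField, mask: DomainMask | None = None) -> float:
    """Integral of c over the in-mask protomer region {c < 1/2}.

    Area element is the physical pixel area grid.dx^2, so the value carries
    the square of whatever unit grid.dx is in.
    """
    c = concentration(field)
    inside = np.ones(field.grid.shape, bool) if mask is None else mask.inside
    sel = inside & (c < 0.5)
    return float(c[sel].sum() * field.grid.dx**2)


def crystallized_fraction(field: PhaseField, mask: DomainMask | None = None) -> float:
    """Fraction of in-mask pixels with c >= 1/2 (fibrillar class; ties -> fibril)."""
    c = concentration(field)
    inside = np.ones(field.grid.shape, bool) if mask is None else mask.inside
    n = int(inside.sum())
    if n == 0:
        raise ValueError("empty mask")
    return float((c[inside] >= 0.5).sum() / n)


def concentration_integral(field: PhaseField, mask: DomainMask | None = None) -> float:
    """Integral of c over the whole in-mask region (both phases)."""
    c = concentration(field)
    inside = np.ones(field.grid.shape, bool) if mask is None else mask.inside
    return float(c[inside].sum() * field.grid.dx**2)


def decline_time(times: np.ndarray, series: np.ndarray, fraction: float) -> float:
    """First time at which ``series`` has completed ``fraction`` of its total
    decline from series[0] to series[-1].

    Used for the formation timescale (availability, fraction=0.9) and the
    maturation timescale (free energy, fraction=0.99). Linear interpolation
    between snapshots. Raises if the series does not decline at all.
    """
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    total = series[0] - series[-1]
    if total <= 0:
        raise ValueError("series does not decline")
    target = series[0] - fraction * total
    below = np.flatnonzero(series <= target)
    if len(below) == 0:
        return float(times[-1])
    i = int(below[0])
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    s0, s1 = series[i - 1], series[i]
    if s0 == s1:
        return float(t1)
    return float(t0 + (s0 - target) / (s0 - s1) * (t1 - t0))


def cumulative_decline_time(
    times: np.ndarray, series: np.ndarray, fraction: float
) -> float:
    """First time the *cumulative* decline of ``series`` reaches ``fraction``
    of its total.

    The cumulative decline at time t is the sum of all decreases up to t
    (increases do not count and are not subtracted). For a monotone series
    this coincides with :func:`decline_time`; for a series with small
    fluctuations it credits late slow relaxation that a net-level crossing
    would miss. Used for the maturation timescale, where the last percent of
    the free-energy decline is carried by sparse defect-annealing events.
    """
    times = np.asarray(times, float)
    series = np.asarray(series, float)
    dec = np.maximum(0.0, -np.diff(series))
    cum = np.concatenate([[0.0], np.cumsum(dec)])
    if cum[-1] <= 0:
        raise ValueError("series does not decline")
    target = fraction * cum[-1]
    i = int(np.argmax(cum >= target))
    if i == 0:
        return float(times[0])
    c0, c1 = cum[i - 1], cum[i]
    t0, t1 = times[i - 1], times[i]
    if c0 == c1:
        return float(t1)
    return float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))
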