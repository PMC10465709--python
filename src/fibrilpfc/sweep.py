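"""Batch orchestration: the (r, phi0) parameter sweep over masked domains.

Each sweep cell (r, phi0, domain, replicate) runs the full pipeline —
seeded GRF initial condition, masked PFC integration, fibril detection,
defect analysis — with a per-cell seed derived deterministically from the
sweep seed, so any scheduling of the independent cells reproduces the same
results. Cell failures are recorded and do not abort the sweep.

The phenomenology probed: high r / low phi0 fills the inter-cellular space
densely with fibrils, while low r / high phi0 leaves fibril-free voids
(localized states), so the equilibrium crystallized fraction rises with r
and falls with phi0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import pfc
from .defects import defect_report
from .grf import GRFParams, sample_grf
from .grid import DomainMask
from .points import detect_fibrils
from .pfc import PFCParams


@dataclass
class SweepSpec:
    """Grid of (r, phi0) values x domains x replicates."""

    r_values: list
    phi0_values: list
    base_params: PFCParams
    domains: list  # list of DomainMask
    n_reps: int = 1
    grf_m2: float = 0.01
    grf_lam: float = 10.0
    seed0: int = 0

    def __post_init__(self) -> None:
        if not self.r_values or not self.phi0_values:
            raise ValueError("sweep grid must be non-empty")
        if not self.domains:
            raise ValueError("at least one domain is required")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def cell_seed(seed0: int, i_r: int, i_phi: int, i_dom: int, rep: int) -> int:
    """Deterministic per-cell seed (< 2^31) derived from the sweep seed."""
    ss = np.random.SeedSequence(seed0, spawn_key=(i_r, i_phi, i_dom, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class SweepResult:
    """Per-cell summary records plus raw samples for pooled distributions."""

    records: pd.DataFrame
    edge_samples: dict  # (i_r, i_phi, i_dom, rep) -> edge-length array
    count_samples: dict  # same keys -> interior neighbor-count array
    spec: SweepSpec = None


def run_cell(
    spec: SweepSpec, i_r: int, i_phi: int, i_dom: int, rep: int
) -> tuple[dict, np.ndarray, np.ndarray]:
    """Run one sweep cell; returns (record, edge_lengths, neighbor_counts)."""
    r = float(spec.r_values[i_r])
    phi0 = float(spec.phi0_values[i_phi])
    mask: DomainMask = spec.domains[i_dom]
    seed = cell_seed(spec.seed0, i_r, i_phi, i_dom, rep)
    params = replace(spec.base_params, r=r, phi0=phi0)
    ic = sample_grf(
        mask.grid, mask, GRFParams(phi0=phi0, m2=spec.grf_m2, lam=spec.grf_lam, seed=seed)
    )
    traj = pfc.run(ic, mask, params, keep_snapshots=False)
    final = traj.final

    h = params.spacing(mask.grid)
    spacing_phys = pfc.one_mode_spacing(params.qstar) * mask.grid.dx / h
    fibrils = detect_fibrils(final, mask, spacing=spacing_phys)
    record = {
        "r": r,
        "phi0": phi0,
        "domain": i_dom,
        "rep": rep,
        "seed": seed,
        "crystallized_fraction": traj.series.crystallized_fraction[-1],
        "availability_final": traj.series.protomer_availability[-1],
        "n_fibrils": fibrils.n,
        "defect_proportion": np.nan,
        "median_edge_nm": np.nan,
        "failed": False,
        "error": "",
    }
    edge_lengths = np.array([])
    counts = np.array([], dtype=int)
    if fibrils.n >= 3:
        try:
            rep_ = defect_report(fibrils)
            record["defect_proportion"] = rep_.defect_proportion
            record["median_edge_nm"] = rep_.median_edge_length()
            edge_lengths = rep_.edge_lengths
            counts = rep_.neighbor_counts[rep_.interior]
        except ValueError:
            pass  # degenerate point set: defect stats stay NaN
    return record, edge_lengths, counts


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run every cell of the sweep; failures are flagged, not raised."""
    records = []
    edge_samples: dict = {}
    count_samples: dict = {}
    for i_r in range(len(spec.r_values)):
        for i_phi in range(len(spec.phi0_values)):
            for i_dom in range(len(spec.domains)):
                for rep in range(spec.n_reps):
                    key = (i_r, i_phi, i_dom, rep)
                    try:
                        rec, el, cnt = run_cell(spec, *key)
                    except (FloatingPointError, ValueError) as exc:
                        rec = {
                            "r": float(spec.r_values[i_r]),
                            "phi0": float(spec.phi0_values[i_phi]),
                            "domain": i_dom,
                            "rep": rep,
                            "seed": cell_seed(spec.seed0, *key),
                            "crystallized_fraction": np.nan,
                            "availability_final": np.nan,
                            "n_fibrils": 0,
                            "defect_proportion": np.nan,
                            "median_edge_nm": np.nan,
                            "failed": True,
                            "error": str(exc),
                        }
                        el, cnt = np.array([]), np.array([], dtype=int)
                    records.append(rec)
                    edge_samples[key] = el
                    count_samples[key] = cnt
    return SweepResult(pd.DataFrame(records), edge_samples, count_samples, spec)


def aggregate(
    result: SweepResult, by: tuple = ("r", "phi0"), edge_bins: int | np.ndarray = 30
) -> dict:
    """Pool edge-length and neighbor-count samples into unit-mass histograms.

    Returns a mapping from group key (values of ``by`` columns) to a dict of
    normalized histograms and the pooled median edge length.
    """
    rec = result.records
    out: dict = {}
    # records and sample dicts were filled in the same order
    keys = list(result.edge_samples.keys())
    rec = rec.assign(_key=keys)
    for key_vals, sub in rec[~rec["failed"]].groupby(list(by)):
        edges = [result.edge_samples[k] for k in sub["_key"]]
        counts = [result.count_samples[k] for k in sub["_key"]]
        pooled_e = np.concatenate([e for e in edges if len(e)]) if any(len(e) for e in edges) else np.array([])
        pooled_c = np.concatenate([c for c in counts if len(c)]) if any(len(c) for c in counts) else np.array([], dtype=int)
        entry: dict = {}
        if len(pooled_e):
            hist, bin_edges = np.histogram(pooled_e, bins=edge_bins)
            entry["edge_hist"] = hist / hist.sum()
            entry["edge_bin_edges"] = bin_edges
            entry["median_edge"] = float(np.median(pooled_e))
        else:
            entry["edge_hist"] = np.array([])
            entry["edge_bin_edges"] = np.array([])
            entry["median_edge"] = float("nan")
        ch = np.bincount(pooled_c, minlength=13)[:13]
        entry["count_hist"] = ch / ch.sum() if ch.sum() else ch.astype(float)
        out[key_vals] = entry
    return out
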