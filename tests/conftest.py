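"""Shared fixtures: equilibrium simulations and planted lattices are expensive,
so they are computed once per session and reused across test modules."""

from __future__ import annotations

import pytest

from fibrilpfc import (
    GridSpec,
    GRFParams,
    PFCParams,
    sample_grf,
    run,
)
from fibrilpfc import pipeline
from fibrilpfc.observables import cumulative_decline_time, decline_time
from fibrilpfc.synthetic import gen_hex_lattice, plant_defects


@pytest.fixture(scope="session")
def periodic_equilibrium():
    """Equilibrated hexagonal pattern on a periodic box at r=0.8, phi0=0.4.

    White-noise initial condition so the bulk nucleates everywhere; grid
    spacing 1.209 model units (the production resolution).
    """
    grid = GridSpec(96, 96, dx=1.0)
    params = PFCParams(
        r=0.8, phi0=0.4, dt=0.2, t_end=300.0, save_stride=125, dx_model=1.209
    )
    ic = sample_grf(grid, None, GRFParams(phi0=0.4, m2=0.01, lam=0.0, seed=11))
    traj = run(ic, None, params, keep_snapshots=False)
    return grid, params, traj


@pytest.fixture(scope="session")
def study_results():
    """Five production masked runs (the acceptance study conditions).

    Returns the per-seed defect reports and formation/maturation times plus
    the fitted length calibration.
    """
    master = 1
    dom_seeds = pipeline.derive_seeds(master, 5, stream=0)
    grf_seeds = pipeline.derive_seeds(master, 5, stream=1)
    out = {"reports": [], "t90": [], "t99": [], "masks": [], "trajs": []}
    for ds, gs in zip(dom_seeds, grf_seeds):
        mask, traj = pipeline.run_study(ds, gs)
        _, report = pipeline.analyze_final(mask, traj)
        s = traj.series
        out["reports"].append(report)
        out["masks"].append(mask)
        out["trajs"].append(traj)
        out["t90"].append(decline_time(s.times, s.protomer_availability, 0.9))
        out["t99"].append(cumulative_decline_time(s.times, s.free_energy, 0.99))
    out["nm_per_px"] = pipeline.fitted_nm_per_px()
    return out


@pytest.fixture(scope="session")
def perfect_lattice():
    """Defect-free triangular lattice, 60 nm spacing, with oracle ground truth."""
    return gen_hex_lattice(spacing=60.0, extent=420.0, jitter_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def jittered_lattice():
    """EM-like lattice jittered at 8% of the spacing."""
    return gen_hex_lattice(spacing=60.0, extent=420.0, jitter_sd=4.8, seed=3)


@pytest.fixture(scope="session")
def near_perfect_lattice():
    """Perfect lattice with a 1%-spacing jitter: breaks the exact
    cocircularity that otherwise makes retriangulation around a planted
    defect tie-break-dependent."""
    return gen_hex_lattice(spacing=60.0, extent=420.0, jitter_sd=0.6, seed=12)


@pytest.fixture(scope="session")
def vacancy_lattice(near_perfect_lattice):
    return plant_defects(near_perfect_lattice, vacancies=1, seed=5)


@pytest.fixture(scope="session")
def interstitial_lattice(near_perfect_lattice):
    return plant_defects(near_perfect_lattice, interstitials=1, seed=6)
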