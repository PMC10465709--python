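"""File formats: HDF5 trajectories/fields, PNG domain masks with YAML
sidecars carrying the pixel size."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml
from PIL import Image

from .grid import DomainMask, GridSpec, PhaseField
from .observables import ObservableSeries
from .pfc import PFCParams, Trajectory


def write_mask(mask: DomainMask, path) -> None:
    """8-bit PNG (0 = outside, 255 = inside) plus a ``.yaml`` sidecar with dx."""
    path = Path(path)
    img = Image.fromarray(np.where(mask.inside, 255, 0).astype(np.uint8))
    img.save(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {"dx_nm": float(mask.grid.dx), "nx": mask.grid.nx, "ny": mask.grid.ny},
            fh,
        )


def read_mask(path, dx_nm: float | None = None) -> DomainMask:
    """Read a binary mask image (nonzero = inside).

    The pixel size comes from the YAML sidecar written by :func:`write_mask`
    unless ``dx_nm`` is given explicitly.
    """
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L"))
    if dx_nm is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = yaml.safe_load(fh)
            dx_nm = float(meta["dx_nm"])
        else:
            raise ValueError(f"no pixel size: pass dx_nm or provide {sidecar}")
    ny, nx = arr.shape
    grid = GridSpec(nx=nx, ny=ny, dx=dx_nm)
    return DomainMask(arr > 0, grid)


def _write_params(group: h5py.Group, params: PFCParams) -> None:
    for key in ("r", "phi0", "qstar", "dt", "t_end", "save_stride"):
        group.attrs[key] = getattr(params, key)
    if params.dx_model is not None:
        group.attrs["dx_model"] = params.dx_model
    if params.phi_b is not None:
        group.attrs["phi_b"] = params.phi_b


def _read_params(group: h5py.Group) -> PFCParams:
    kw = {k: group.attrs[k] for k in ("r", "phi0", "qstar", "dt", "t_end")}
    kw["save_stride"] = int(group.attrs["save_stride"])
    if "dx_model" in group.attrs:
        kw["dx_model"] = float(group.attrs["dx_model"])
    if "phi_b" in group.attrs:
        kw["phi_b"] = float(group.attrs["phi_b"])
    return PFCParams(**kw)


def save_field(field: PhaseField, path, name: str = "phi") -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset(name, data=field.values)
        ds.attrs["time"] = field.time
        ds.attrs["dx"] = field.grid.dx


def load_field(path, name: str = "phi") -> PhaseField:
    with h5py.File(path, "r") as fh:
        ds = fh[name]
        values = ds[...]
        time = float(ds.attrs["time"])
        dx = float(ds.attrs["dx"])
    ny, nx = values.shape
    return PhaseField(values, GridSpec(nx=nx, ny=ny, dx=dx), time)


def save_trajectory(traj: Trajectory, path) -> None:
    """Trajectory -> HDF5: snapshot stack, times, observable series, params."""
    with h5py.File(path, "w") as fh:
        stack = np.stack([s.values for s in traj.snapshots])
        fh.create_dataset("phi", data=stack, compression="gzip", compression_opts=4)
        fh.create_dataset("snapshot_times", data=np.array([s.time for s in traj.snapshots]))
        grp = fh.create_group("series")
        s = traj.series
        grp.create_dataset("times", data=s.times)
        grp.create_dataset("free_energy", data=s.free_energy)
        grp.create_dataset("availability", data=s.protomer_availability)
        grp.create_dataset("crystallized_fraction", data=s.crystallized_fraction)
        if s.defect_proportion is not None:
            grp.create_dataset("defect_proportion", data=s.defect_proportion)
        _write_params(fh, traj.params)
        g = traj.snapshots[0].grid
        fh.attrs["dx"] = g.dx
        if traj.mask is not None:
            fh.create_dataset("mask", data=traj.mask.inside.astype(np.uint8))


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        stack = fh["phi"][...]
        snap_times = fh["snapshot_times"][...]
        dx = float(fh.attrs["dx"])
        ny, nx = stack.shape[1:]
        grid = GridSpec(nx=nx, ny=ny, dx=dx)
        snapshots = [
            PhaseField(stack[i], grid, float(snap_times[i])) for i in range(len(stack))
        ]
        grp = fh["series"]
        series = ObservableSeries(
            times=grp["times"][...],
            free_energy=grp["free_energy"][...],
            protomer_availability=grp["availability"][...],
            crystallized_fraction=grp["crystallized_fraction"][...],
            defect_proportion=grp["defect_proportion"][...]
            if "defect_proportion" in grp
            else None,
        )
        params = _read_params(fh)
        mask = None
        if "mask" in fh:
            mask = DomainMask(fh["mask"][...].astype(bool), grid)
    return Trajectory(snapshots, series.times, series, params, mask)
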