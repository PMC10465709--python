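"""Structured run configuration: YAML loading, whole-config validation and
provenance records.

Validation constructs every parameter object up front and collects *all*
violations instead of stopping at the first, so a bad config fails before
any computation starts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .grf import GRFParams
from .grid import GridSpec
from .pfc import PFCParams
from .synthetic import SyntheticDomainSpec


@dataclass
class RunConfig:
    """Validated bundle of per-stage parameters."""

    grid: GridSpec
    pfc: PFCParams
    grf: GRFParams
    domain: SyntheticDomainSpec | None = None
    mask_path: str | None = None
    prune_factor: float = 2.0
    seed: int = 0
    outdir: str = "out"


DEFAULTS = {
    "grid": {"nx": 112, "ny": 112, "dx": 10.0},
    "pfc": {"r": 0.8, "phi0": 0.4, "qstar": 1.0, "dt": 0.2, "t_end": 1000.0,
            "save_stride": 25, "dx_model": 1.209},
    "grf": {"m2": 0.01, "lam": 10.0},
    "domain": {"mean_radius": 420.0, "boundary_roughness": 0.30, "n_modes": 8},
    "analysis": {"prune_factor": 2.0},
    "seed": 0,
    "outdir": "out",
}


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return data


def _merged(user: dict) -> dict:
    cfg = {}
    for key, val in DEFAULTS.items():
        if isinstance(val, dict):
            cfg[key] = {**val, **(user.get(key) or {})}
        else:
            cfg[key] = user.get(key, val)
    for key in user:
        if key not in DEFAULTS and key not in ("mask",):
            cfg[key] = user[key]
    if "mask" in user:
        cfg["mask"] = user["mask"]
    return cfg


def build_config(user: dict | None = None, **overrides) -> RunConfig:
    """Merge defaults <- config file <- CLI overrides; validate everything.

    Raises ``ValueError`` listing every violation found.
    """
    cfg = _merged(user or {})
    for dotted, value in overrides.items():
        if value is None:
            continue
        section, _, key = dotted.partition(".")
        if key:
            cfg.setdefault(section, {})[key] = value
        else:
            cfg[section] = value

    errors: list[str] = []
    built: dict = {}

    def attempt(name, ctor, kw):
        try:
            built[name] = ctor(**kw)
        except (ValueError, TypeError) as exc:
            errors.append(f"[{name}] {exc}")

    attempt("grid", GridSpec, cfg["grid"])
    attempt("pfc", PFCParams, cfg["pfc"])
    grf_kw = dict(cfg["grf"])
    grf_kw.setdefault("phi0", cfg["pfc"].get("phi0", 0.4))
    grf_kw.setdefault("seed", cfg["seed"])
    attempt("grf", GRFParams, grf_kw)
    mask_path = cfg.get("mask")
    if mask_path is None:
        dom_kw = dict(cfg["domain"])
        dom_kw.setdefault("seed", cfg["seed"])
        attempt("domain", SyntheticDomainSpec, dom_kw)
    prune = cfg["analysis"].get("prune_factor", 2.0)
    if not prune > 0:
        errors.append("[analysis] prune_factor must be positive")
    if not isinstance(cfg["seed"], int):
        errors.append("[seed] must be an integer")

    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(
        grid=built["grid"],
        pfc=built["pfc"],
        grf=built["grf"],
        domain=built.get("domain"),
        mask_path=mask_path,
        prune_factor=prune,
        seed=cfg["seed"],
        outdir=str(cfg["outdir"]),
    )


def write_provenance(outdir, config: RunConfig, seed: int, extra: dict | None = None) -> Path:
    """Write a provenance JSON (full config + seed + version) to outdir."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": __version__,
        "seed": seed,
        "grid": asdict(config.grid),
        "pfc": asdict(config.pfc),
        "grf": asdict(config.grf),
        "domain": asdict(config.domain) if config.domain else None,
        "mask_path": config.mask_path,
        "prune_factor": config.prune_factor,
    }
    if extra:
        payload.update(extra)
    path = outdir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
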