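"""Run configuration: schema validation and derivation of all simulation
parameters from a structured (YAML) config file.

``resolve_config`` turns the declarative sections (preset, cg, model, run,
io) into a frozen *manifest* holding every derived quantity — bond length,
Kuhn length, bending rigidity, box size, the realized lattice volume
fraction and the default contact thresholds — so that a run is fully
reproducible from the manifest alone.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import cg_theory
from .cg_theory import PRESETS, ChromatinPreset, kappa_from_kuhn_ratio, solve_cg_geometry
from .lattice import choose_box
from .observables import default_contact_threshold
from .epigenome import default_kinetics_threshold

__all__ = ["resolve_config", "manifest_json", "load_yaml"]

_SCHEMA = {
    "preset": {"name", "rho", "nu0", "b0", "lk0", "c", "ne0"},
    "cg": {"nu", "phi", "nk"},
    "model": {"e_i", "n_states", "kappa", "include_bonded_pairs"},
    "run": {
        "n_monomers",
        "region_bp",
        "n_mcs",
        "snapshot_every",
        "n_replicas",
        "seed",
        "energy_check_every",
        "init",
    },
    "io": {"outdir", "prefix"},
}


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return data


def _check_schema(cfg: dict) -> None:
    unknown_sections = set(cfg) - set(_SCHEMA)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    for section, keys in cfg.items():
        if keys is None:
            continue
        bad = set(keys) - _SCHEMA[section]
        if bad:
            raise ValueError(f"unknown keys in [{section}]: {sorted(bad)}")


def _build_preset(sec: dict) -> ChromatinPreset:
    sec = dict(sec or {})
    name = sec.pop("name", None)
    if name is not None:
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        base = PRESETS[name]
        fields = {
            "rho": base.rho,
            "nu0": base.nu0,
            "b0": base.b0,
            "lk0": base.lk0,
            "c": base.c,
            "ne0": base.ne0,
        }
        fields.update(sec)
        return ChromatinPreset(**fields)
    return ChromatinPreset(**sec)


def resolve_config(source) -> dict:
    """Resolve a config file (path) or mapping into a full run manifest.

    Raises on schema violations, infeasible volume fractions (> 2) and
    unreachable rigidity; echoes every derived quantity.
    """
    cfg = load_yaml(source) if isinstance(source, (str, Path)) else dict(source)
    _check_schema(cfg)
    preset = _build_preset(cfg.get("preset", {"name": "drosophila"}))
    cg = dict(cfg.get("cg") or {})
    nu = float(cg.get("nu", preset.nu0))
    n = nu / preset.nu0
    if abs(n - round(n)) > 1e-9:
        raise ValueError("cg.nu must be an integer multiple of preset nu0")
    n = int(round(n))
    run = dict(cfg.get("run") or {})
    if ("n_monomers" in run) == ("region_bp" in run):
        raise ValueError("give exactly one of run.n_monomers or run.region_bp")
    if "n_monomers" in run:
        n_monomers = int(run["n_monomers"])
    else:
        region = float(run["region_bp"])
        n_monomers = int(round(region / nu))
        if n_monomers * nu != region:
            raise ValueError("run.region_bp must be a multiple of cg.nu")

    if "nk" in cg and "phi" in cg:
        raise ValueError("give at most one of cg.phi / cg.nk")
    if "nk" in cg:
        row = cg_theory.build_cg_table(preset, [nu], nks=[float(cg["nk"])])[0]
        phi_target = row.phi
    else:
        phi_target = float(cg.get("phi", 1.0))
    if not (0 < phi_target <= 2):
        raise ValueError(f"phi = {phi_target} infeasible (must be in (0, 2])")

    lattice = choose_box(n_monomers, phi_target)
    phi_real = n_monomers / lattice.n_sites
    b, lk = solve_cg_geometry(preset, n, phi_real)
    model = dict(cfg.get("model") or {})
    kappa = (
        float(model["kappa"])
        if "kappa" in model
        else kappa_from_kuhn_ratio(min(lk / b, cg_theory.KUHN_RATIO_CAP - 1e-9))
    )
    manifest = {
        "preset": {
            "rho": preset.rho,
            "nu0": preset.nu0,
            "b0": preset.b0,
            "lk0": preset.lk0,
            "c": preset.c,
            "ne0": preset.ne0,
            "phi0": preset.phi0,
        },
        "cg": {
            "nu": nu,
            "n": n,
            "phi_target": phi_target,
            "phi_realized": phi_real,
            "b_nm": b,
            "lk_nm": lk,
            "kappa_kT": kappa,
            "nk_bp": nu * lk / b,
        },
        "lattice": {"S": lattice.S, "M": lattice.M, "n_sites": lattice.n_sites},
        "model": {
            "e_i": float(model.get("e_i", 0.0)),
            "n_states": int(model.get("n_states", 4)),
            "include_bonded_pairs": bool(model.get("include_bonded_pairs", False)),
        },
        "run": {
            "n_monomers": n_monomers,
            "chain_bp": n_monomers * nu,
            "n_mcs": int(run.get("n_mcs", 100_000)),
            "snapshot_every": int(run.get("snapshot_every", 1000)),
            "n_replicas": int(run.get("n_replicas", 1)),
            "seed": int(run.get("seed", 0)),
            "energy_check_every": int(run.get("energy_check_every", 0)),
            "init": run.get("init", "hedgehog"),
        },
        "observables": {
            "dc_map_nm": default_contact_threshold(b),
            "d_kinetics_nm": default_kinetics_threshold(b),
        },
        "io": dict(cfg.get("io") or {}),
    }
    if preset.ne0 is not None:
        rep = cg_theory.entanglement(preset, n_monomers * nu)
        manifest["entanglement"] = {
            "ne_bp": rep.ne,
            "le_nm": rep.le,
            "L_over_Le": rep.ratio,
        }
    return manifest


def manifest_json(manifest: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a manifest."""
    return json.dumps(manifest, sort_keys=True, indent=2)


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(manifest_json(manifest).encode()).hexdigest()[:16]
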