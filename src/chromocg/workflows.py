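"""End-to-end workflow wiring: resolve config -> init -> simulate -> measure.

Two pipelines mirror the two halves of the method: the *null model*
(homopolymer at controlled entanglement; MSD and structure scaling) and
the *copolymer* (epigenome-decorated chain; contact maps, intra/inter
state contact statistics, pair kinetics).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np

from . import epigenome as epi
from . import observables as obs
from .cg_theory import phantom_end_to_end
from .config import manifest_hash, manifest_json, resolve_config
from .conformation import init_conformation
from .engine import EnergyModel, KmcConfig, Trajectory, run_replicas
from .lattice import FccLattice

logger = logging.getLogger("chromocg")

__all__ = ["simulate_from_manifest", "workflow_null_model", "workflow_copolymer"]


def _lattice(manifest: dict) -> FccLattice:
    return FccLattice(S=manifest["lattice"]["S"], b=manifest["cg"]["b_nm"])


def simulate_from_manifest(
    manifest: dict, states: np.ndarray | None = None
) -> list[Trajectory]:
    """Run the replicas a manifest describes (optionally state-decorated)."""
    lat = _lattice(manifest)
    rcfg = manifest["run"]
    mcfg = manifest["model"]
    if mcfg["e_i"] != 0.0 and states is None:
        raise ValueError("copolymer energies need per-monomer states")
    model = (
        EnergyModel.homotypic(
            kappa=manifest["cg"]["kappa_kT"],
            e_i=mcfg["e_i"],
            n_states=mcfg["n_states"],
        )
        if mcfg["e_i"] != 0.0
        else EnergyModel(kappa=manifest["cg"]["kappa_kT"])
    )
    model.include_bonded_pairs = mcfg["include_bonded_pairs"]
    n = rcfg["n_monomers"]

    def make_conf(seed: int):
        conf = init_conformation(rcfg["init"], n, lat, seed=seed)
        conf.states = states
        return conf

    cfg = KmcConfig(
        n_mcs=rcfg["n_mcs"],
        snapshot_every=rcfg["snapshot_every"],
        seed=rcfg["seed"],
        energy_check_every=rcfg["energy_check_every"],
    )
    logger.info(
        "simulating %d replicas of N=%d for %d MCS (manifest %s)",
        rcfg["n_replicas"], n, rcfg["n_mcs"], manifest_hash(manifest),
    )
    trajs = run_replicas(make_conf, model, cfg, rcfg["n_replicas"])
    for t in trajs:
        logger.info("replica seed %d acceptance %.4f", t.seed, t.acceptance_rate)
    return trajs


def workflow_null_model(source, outdir: str | None = None) -> dict:
    """Null-model pipeline: g1/g3, <R^2(s)>, Pc(s) and their exponents.

    Returns a report dict; if an intermediate-time window cannot be
    bracketed the exponent entries carry None plus a reason instead of a
    number (no fit is forced).
    """
    manifest = resolve_config(source)
    trajs = simulate_from_manifest(manifest)
    lat = _lattice(manifest)
    nu = manifest["cg"]["nu"]
    g1 = obs.msd_monomer(trajs)
    g3 = obs.msd_com(trajs)
    n = manifest["run"]["n_monomers"]
    half = (manifest["run"]["n_mcs"] // 2, manifest["run"]["n_mcs"])
    dc = manifest["observables"]["dc_map_nm"]
    seps = np.unique(np.round(np.logspace(0, math.log10(n - 1), 50)).astype(int))
    pc = obs.contact_probability(trajs, dc=dc, window=half, separations=seps, nu=nu)
    r2, sigma2 = obs.distance_moments(trajs, window=half, separations=seps, nu=nu)

    report: dict = {
        "manifest": manifest,
        "manifest_hash": manifest_hash(manifest),
        "acceptance": [t.acceptance_rate for t in trajs],
        "series": {"g1": g1, "g3": g3, "Pc": pc, "R2": r2, "sigma2": sigma2},
        "fits": {},
    }
    re2 = phantom_end_to_end(n, manifest["cg"]["kappa_kT"], lat.b)
    try:
        window = obs.intermediate_time_window(g1, manifest["cg"]["lk_nm"], re2)
        report["fits"]["g1_intermediate"] = obs.fit_power_law(g1, window)
    except ValueError as exc:
        report["fits"]["g1_intermediate"] = None
        report["fits"]["g1_intermediate_reason"] = str(exc)
        logger.warning("g1 fit skipped: %s", exc)
    try:
        s_lo, s_hi = obs.structure_fit_window(
            manifest["cg"]["lk_nm"] / lat.b, lat.b, lat.box_edge_nm
        )
        s_window = (s_lo * nu, min(s_hi, n - 1) * nu)
    except ValueError as exc:
        s_window = None
        report["fits"]["structure_window_reason"] = str(exc)
    for name, series in (("Pc", pc), ("R2", r2)):
        try:
            if s_window is None:
                raise ValueError("no admissible structure window")
            report["fits"][name] = obs.fit_power_law(series, s_window)
        except ValueError as exc:
            report["fits"][name] = None
            report["fits"][f"{name}_reason"] = str(exc)

    if outdir:
        _write_null_outputs(report, outdir)
    return report


def _write_null_outputs(report: dict, outdir: str) -> None:
    from .io import write_fit_json, write_series_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = report["manifest_hash"]
    for name, series in report["series"].items():
        write_series_tsv(series, out / f"{name}.tsv", comment=f"manifest {tag}")
    write_fit_json(
        {k: v for k, v in report["fits"].items() if not k.endswith("_reason")},
        out / "fits.json",
    )
    (out / "manifest.json").write_text(manifest_json(report["manifest"]))


def workflow_copolymer(
    source,
    annotation,
    e_i_values: list[float] | None = None,
    pairs: list[tuple[int, int]] | None = None,
    outdir: str | None = None,
) -> dict:
    """Copolymer pipeline: maps, state-resolved Pc, ratios, pair kinetics.

    ``annotation`` is an EpigenomeAnnotation or BED path covering the
    region; ``e_i_values`` sweeps the same-state contact energy (defaults
    to the manifest's single value).  ``pairs`` lists monomer index pairs
    for contact kinetics (skipped with a log notice when empty).
    """
    manifest = resolve_config(source)
    nu = manifest["cg"]["nu"]
    n = manifest["run"]["n_monomers"]
    region = ("chrSim", 0, int(n * nu))
    if not isinstance(annotation, epi.EpigenomeAnnotation):
        annotation = epi.EpigenomeAnnotation.from_bed(annotation)
    chroms = annotation.intervals["chrom"].unique()
    if len(chroms) == 1:
        region = (chroms[0], *annotation.span(chroms[0]))
        if region[2] - region[1] < n * nu:
            raise ValueError("annotation does not cover the simulated region")
        region = (region[0], region[1], region[1] + int(n * nu))
    states = epi.load_epigenome(annotation, region, nu)
    dc = manifest["observables"]["dc_map_nm"]
    d_kin = manifest["observables"]["d_kinetics_nm"]
    sweep = e_i_values if e_i_values is not None else [manifest["model"]["e_i"]]

    results = {}
    for e_i in sweep:
        m = {**manifest, "model": {**manifest["model"], "e_i": float(e_i)}}
        trajs = simulate_from_manifest(m, states=states)
        cmap = epi.contact_map(trajs, dc=dc, nu=nu)
        pc, p_intra, p_inter = epi.pc_by_state(trajs, dc=dc, states=states, nu=nu)
        bands = [
            (lo, hi)
            for lo, hi in epi.DEFAULT_BANDS_BP
            if lo < (n - 1) * nu
        ]
        ratios = epi.ratio_timecourse(trajs, dc=dc, states=states, nu=nu,
                                      distance_bands=bands)
        kinetics = []
        if pairs:
            for (i, j) in pairs:
                for traj in trajs:
                    times, dist = epi.pair_distance_series(traj, i, j)
                    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
                    kin = epi.pair_kinetics(dist, threshold=d_kin, dt=dt)
                    kinetics.append(((i, j), traj.seed, kin))
        else:
            logger.info("no pairs declared; kinetics stage skipped")
        results[e_i] = {
            "trajectories": trajs,
            "contact_map": cmap,
            "Pc": pc,
            "P_intra": p_intra,
            "P_inter": p_inter,
            "ratio_timecourse": ratios,
            "kinetics": kinetics,
        }
    report = {
        "manifest": manifest,
        "manifest_hash": manifest_hash(manifest),
        "states": states,
        "by_e_i": results,
    }
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for e_i, res in results.items():
            res["contact_map"].to_tsv(out / f"map_ei{e_i:+.2f}.tsv")
            res["ratio_timecourse"].to_csv(
                out / f"ratios_ei{e_i:+.2f}.tsv", sep="\t", index=False
            )
    return report
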