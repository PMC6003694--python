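"""Text serialization of trajectories and tabular observable output.

Trajectories are stored as plain columnar text: a commented header with
the lattice, seed and acceptance statistics, an optional per-monomer state
line, then one block per snapshot holding unfolded integer grid
coordinates.  Observable series and fits go to TSV / JSON.
"""

from __future__ import annotations

import json

import numpy as np

from .engine import Trajectory
from .lattice import FccLattice
from .observables import ObservableSeries, PowerLawFit

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_series_tsv",
    "write_fit_json",
]


def write_trajectory(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chromocg trajectory\n")
        spm = traj.sec_per_mcs if traj.sec_per_mcs is not None else "-"
        fh.write(
            f"# S={traj.lattice.S} b={float(traj.lattice.b)!r} seed={traj.seed} "
            f"acceptance={float(traj.acceptance_rate)!r} sec_per_mcs={spm}\n"
        )
        if traj.states is not None:
            fh.write("# states " + " ".join(map(str, traj.states)) + "\n")
        for t in range(traj.n_snapshots):
            fh.write(
                f"# snapshot mcs={int(traj.mcs[t])} energy={float(traj.energy[t])!r}\n"
            )
            for m in range(traj.n_monomers):
                x, y, z = traj.positions[t, m]
                fh.write(f"{x} {y} {z}\n")


def read_trajectory(path) -> Trajectory:
    S = b = seed = None
    acceptance = 0.0
    sec_per_mcs = None
    states = None
    mcs_list: list[int] = []
    energy_list: list[float] = []
    blocks: list[list[list[int]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("states"):
                    states = np.array(body.split()[1:], dtype=np.int8)
                    continue
                if body.startswith("snapshot"):
                    kv = dict(tok.split("=", 1) for tok in body.split()[1:])
                    mcs_list.append(int(kv["mcs"]))
                    energy_list.append(float(kv["energy"]))
                    blocks.append([])
                    continue
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "S":
                            S = int(v)
                        elif k == "b":
                            b = float(v)
                        elif k == "seed":
                            seed = int(v)
                        elif k == "acceptance":
                            acceptance = float(v)
                        elif k == "sec_per_mcs" and v != "-":
                            sec_per_mcs = float(v)
                continue
            blocks[-1].append([int(x) for x in line.split()])
    if S is None or b is None or not blocks:
        raise ValueError(f"{path} is not a chromocg trajectory")
    return Trajectory(
        lattice=FccLattice(S=S, b=b),
        mcs=np.array(mcs_list, dtype=np.int64),
        positions=np.array(blocks, dtype=np.int64),
        energy=np.array(energy_list),
        seed=seed if seed is not None else 0,
        acceptance_rate=acceptance,
        states=states,
        sec_per_mcs=sec_per_mcs,
    )


def write_series_tsv(series: ObservableSeries, path, comment: str = "") -> None:
    """TSV with columns (abscissa, value, stderr, n) and a commented header."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# {series.label or 'series'}\n")
        fh.write("# abscissa\tvalue\tstderr\tn\n")
        for a, v, e, n in zip(
            series.abscissa, series.values, series.stderr, series.n_samples
        ):
            fh.write(f"{a!r}\t{v!r}\t{e!r}\t{n}\n")


def write_fit_json(fits: dict[str, PowerLawFit | None], path) -> None:
    payload = {}
    for name, fit in fits.items():
        if fit is None:
            payload[name] = None
        else:
            payload[name] = {
                "exponent": fit.exponent,
                "amplitude": fit.amplitude,
                "stderr": fit.stderr,
                "window": list(fit.window),
                "n_points": fit.n_points,
            }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
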