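"""Kinetic Monte-Carlo driver: Hamiltonian, run configuration, trajectories.

One Monte-Carlo step (MCS) is N trial moves; each trial picks a monomer and
one of the 12 nearest-neighbor displacements uniformly, checks the
stored-length occupancy and connectivity rules, and accepts with the
Metropolis probability min(1, exp(-dE)) at temperature 1 (energies in kT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .conformation import Conformation, validate
from .lattice import FccLattice

__all__ = [
    "EnergyModel",
    "KmcConfig",
    "Trajectory",
    "total_energy",
    "run",
    "run_replicas",
]


@dataclass
class EnergyModel:
    """Bending rigidity plus epigenomic state-pair interaction matrix.

    Parameters
    ----------
    kappa : float
        Bending rigidity, kT; energy kappa*(1 - cos theta) per angle between
        consecutive non-zero bonds.
    U : ndarray (K, K) or None
        Symmetric interaction matrix over state indices, kT; entry
        U[e, e'] applies to monomer pairs on nearest-neighbor sites.  The
        homotypic copolymer of interest has U = E_i * I (E_i < 0 attracts).
    include_bonded_pairs : bool
        If True, bonded pairs |i - j| = 1 on nearest-neighbor sites also
        contribute; the default excludes them (they would only add a
        state-independent offset for homotypic matrices).
    """

    kappa: float = 0.0
    U: np.ndarray | None = None
    include_bonded_pairs: bool = False

    def __post_init__(self) -> None:
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=np.float64)
            if self.U.ndim != 2 or self.U.shape[0] != self.U.shape[1]:
                raise ValueError("U must be a square matrix")
            if not np.allclose(self.U, self.U.T):
                raise ValueError("U must be symmetric")

    @classmethod
    def homotypic(
        cls, kappa: float, e_i: float, n_states: int = 4
    ) -> "EnergyModel":
        """Same-state contact energy E_i for every state, zero otherwise."""
        return cls(kappa=kappa, U=e_i * np.eye(n_states))

    @property
    def has_interactions(self) -> bool:
        return self.U is not None and np.any(self.U != 0.0)

    @property
    def exclude_min(self) -> int:
        return 1 if self.include_bonded_pairs else 2


@dataclass
class KmcConfig:
    """Run length, recording cadence and seeding of one KMC run."""

    n_mcs: int
    snapshot_every: int = 1000
    seed: int = 0
    energy_check_every: int = 0  # 0 disables the full-energy audit

    def __post_init__(self) -> None:
        if self.n_mcs < 0:
            raise ValueError("n_mcs must be >= 0")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")
        if self.energy_check_every < 0:
            raise ValueError("energy_check_every must be >= 0")


@dataclass
class Trajectory:
    """Time-ordered unfolded snapshots of one KMC run.

    ``positions`` holds unfolded integer grid coordinates of shape
    (n_snapshots, N, 3); multiply by ``lattice.a`` (done by
    :meth:`positions_nm`) for nm.
    """

    lattice: FccLattice
    mcs: np.ndarray  # (T,)
    positions: np.ndarray  # (T, N, 3) int64, unfolded grid units
    energy: np.ndarray  # (T,) running total energy, kT
    seed: int
    acceptance_rate: float
    states: np.ndarray | None = None
    energy_audit: np.ndarray | None = None  # (n_audit, 3): mcs, incr, recomputed
    sec_per_mcs: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[1]

    @property
    def n_snapshots(self) -> int:
        return self.positions.shape[0]

    def positions_nm(self) -> np.ndarray:
        """Unfolded coordinates in nm, float64 (T, N, 3)."""
        return self.positions.astype(np.float64) * self.lattice.a

    def times(self) -> np.ndarray:
        """Snapshot times: seconds if a time mapping is set, else MCS."""
        if self.sec_per_mcs is not None:
            return self.mcs * self.sec_per_mcs
        return self.mcs.astype(np.float64)

    def snapshot(self, t_index: int) -> Conformation:
        """Snapshot ``t_index`` as a Conformation (folded + images)."""
        return Conformation.from_unfolded(
            self.lattice, self.positions[t_index], states=self.states
        )


def _states_array(conf: Conformation, model: EnergyModel) -> np.ndarray:
    if model.has_interactions:
        if conf.states is None:
            raise ValueError("nonzero U requires per-monomer states")
        states = np.asarray(conf.states, dtype=np.int8)
        if states.min() < 0 or states.max() >= model.U.shape[0]:
            raise ValueError("state index outside the U matrix")
        return states
    if conf.states is not None:
        return np.asarray(conf.states, dtype=np.int8)
    return np.zeros(conf.n_monomers, dtype=np.int8)


def total_energy(conf: Conformation, model: EnergyModel) -> float:
    """Total Hamiltonian of a conformation, kT."""
    states = _states_array(conf, model)
    U = model.U if model.U is not None else np.zeros((1, 1))
    return float(
        _kernels.total_energy_kernel(
            np.ascontiguousarray(conf.unfolded),
            states,
            float(model.kappa),
            np.ascontiguousarray(U, dtype=np.float64),
            conf.lattice.M,
            model.exclude_min,
        )
    )


def run(conf: Conformation, model: EnergyModel, config: KmcConfig) -> Trajectory:
    """Simulate a trajectory; deterministic given ``config.seed``.

    The running (incrementally updated) energy is audited against a full
    recomputation every ``energy_check_every`` MCS; a discrepancy beyond
    1e-6 kT aborts with the offending state attached.
    """
    pos = np.ascontiguousarray(conf.unfolded, dtype=np.int64).copy()
    states = _states_array(conf, model)
    U = np.ascontiguousarray(
        model.U if model.U is not None else np.zeros((1, 1)), dtype=np.float64
    )
    n_snap = config.n_mcs // config.snapshot_every + 1
    out_pos = np.empty((n_snap, pos.shape[0], 3), dtype=np.int64)
    out_mcs = np.empty(n_snap, dtype=np.int64)
    out_energy = np.empty(n_snap, dtype=np.float64)
    n_audit = (
        config.n_mcs // config.energy_check_every if config.energy_check_every else 0
    )
    audit = np.empty((n_audit, 3), dtype=np.float64)

    accepted, trials, _ = _kernels.kmc_run(
        pos,
        states,
        float(model.kappa),
        U,
        conf.lattice.M,
        config.n_mcs,
        config.snapshot_every,
        config.energy_check_every,
        int(config.seed) % (2**31),
        model.exclude_min,
        out_pos,
        out_mcs,
        out_energy,
        audit,
        model.has_interactions,
    )

    if n_audit and np.any(np.abs(audit[:, 1] - audit[:, 2]) > 1e-6):
        i = int(np.argmax(np.abs(audit[:, 1] - audit[:, 2])))
        raise RuntimeError(
            "energy bookkeeping drift at MCS "
            f"{int(audit[i, 0])}: incremental {audit[i, 1]!r} vs "
            f"recomputed {audit[i, 2]!r}; final state: {pos.tolist()[:8]}..."
        )

    return Trajectory(
        lattice=conf.lattice,
        mcs=out_mcs,
        positions=out_pos,
        energy=out_energy,
        seed=config.seed,
        acceptance_rate=accepted / trials if trials else 0.0,
        states=conf.states,
        energy_audit=audit if n_audit else None,
        meta={"kappa": model.kappa, "n_mcs": config.n_mcs},
    )


def run_replicas(
    base_conf_generator: Callable[[int], Conformation],
    model: EnergyModel,
    config: KmcConfig,
    n_replicas: int,
) -> list[Trajectory]:
    """Independent replicas: replica k uses seed = base seed + k.

    ``base_conf_generator(seed)`` must return the initial conformation for
    that replica (it may ignore the seed for a fixed start).
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    out = []
    for k in range(n_replicas):
        seed_k = config.seed + k
        conf_k = base_conf_generator(seed_k)
        cfg_k = KmcConfig(
            n_mcs=config.n_mcs,
            snapshot_every=config.snapshot_every,
            seed=seed_k,
            energy_check_every=config.energy_check_every,
        )
        out.append(run(conf_k, model, cfg_k))
    return out
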