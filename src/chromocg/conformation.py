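"""Lattice-chain conformations: storage, validity, unfolding, initializers.

A conformation stores folded site coordinates together with per-monomer
periodic-image counters, so that unfolded (real-space) coordinates are
always recoverable: ``unfolded = sites + M * images``.  Consecutive
monomers sit either on the same site (a unit of *stored length*, standing
for contour-length fluctuation) or on nearest-neighbor sites; a site holds
at most two monomers and only if they are consecutive along the chain.

Initial configurations:

``hedgehog``
    Knot-free growth: a short straight central scaffold, then repeated
    insertion of new monomers at sites adjacent to (or coincident with)
    both ends of a randomly chosen existing bond.  Because every insertion
    is local, the chain is grown without ever threading through itself.
``line``
    A straight nearest-neighbor path; if the chain is longer than the box
    traverse, consecutive pairs double up on sites (stored length) to halve
    the footprint.
``random_collapse``
    Plain random sequential growth (may be knotted); the control case for
    reptation-like dynamics of topologically complex states.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .lattice import NEIGHBOR_OFFSETS, FccLattice, is_nn_offset

__all__ = [
    "Conformation",
    "validate",
    "unfold",
    "init_conformation",
    "write_conformation",
    "read_conformation",
    "write_xyz",
]

_O13 = np.vstack([np.zeros((1, 3), dtype=np.int64), NEIGHBOR_OFFSETS])
_O13_SET = {tuple(o) for o in _O13.tolist()}


@dataclass
class Conformation:
    """Ordered monomer positions on a periodic fcc lattice.

    Attributes
    ----------
    lattice : FccLattice
    sites : ndarray of shape (N, 3), int
        Folded grid coordinates, each in [0, M)^3 with even sum.
    images : ndarray of shape (N, 3), int
        Box-wrap counters; unfolded = sites + M * images.
    states : ndarray of shape (N,), int or None
        Optional per-monomer epigenomic state indices.
    """

    lattice: FccLattice
    sites: np.ndarray
    images: np.ndarray
    states: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.images = np.asarray(self.images, dtype=np.int64)
        if self.sites.shape != self.images.shape or self.sites.ndim != 2:
            raise ValueError("sites and images must both be (N, 3)")
        if self.states is not None:
            self.states = np.asarray(self.states)
            if self.states.shape[0] != self.sites.shape[0]:
                raise ValueError("states length must match the chain length")

    @property
    def n_monomers(self) -> int:
        return self.sites.shape[0]

    @property
    def unfolded(self) -> np.ndarray:
        """Unfolded integer grid coordinates, (N, 3)."""
        return self.sites + self.lattice.M * self.images

    @classmethod
    def from_unfolded(
        cls,
        lattice: FccLattice,
        coords: np.ndarray,
        states: np.ndarray | None = None,
        **meta,
    ) -> "Conformation":
        coords = np.asarray(coords, dtype=np.int64)
        return cls(
            lattice=lattice,
            sites=lattice.fold(coords),
            images=lattice.images(coords),
            states=states,
            meta=dict(meta),
        )

    def occupancy(self) -> dict[tuple[int, int, int], list[int]]:
        """Map folded site -> ordered list of monomer indices on it."""
        occ: dict[tuple[int, int, int], list[int]] = {}
        for i, s in enumerate(map(tuple, self.sites.tolist())):
            occ.setdefault(s, []).append(i)
        return occ


def validate(conf: Conformation) -> list[str]:
    """Check all conformation invariants; return human-readable violations.

    An empty list means the conformation is valid.  Reported rules:
    ``parity`` (coordinates off the fcc sublattice), ``box`` (folded
    coordinate outside [0, M)), ``connectivity`` (a bond that is neither
    zero-length nor a nearest-neighbor step) and ``occupancy`` (more than
    two monomers on a site, or a doubly occupied site whose occupants are
    not consecutive).
    """
    out: list[str] = []
    lat = conf.lattice
    if not np.all(lat.is_site(conf.sites)):
        bad = np.nonzero(~lat.is_site(conf.sites))[0]
        out.extend(f"parity: monomer {i} off-lattice" for i in bad)
    if np.any(conf.sites < 0) or np.any(conf.sites >= lat.M):
        out.append("box: folded coordinates outside [0, M)")
    d = np.diff(conf.unfolded, axis=0)
    if d.size:
        ok = (d == 0).all(axis=1) | is_nn_offset(d)
        for i in np.nonzero(~ok)[0]:
            out.append(
                f"connectivity: bond {i}-{i + 1} has displacement {d[i].tolist()}"
            )
    for site, members in conf.occupancy().items():
        if len(members) > 2:
            out.append(f"occupancy: site {site} holds {len(members)} monomers")
        elif len(members) == 2 and abs(members[0] - members[1]) != 1:
            out.append(
                f"occupancy: site {site} holds non-consecutive monomers "
                f"{members[0]}, {members[1]}"
            )
    return out


def unfold(conf: Conformation) -> np.ndarray:
    """Unfolded real-space coordinates in nm, shape (N, 3).

    Continuous across box boundaries: inter-monomer vectors equal the
    accumulated bond vectors, so chains may extend beyond the box.
    """
    return conf.lattice.to_nm(conf.unfolded)


def _grow_insertions(
    coords: list[np.ndarray],
    occ: dict[tuple[int, int, int], int],
    lattice: FccLattice,
    n_target: int,
    rng: np.random.Generator,
    max_stall: int,
) -> bool:
    """Insert monomers at random bonds until the chain reaches n_target."""
    M = lattice.M
    stall = 0
    while len(coords) < n_target:
        i = int(rng.integers(len(coords) - 1))
        a, bpt = coords[i], coords[i + 1]
        if np.array_equal(a, bpt):
            # a stored-length bond: any insertion between the co-located
            # pair would leave them doubly occupying a site while no longer
            # consecutive, so such bonds accept no insertions
            stall += 1
            if stall > max_stall:
                return False
            continue
        cands = a[None, :] + _O13
        keep = []
        for p in cands:
            if tuple((bpt - p).tolist()) not in _O13_SET:
                continue
            cnt = occ.get(tuple(np.mod(p, M).tolist()), 0)
            if cnt == 0:
                keep.append(p)
            elif cnt == 1 and (np.array_equal(p, a) or np.array_equal(p, bpt)):
                keep.append(p)
        if not keep:
            stall += 1
            if stall > max_stall:
                return False
            continue
        stall = 0
        p = keep[int(rng.integers(len(keep)))]
        key = tuple(np.mod(p, M).tolist())
        occ[key] = occ.get(key, 0) + 1
        coords.insert(i + 1, p)
    return True


def init_conformation(
    kind: str,
    n_monomers: int,
    lattice: FccLattice,
    seed: int = 0,
    n_restarts: int = 5,
) -> Conformation:
    """Generate a valid initial conformation.

    Parameters
    ----------
    kind : {"hedgehog", "line", "random_collapse"}
    n_monomers : int
        Chain length; at most twice the number of lattice sites.
    lattice : FccLattice
    seed : int
        Seed for the growth randomness (hedgehog / random_collapse).
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if n_monomers > 2 * lattice.n_sites:
        raise ValueError("chain longer than twice the number of sites")
    M = lattice.M
    if kind == "line":
        n_sites_needed = n_monomers if n_monomers <= M else -(-n_monomers // 2)
        if n_sites_needed > M:
            raise ValueError(
                f"line initializer supports at most {2 * M} monomers on this box"
            )
        step = np.array([1, 1, 0], dtype=np.int64)
        start = np.array([0, 0, M // 2], dtype=np.int64)
        if n_monomers <= M:
            coords = start[None, :] + np.arange(n_monomers)[:, None] * step
        else:  # stored-length folding: consecutive pairs share sites
            site_idx = np.arange(n_monomers) // 2
            coords = start[None, :] + site_idx[:, None] * step
        return Conformation.from_unfolded(lattice, coords, kind="line")

    for attempt in range(n_restarts):
        rng = np.random.default_rng(seed + 1000003 * attempt)
        if kind == "hedgehog":
            L0 = min(n_monomers, M)
            c0 = M // 2
            step = np.array([1, 1, 0], dtype=np.int64)
            start = np.array([c0 - (L0 // 2), c0 - (L0 // 2), c0], dtype=np.int64)
            if start.sum() % 2:
                start[2] += 1
            coords = [start + k * step for k in range(L0)]
            occ: dict[tuple[int, int, int], int] = {}
            for p in coords:
                key = tuple(np.mod(p, M).tolist())
                occ[key] = occ.get(key, 0) + 1
            if n_monomers == 1 or _grow_insertions(
                coords, occ, lattice, n_monomers, rng, max_stall=200 * n_monomers
            ):
                conf = Conformation.from_unfolded(
                    lattice, np.array(coords), kind="hedgehog", seed=seed
                )
                return conf
        elif kind == "random_collapse":
            p0 = 2 * rng.integers(0, lattice.S, size=3)
            coords = [np.asarray(p0, dtype=np.int64)]
            occ = {tuple(np.mod(p0, M).tolist()): 1}
            ok = True
            stall = 0
            while len(coords) < n_monomers:
                prev = coords[-1]
                order = rng.permutation(13)
                placed = False
                for oi in order:
                    p = prev + _O13[oi]
                    key = tuple(np.mod(p, M).tolist())
                    cnt = occ.get(key, 0)
                    # an occupied target is legal only as stored length on prev
                    if cnt == 0 or (cnt == 1 and np.array_equal(p, prev)):
                        occ[key] = cnt + 1
                        coords.append(p)
                        placed = True
                        break
                if not placed:
                    # back out a few monomers and retry
                    stall += 1
                    if stall > 50 * n_monomers:
                        ok = False
                        break
                    n_back = min(len(coords) - 1, 8)
                    for _ in range(n_back):
                        q = coords.pop()
                        key = tuple(np.mod(q, M).tolist())
                        occ[key] -= 1
                        if occ[key] == 0:
                            del occ[key]
            if ok and len(coords) == n_monomers:
                return Conformation.from_unfolded(
                    lattice, np.array(coords), kind="random_collapse", seed=seed
                )
        else:
            raise ValueError(f"unknown initializer kind: {kind!r}")
    raise RuntimeError(
        f"{kind} growth stalled for N={n_monomers} on S={lattice.S} "
        f"after {n_restarts} restarts; the box may be too full"
    )


# ---------------------------------------------------------------------------
# text serialization


def write_conformation(conf: Conformation, path_or_handle) -> None:
    """Write a conformation as columnar text.

    Header comments carry S, b and any metadata; one row per monomer with
    columns (index, i, j, k, image_x, image_y, image_z, state).
    """
    own = isinstance(path_or_handle, (str, bytes))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("# chromocg conformation\n")
        fh.write(f"# S={conf.lattice.S} b={conf.lattice.b!r}\n")
        for k, v in conf.meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("# monomer i j k ix iy iz state\n")
        states = conf.states
        for m in range(conf.n_monomers):
            s = conf.sites[m]
            im = conf.images[m]
            st = "-" if states is None else str(states[m])
            fh.write(
                f"{m} {s[0]} {s[1]} {s[2]} {im[0]} {im[1]} {im[2]} {st}\n"
            )
    finally:
        if own:
            fh.close()


def read_conformation(path_or_handle) -> Conformation:
    """Read a conformation written by :func:`write_conformation`."""
    own = isinstance(path_or_handle, (str, bytes))
    fh = open(path_or_handle) if own else path_or_handle
    try:
        S = b = None
        meta: dict = {}
        rows, states = [], []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "S":
                            S = int(v)
                        elif k == "b":
                            b = float(v)
                        else:
                            meta[k] = v
                continue
            parts = line.split()
            rows.append([int(x) for x in parts[1:7]])
            states.append(parts[7])
        if S is None or b is None:
            raise ValueError("missing S/b header")
        arr = np.array(rows, dtype=np.int64)
        st = None
        if states and states[0] != "-":
            st = np.array([int(s) for s in states], dtype=np.int64)
        return Conformation(
            lattice=FccLattice(S=S, b=b),
            sites=arr[:, :3],
            images=arr[:, 3:],
            states=st,
            meta=meta,
        )
    finally:
        if own:
            fh.close()


def write_xyz(conf: Conformation, path_or_handle, comment: str = "") -> None:
    """Export unfolded coordinates (nm) in XYZ format for visualization."""
    own = isinstance(path_or_handle, (str, bytes))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        coords = unfold(conf)
        fh.write(f"{conf.n_monomers}\n{comment}\n")
        for m, (x, y, z) in enumerate(coords):
            label = "C" if conf.states is None else f"S{conf.states[m]}"
            fh.write(f"{label} {x:.4f} {y:.4f} {z:.4f}\n")
    finally:
        if own:
            fh.close()
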