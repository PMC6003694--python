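"""Face-centered-cubic lattice geometry with periodic boundaries.

Sites are embedded as integer triples (i, j, k) with even coordinate sum on
a cubic grid of spacing a = b/sqrt(2); the 12 nearest neighbors are the
permutations of (+-1, +-1, 0), all at Euclidean distance b.  The periodic
box is an S x S x S stack of cubic unit cells (4 sites each), i.e. the
integer grid has period M = 2S per axis, so the box holds M^3/2 = 4 S^3
sites.  M is even, hence the wrap preserves the parity that defines the
lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NEIGHBOR_OFFSETS", "FccLattice"]

#: The 12 nearest-neighbor offsets in grid units: permutations of (+-1,+-1,0).
NEIGHBOR_OFFSETS = np.array(
    [
        [1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0],
        [1, 0, 1], [1, 0, -1], [-1, 0, 1], [-1, 0, -1],
        [0, 1, 1], [0, 1, -1], [0, -1, 1], [0, -1, -1],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class FccLattice:
    """Periodic fcc lattice of S x S x S unit cells with bond length b (nm).

    Attributes
    ----------
    S : int
        Unit cells per box edge; the box holds 4 S^3 sites.
    b : float
        Nearest-neighbor distance, nm.
    """

    S: int
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if self.b <= 0:
            raise ValueError("b must be positive")

    @property
    def M(self) -> int:
        """Integer-grid period per axis (= 2S)."""
        return 2 * self.S

    @property
    def n_sites(self) -> int:
        return 4 * self.S**3

    @property
    def a(self) -> float:
        """Cubic-grid spacing in nm (= b / sqrt(2))."""
        return self.b / np.sqrt(2.0)

    @property
    def box_edge_nm(self) -> float:
        """Physical box edge, nm (= M * a)."""
        return self.M * self.a

    def is_site(self, coords: np.ndarray) -> np.ndarray:
        """True where integer triples have even coordinate sum."""
        coords = np.asarray(coords)
        return coords.sum(axis=-1) % 2 == 0

    def fold(self, coords: np.ndarray) -> np.ndarray:
        """Wrap integer grid coordinates into [0, M) per axis."""
        return np.mod(np.asarray(coords, dtype=np.int64), self.M)

    def images(self, coords: np.ndarray) -> np.ndarray:
        """Box-wrap counts such that coords = fold(coords) + M * images."""
        return np.floor_divide(np.asarray(coords, dtype=np.int64), self.M)

    def site_index(self, folded: np.ndarray) -> np.ndarray:
        """Flat index of folded coordinates (row-major over the M^3 grid)."""
        folded = np.asarray(folded, dtype=np.int64)
        return (folded[..., 0] * self.M + folded[..., 1]) * self.M + folded[..., 2]

    def neighbors(self, site: np.ndarray) -> np.ndarray:
        """The 12 nearest-neighbor sites of ``site``, folded into the box.

        ``site`` is an integer triple on the lattice (even coordinate sum).
        """
        site = np.asarray(site, dtype=np.int64)
        if site.shape != (3,):
            raise ValueError("site must be an integer triple")
        if not self.is_site(site):
            raise ValueError(f"{site.tolist()} is not an fcc site (odd parity)")
        if np.any(site < 0) or np.any(site >= self.M):
            raise ValueError(f"{site.tolist()} outside the box [0, {self.M})^3")
        return self.fold(site[None, :] + NEIGHBOR_OFFSETS)

    def min_image(self, delta: np.ndarray) -> np.ndarray:
        """Minimal-image displacement: components mapped into [-M/2, M/2)."""
        delta = np.asarray(delta, dtype=np.int64)
        M = self.M
        return (delta + M // 2) % M - M // 2

    def to_nm(self, coords: np.ndarray) -> np.ndarray:
        """Convert grid coordinates (possibly unfolded) to nm."""
        return np.asarray(coords, dtype=np.float64) * self.a


def is_nn_offset(delta: np.ndarray) -> np.ndarray:
    """True where integer displacement(s) are one of the 12 NN offsets."""
    delta = np.asarray(delta, dtype=np.int64)
    ad = np.abs(delta)
    return (ad.sum(axis=-1) == 2) & (ad.max(axis=-1) == 1)


def choose_box(n_monomers: int, phi_target: float, s_min: int = 2) -> FccLattice:
    """Box size whose realized volume fraction best matches ``phi_target``.

    Picks the integer S >= s_min minimizing |N/(4 S^3) - phi_target|.  The
    realized Phi (= N / 4S^3) should then be fed back into the geometry
    solver so that b, lk and kappa match the lattice actually simulated.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if not (0 < phi_target <= 2):
        raise ValueError("phi_target must lie in (0, 2]")
    s_real = (n_monomers / (4.0 * phi_target)) ** (1.0 / 3.0)
    best = None
    for S in {max(s_min, int(np.floor(s_real))), max(s_min, int(np.ceil(s_real)))}:
        err = abs(n_monomers / (4.0 * S**3) - phi_target)
        if best is None or err < best[0]:
            best = (err, S)
    return FccLattice(S=best[1])
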