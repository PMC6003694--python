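"""Epigenomic annotations and copolymer-specific contact observables.

The block-copolymer decoration assigns each monomer one of four chromatin
states — ``active`` (the two euchromatic classes of the five-state fly
annotation, merged), ``HP1`` (constitutive heterochromatin), ``PcG``
(Polycomb) and ``black`` (the prevalent, unmarked heterochromatin) — and
couples same-state monomers on nearest-neighbor lattice sites with a
contact energy E_i.  This module handles BED-style annotation I/O, a
synthetic-epigenome generator emulating the domain structure of the real
annotation, and the contact observables specific to the copolymer:
contact maps, intra-/inter-state contact probabilities, their time
courses, and pair-contact kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .engine import Trajectory
from .observables import ObservableSeries

__all__ = [
    "STATE_ALPHABET",
    "EpigenomeAnnotation",
    "ContactMap",
    "ContactKinetics",
    "load_epigenome",
    "synthetic_epigenome",
    "contact_map",
    "pc_by_state",
    "ratio_timecourse",
    "pair_kinetics",
    "map_correlation",
]

#: Canonical merged state alphabet, in index order.
STATE_ALPHABET = ("active", "HP1", "PcG", "black")

#: Five-state color labels of the fly annotation -> merged four-state labels.
DEFAULT_STATE_MAP = {
    "YELLOW": "active",
    "RED": "active",
    "GREEN": "HP1",
    "BLUE": "PcG",
    "BLACK": "black",
}

#: Approximate genomic share of each merged state in the fly annotation.
DEFAULT_STATE_FREQS = {"active": 0.35, "HP1": 0.07, "PcG": 0.10, "black": 0.48}


@dataclass
class EpigenomeAnnotation:
    """Interval annotation (0-based half-open) with a state alphabet."""

    intervals: pd.DataFrame  # columns: chrom, start, end, state
    state_alphabet: tuple[str, ...] = STATE_ALPHABET

    def __post_init__(self) -> None:
        df = self.intervals
        if not {"chrom", "start", "end", "state"}.issubset(df.columns):
            raise ValueError("intervals need columns chrom, start, end, state")
        if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
            raise ValueError("every interval needs start < end")

    def to_bed(self, path) -> None:
        """Write as 4-column tab-separated BED (no header)."""
        self.intervals[["chrom", "start", "end", "state"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(
        cls, path, state_alphabet: tuple[str, ...] = STATE_ALPHABET
    ) -> "EpigenomeAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "state"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "state": str},
            comment="#",
        )
        return cls(intervals=df, state_alphabet=state_alphabet)

    def span(self, chrom: str) -> tuple[int, int]:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no intervals on {chrom}")
        return int(sub["start"].min()), int(sub["end"].max())


def load_epigenome(
    annotation,
    region: tuple[str, int, int],
    nu: float,
    state_map: dict[str, str] | None = None,
    state_alphabet: Sequence[str] = STATE_ALPHABET,
    default_state: str = "black",
) -> np.ndarray:
    """Per-monomer state indices for a region at resolution ``nu`` bp.

    Each nu-bp monomer takes the state with the largest base-pair overlap
    (majority rule).  Input labels go through ``state_map`` (the five-state
    color labels merge the two euchromatic classes into ``active``; labels
    already in the alphabet pass through).  Uncovered monomers get
    ``default_state`` with a warning; unknown labels raise.

    Parameters
    ----------
    annotation : EpigenomeAnnotation or path
    region : (chrom, start, end) in bp, 0-based half-open
    nu : bp per monomer; the region length must be a multiple of nu
    """
    if not isinstance(annotation, EpigenomeAnnotation):
        annotation = EpigenomeAnnotation.from_bed(annotation)
    chrom, start, end = region
    if end <= start:
        raise ValueError("region end must exceed start")
    nu = int(nu)
    n_monomers = (end - start) // nu
    if n_monomers * nu != end - start:
        raise ValueError("region length must be a multiple of nu")
    alphabet = list(state_alphabet)
    lut = dict(DEFAULT_STATE_MAP if state_map is None else state_map)
    for s in alphabet:
        lut.setdefault(s, s)
    overlap = np.zeros((n_monomers, len(alphabet)), dtype=np.float64)
    sub = annotation.intervals[annotation.intervals["chrom"] == chrom]
    for s0, e0, lab in zip(sub["start"], sub["end"], sub["state"]):
        if lab not in lut:
            raise ValueError(f"unknown state label {lab!r}")
        k = alphabet.index(lut[lab])
        lo, hi = max(s0, start), min(e0, end)
        if hi <= lo:
            continue
        m_lo, m_hi = (lo - start) // nu, (hi - 1 - start) // nu
        for m in range(m_lo, m_hi + 1):
            bin_lo = start + m * nu
            overlap[m, k] += min(hi, bin_lo + nu) - max(lo, bin_lo)
    states = overlap.argmax(axis=1)
    uncovered = overlap.sum(axis=1) == 0
    if uncovered.any():
        import warnings

        warnings.warn(
            f"{int(uncovered.sum())} monomers uncovered; assigned "
            f"{default_state!r}"
        )
        states[uncovered] = alphabet.index(default_state)
    return states.astype(np.int8)


def synthetic_epigenome(
    n_monomers: int,
    mean_domain_len: float,
    state_freqs: dict[str, float] | None = None,
    seed: int = 0,
    nu: int = 10_000,
    chrom: str = "chrSim",
) -> EpigenomeAnnotation:
    """Synthetic block epigenome emulating the fly four-state annotation.

    Domains alternate states (never two consecutive domains of the same
    state, picked uniformly among the other states) with geometric lengths.
    State ``i`` gets mean domain length ``K * p_i * mean_domain_len``
    (K = number of states), which makes the per-monomer state frequencies
    equal to ``p_i`` in expectation while the overall mean domain length is
    ``mean_domain_len`` — and gives the prevalent state the longest
    domains, as observed for black chromatin.

    Parameters
    ----------
    n_monomers : int
        Total monomers; intervals are emitted in bp on a nu-bp grid.
    mean_domain_len : float
        Target mean domain length, monomers.
    state_freqs : dict state -> frequency, summing to 1.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if mean_domain_len < 1:
        raise ValueError("mean_domain_len must be >= 1")
    freqs = dict(DEFAULT_STATE_FREQS if state_freqs is None else state_freqs)
    labels = [s for s, p in freqs.items() if p > 0]
    p = np.array([freqs[s] for s in labels])
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("state frequencies must sum to 1")
    if np.any(p <= 0):
        raise ValueError("degenerate state frequencies")
    rng = np.random.default_rng(seed)
    K = len(labels)
    if K == 1:
        df = pd.DataFrame(
            [(chrom, 0, n_monomers * nu, labels[0])],
            columns=["chrom", "start", "end", "state"],
        )
        return EpigenomeAnnotation(intervals=df, state_alphabet=tuple(STATE_ALPHABET))
    rows = []
    pos = 0
    prev = -1
    while pos < n_monomers:
        if K == 1:
            k = 0
        else:
            choices = [j for j in range(K) if j != prev]
            k = choices[int(rng.integers(K - 1))]
        mean_k = max(K * p[k] * mean_domain_len, 1.0)
        length = int(rng.geometric(1.0 / mean_k))
        length = min(length, n_monomers - pos)
        rows.append((chrom, pos * nu, (pos + length) * nu, labels[k]))
        pos += length
        prev = k
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return EpigenomeAnnotation(intervals=df, state_alphabet=tuple(STATE_ALPHABET))


@dataclass
class ContactMap:
    """Symmetric contact-frequency matrix over monomer bins."""

    matrix: np.ndarray
    bin_size_bp: float
    window: tuple[float, float] | None = None
    dc: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if np.nanmin(m) < 0:
            raise ValueError("matrix must be non-negative")
        self.matrix = m

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter="\t")

    def to_triplets(self, path) -> None:
        i, j = np.nonzero(np.triu(self.matrix))
        pd.DataFrame({"bin_i": i, "bin_j": j, "value": self.matrix[i, j]}).to_csv(
            path, sep="\t", index=False
        )


def _window_indices(traj: Trajectory, window, max_snapshots):
    if window is None:
        idx = np.arange(traj.n_snapshots)
    else:
        lo, hi = window
        idx = np.nonzero((traj.mcs >= lo) & (traj.mcs <= hi))[0]
        if idx.size == 0:
            raise ValueError(f"no snapshots inside window {window}")
    return idx[:: max(1, idx.size // max_snapshots)]


def contact_map(
    trajs: Sequence[Trajectory],
    dc: float,
    window: tuple[float, float] | None = None,
    bin_size: int = 1,
    nu: float = 1.0,
    max_snapshots: int = 400,
) -> ContactMap:
    """Average contact map over a time window and replicas.

    Entry (I, J) is the mean over snapshots of the fraction of monomer
    pairs between bins I and J whose unfolded 3D distance is < dc (strict).
    With bin_size = 1 the diagonal is 1 (a monomer always contacts itself).
    """
    if dc <= 0:
        raise ValueError("dc must be positive")
    N = trajs[0].n_monomers
    n_bins = -(-N // bin_size)
    counts = np.zeros((n_bins, n_bins))
    n_snap = 0
    # strict inequality: shrink the KD-tree radius below the next lattice shell
    radius = dc * (1.0 - 1e-9)
    bins = np.arange(N) // bin_size
    for traj in trajs:
        coords = traj.positions_nm()
        for t in _window_indices(traj, window, max_snapshots):
            pairs = cKDTree(coords[t]).query_pairs(radius, output_type="ndarray")
            n_snap += 1
            if pairs.size == 0:
                continue
            bi, bj = bins[pairs[:, 0]], bins[pairs[:, 1]]
            np.add.at(counts, (bi, bj), 1.0)
            np.add.at(counts, (bj, bi), 1.0)
    # self-pairs (distance 0 < dc) on the diagonal
    np.add.at(counts, (bins, bins), float(n_snap))
    per_bin = np.bincount(bins, minlength=n_bins).astype(np.float64)
    norm = np.outer(per_bin, per_bin)
    freq = counts / (norm * max(n_snap, 1))
    return ContactMap(
        matrix=freq, bin_size_bp=bin_size * nu, window=window, dc=dc
    )


def _contacts_by_separation(coords, dc, seps):
    """Boolean contact arrays {s: (n_snap, N-s)} for requested separations."""
    out = {}
    for s in seps:
        d = coords[:, s:, :] - coords[:, :-s, :]
        out[s] = np.sum(d * d, axis=-1) < dc * dc
    return out


def pc_by_state(
    trajs: Sequence[Trajectory],
    dc: float,
    states: np.ndarray,
    window: tuple[float, float] | None = None,
    separations: Sequence[int] | None = None,
    nu: float | None = None,
    max_snapshots: int = 300,
) -> tuple[ObservableSeries, ObservableSeries, ObservableSeries]:
    """Sequence-average, intra-state and inter-state contact probabilities.

    Returns (Pc, P_intra, P_inter) on a common separation grid; a
    separation with no same-state (or no different-state) pairs is masked
    (NaN).  The pair-count-weighted average of P_intra and P_inter equals
    Pc identically.
    """
    states = np.asarray(states)
    N = trajs[0].n_monomers
    if states.shape[0] != N:
        raise ValueError("states length must match the chain")
    if separations is None:
        separations = np.unique(
            np.round(np.logspace(0, math.log10(N - 1), 40)).astype(int)
        )
    seps = np.asarray(sorted(set(int(s) for s in separations if 1 <= s < N)))
    tot = np.zeros((3, seps.size))  # contact sums: all, intra, inter
    cnt = np.zeros((3, seps.size))
    for traj in trajs:
        coords = traj.positions_nm()
        idx = _window_indices(traj, window, max_snapshots)
        coords = coords[idx]
        for si, s in enumerate(seps):
            d = coords[:, s:, :] - coords[:, :-s, :]
            hit = np.sum(d * d, axis=-1) < dc * dc
            same = states[s:] == states[:-s]
            tot[0, si] += hit.sum()
            cnt[0, si] += hit.size
            tot[1, si] += hit[:, same].sum()
            cnt[1, si] += hit[:, same].size
            tot[2, si] += hit[:, ~same].sum()
            cnt[2, si] += hit[:, ~same].size
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    scale = float(nu) if nu else 1.0
    out = []
    for row, label in zip(vals, ("Pc", "P_intra", "P_inter")):
        out.append(
            ObservableSeries(
                abscissa=seps * scale,
                values=row,
                stderr=np.zeros(seps.size),
                n_samples=cnt[0],
                label=label,
            )
        )
    return tuple(out)


DEFAULT_BANDS_BP = ((10_000, 100_000), (100_000, 1_000_000), (1_000_000, 10_000_000))


def ratio_timecourse(
    trajs: Sequence[Trajectory],
    dc: float,
    states: np.ndarray,
    nu: float,
    distance_bands: Sequence[tuple[float, float]] = DEFAULT_BANDS_BP,
    max_times: int = 200,
) -> pd.DataFrame:
    """Time evolution of P_intra/Pc and P_inter/Pc per genomic-distance band.

    For every recorded time the ratios are formed from ensemble contact
    fractions pooled over the band's separations (in bp) and all replicas.
    Returns a tidy DataFrame with columns (time, band_lo, band_hi,
    intra_over_pc, inter_over_pc).
    """
    states = np.asarray(states)
    N = trajs[0].n_monomers
    n_snap = min(t.n_snapshots for t in trajs)
    t_idx = np.arange(n_snap)[:: max(1, n_snap // max_times)]
    bands_mono = []
    for lo, hi in distance_bands:
        s_lo, s_hi = max(1, int(round(lo / nu))), min(N - 1, int(round(hi / nu)))
        if s_lo > s_hi:
            raise ValueError(f"band ({lo}, {hi}) holds no separations at nu={nu}")
        bands_mono.append((s_lo, s_hi))
    rows = []
    acc = {}  # (band, time) -> [all_hits, all_n, intra_hits, intra_n, inter_hits, inter_n]
    for traj in trajs:
        coords = traj.positions_nm()
        for bi, (s_lo, s_hi) in enumerate(bands_mono):
            for s in range(s_lo, s_hi + 1):
                same = states[s:] == states[:-s]
                d = coords[t_idx, s:, :] - coords[t_idx, :-s, :]
                hit = np.sum(d * d, axis=-1) < dc * dc
                a = acc.setdefault(bi, np.zeros((6, t_idx.size)))
                a[0] += hit.sum(axis=1)
                a[1] += hit.shape[1]
                a[2] += hit[:, same].sum(axis=1)
                a[3] += same.sum()
                a[4] += hit[:, ~same].sum(axis=1)
                a[5] += (~same).sum()
    mcs = trajs[0].mcs[t_idx]
    for bi, (lo, hi) in enumerate(distance_bands):
        a = acc[bi]
        with np.errstate(invalid="ignore", divide="ignore"):
            pc = a[0] / a[1]
            intra = np.where(a[3] > 0, a[2] / np.maximum(a[3], 1), np.nan)
            inter = np.where(a[5] > 0, a[4] / np.maximum(a[5], 1), np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "time": mcs,
                        "band_lo": lo,
                        "band_hi": hi,
                        "intra_over_pc": intra / pc,
                        "inter_over_pc": inter / pc,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


@dataclass
class ContactKinetics:
    """First-encounter, contact and search times of one locus pair.

    ``tau_first`` is None when the pair never meets within the series
    (censored); durations share the time unit of the input series.
    """

    tau_first: float | None
    tau_c: list[float]
    tau_s: list[float]
    threshold: float
    censored: bool
    span: float
    trailing: float = 0.0

    @property
    def censored_fraction(self) -> float:
        return 1.0 if self.censored else 0.0


def pair_kinetics(
    distance_series: np.ndarray, threshold: float, dt: float = 1.0
) -> ContactKinetics:
    """Contact kinetics of a regularly sampled pair-distance series.

    A sample is "in contact" when distance < threshold.  ``tau_first`` is
    the time of the first in-contact sample, ``tau_c`` the lengths of the
    maximal in-contact runs, ``tau_s`` the gaps between consecutive runs.
    The identity tau_first + sum(tau_c) + sum(tau_s) + trailing = span
    holds exactly (span = n_samples * dt).
    """
    d = np.asarray(distance_series, dtype=np.float64)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("distance_series must be a non-empty 1-D array")
    below = d < threshold
    span = d.size * dt
    if not below.any():
        return ContactKinetics(
            tau_first=None,
            tau_c=[],
            tau_s=[],
            threshold=threshold,
            censored=True,
            span=span,
            trailing=span,
        )
    edges = np.diff(below.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [d.size]])
    tau_first = float(starts[0]) * dt
    tau_c = [(e - s) * dt for s, e in zip(starts, ends)]
    tau_s = [(s - e) * dt for e, s in zip(ends[:-1], starts[1:])]
    trailing = (d.size - ends[-1]) * dt
    return ContactKinetics(
        tau_first=tau_first,
        tau_c=tau_c,
        tau_s=tau_s,
        threshold=threshold,
        censored=False,
        span=span,
        trailing=trailing,
    )


def pair_distance_series(
    traj: Trajectory, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """(times, unfolded distances in nm) between monomers i and j."""
    coords = traj.positions_nm()
    d = np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=-1)
    return traj.times(), d


def default_kinetics_threshold(b: float) -> float:
    """Default pair-contact threshold 2*sqrt(2)*b (325 nm at b = 115.3 nm)."""
    return 2.0 * math.sqrt(2.0) * b


def map_correlation(
    map_a: ContactMap, map_b: ContactMap, min_offset: int = 1
) -> float:
    """Pearson correlation of two maps over matched upper-triangle entries.

    Entries within ``min_offset`` of the diagonal are excluded; entries
    NaN in either map are dropped.
    """
    a, b = map_a.matrix, map_b.matrix
    if a.shape != b.shape or map_a.bin_size_bp != map_b.bin_size_bp:
        raise ValueError("maps must share the same bin grid")
    iu = np.triu_indices_from(a, k=min_offset)
    av, bv = a[iu], b[iu]
    ok = np.isfinite(av) & np.isfinite(bv)
    if ok.sum() < 3:
        raise ValueError("too few matched entries")
    return float(stats.pearsonr(av[ok], bv[ok])[0])
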