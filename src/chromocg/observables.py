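"""Structural and dynamical measurements on KMC trajectories.

All observables work on *unfolded* coordinates (nm): mean squared
displacements of monomers (g1) and of the chain center of mass (g3) as
functions of lag time, moments of the inter-monomer distance R(s) at
genomic separation s, the contact probability Pc(s), power-law fits on
declared windows, and the MCS -> seconds time mapping obtained by matching
g1 to the experimentally typical amplitude 0.01 um^2 s^-1/2.

Ensemble errors are standard deviations of the mean across replicas
(per-replica blocking); overlapping time origins within a replica are
averaged for statistics and their correlation is absorbed by the
replica-level error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .engine import Trajectory

__all__ = [
    "ObservableSeries",
    "TimeMapping",
    "PowerLawFit",
    "msd_monomer",
    "msd_com",
    "distance_moments",
    "contact_probability",
    "fit_power_law",
    "time_map",
    "default_contact_threshold",
    "intermediate_time_window",
]

#: Experimentally typical monomer MSD amplitude, um^2 at t in seconds**0.5.
REFERENCE_G1_AMPLITUDE = 0.01


@dataclass
class ObservableSeries:
    """A measured curve with ensemble errors.

    ``abscissa`` is a lag time (MCS or s) or genomic separation (monomers
    or bp), strictly increasing; ``stderr`` is the standard deviation of
    the ensemble mean (0 where only one replica contributes).
    """

    abscissa: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    n_samples: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.stderr = np.asarray(self.stderr, dtype=np.float64)
        self.n_samples = np.asarray(self.n_samples)
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(self.stderr < 0):
            raise ValueError("stderr must be >= 0")


@dataclass
class TimeMapping:
    """Seconds per MCS from the g1 amplitude calibration."""

    sec_per_mcs: float
    reference_amplitude: float
    fit_window: tuple[float, float]
    local_exponent: float  # measured log-log slope inside the window

    def __post_init__(self) -> None:
        if self.sec_per_mcs <= 0:
            raise ValueError("sec_per_mcs must be positive")


@dataclass
class PowerLawFit:
    exponent: float
    amplitude: float
    stderr: float
    window: tuple[float, float]
    n_points: int


def default_contact_threshold(b: float) -> float:
    """Default contact distance: sqrt(2) * b, the fcc cubic-cell edge.

    At the 10-kbp coarse-graining of the fly model (b = 115.3 nm) this
    evaluates to the 163 nm threshold used for coarse-grained contact maps;
    it generalizes across coarse-graining levels.  The finest-scale
    (nucleosomal) reference instead uses a fixed 55 nm (~ its Kuhn length).
    """
    return math.sqrt(2.0) * b


def _default_lags(n_snap: int, n_lags: int) -> np.ndarray:
    lags = np.unique(
        np.round(np.logspace(0, math.log10(max(n_snap - 1, 1)), n_lags)).astype(int)
    )
    return lags[lags >= 1]


def _msd(
    trajs: Sequence[Trajectory],
    lags: np.ndarray | None,
    com: bool,
    max_origins: int,
    n_lags: int,
) -> ObservableSeries:
    if not trajs:
        raise ValueError("need at least one trajectory")
    n_snap = min(t.n_snapshots for t in trajs)
    if n_snap < 2:
        raise ValueError("trajectories too short for any lag")
    dt_mcs = float(trajs[0].mcs[1] - trajs[0].mcs[0])
    if lags is None:
        lag_idx = _default_lags(n_snap, n_lags)
    else:
        lag_idx = np.unique(np.round(np.asarray(lags) / dt_mcs).astype(int))
        dropped = lag_idx[(lag_idx < 1) | (lag_idx >= n_snap)]
        if dropped.size:
            import warnings

            warnings.warn(f"dropping {dropped.size} lags outside the span")
        lag_idx = lag_idx[(lag_idx >= 1) & (lag_idx < n_snap)]
    per_replica = np.empty((len(trajs), lag_idx.size))
    for r, traj in enumerate(trajs):
        coords = traj.positions_nm()[:n_snap]
        if com:
            coords = coords.mean(axis=1, keepdims=True)
        for li, lag in enumerate(lag_idx):
            stride = max(1, (n_snap - lag) // max_origins)
            d = coords[lag::stride][: (n_snap - lag - 1) // stride + 1] - coords[
                :-lag:stride
            ][: (n_snap - lag - 1) // stride + 1]
            per_replica[r, li] = np.mean(np.sum(d * d, axis=-1))
    mean = per_replica.mean(axis=0)
    if len(trajs) > 1:
        err = per_replica.std(axis=0, ddof=1) / math.sqrt(len(trajs))
    else:
        err = np.zeros_like(mean)
    return ObservableSeries(
        abscissa=lag_idx * dt_mcs,
        values=mean,
        stderr=err,
        n_samples=np.full(lag_idx.size, len(trajs)),
        label="g3" if com else "g1",
    )


def msd_monomer(
    trajs: Sequence[Trajectory],
    lags: np.ndarray | None = None,
    max_origins: int = 500,
    n_lags: int = 60,
) -> ObservableSeries:
    """g1(t): MSD of individual monomers, nm^2 vs lag in MCS.

    Averages over monomers, snapshot-grid time origins (up to
    ``max_origins`` per lag) and replicas.  ``lags`` in MCS (defaults to a
    log-spaced grid on the snapshot cadence); lags beyond the trajectory
    span are dropped with a warning.
    """
    return _msd(trajs, lags, com=False, max_origins=max_origins, n_lags=n_lags)


def msd_com(
    trajs: Sequence[Trajectory],
    lags: np.ndarray | None = None,
    max_origins: int = 500,
    n_lags: int = 60,
) -> ObservableSeries:
    """g3(t): MSD of the chain center of mass, nm^2 vs lag in MCS."""
    return _msd(trajs, lags, com=True, max_origins=max_origins, n_lags=n_lags)


def _window_slice(traj: Trajectory, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.arange(traj.n_snapshots)
    lo, hi = window
    idx = np.nonzero((traj.mcs >= lo) & (traj.mcs <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"no snapshots inside window {window}")
    return idx


def distance_moments(
    trajs: Sequence[Trajectory],
    window: tuple[float, float] | None = None,
    separations: Sequence[int] | None = None,
    nu: float | None = None,
    max_snapshots: int = 500,
) -> tuple[ObservableSeries, ObservableSeries]:
    """<R^2(s)> and sigma^2(s) = <R^4(s)> - <R^2(s)>^2 at separations s.

    ``separations`` are in monomers; the abscissa is converted to bp when
    ``nu`` (bp per monomer) is given.  ``window`` restricts snapshots to an
    MCS interval; snapshots are subsampled to at most ``max_snapshots``.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    N = trajs[0].n_monomers
    if separations is None:
        separations = np.unique(
            np.round(np.logspace(0, math.log10(N - 1), 40)).astype(int)
        )
    seps = np.asarray(sorted(set(int(s) for s in separations)))
    if np.any(seps < 0) or np.any(seps >= N):
        raise ValueError("separations must lie in [0, N)")
    r2 = np.empty((len(trajs), seps.size))
    r4 = np.empty((len(trajs), seps.size))
    for r, traj in enumerate(trajs):
        idx = _window_slice(traj, window)
        idx = idx[:: max(1, idx.size // max_snapshots)]
        coords = traj.positions_nm()[idx]
        for si, s in enumerate(seps):
            if s == 0:
                r2[r, si] = 0.0
                r4[r, si] = 0.0
                continue
            d = coords[:, s:, :] - coords[:, :-s, :]
            q = np.sum(d * d, axis=-1)
            r2[r, si] = q.mean()
            r4[r, si] = (q * q).mean()
    scale = float(nu) if nu else 1.0
    mean_r2 = r2.mean(axis=0)
    var = r4.mean(axis=0) - mean_r2**2
    nrep = len(trajs)
    err2 = r2.std(axis=0, ddof=1) / math.sqrt(nrep) if nrep > 1 else np.zeros_like(mean_r2)
    series_r2 = ObservableSeries(
        abscissa=seps * scale,
        values=mean_r2,
        stderr=err2,
        n_samples=np.full(seps.size, nrep),
        label="R2",
    )
    series_var = ObservableSeries(
        abscissa=series_r2.abscissa.copy(),
        values=var,
        stderr=np.zeros_like(var),
        n_samples=np.full(seps.size, nrep),
        label="sigma2",
    )
    return series_r2, series_var


def contact_probability(
    trajs: Sequence[Trajectory],
    dc: float,
    window: tuple[float, float] | None = None,
    separations: Sequence[int] | None = None,
    nu: float | None = None,
    max_snapshots: int = 500,
) -> ObservableSeries:
    """Pc(s): fraction of monomer pairs at separation s closer than dc (nm).

    The contact criterion is a strict inequality (distance < dc); Pc(0) = 1
    by definition.
    """
    if dc <= 0:
        raise ValueError("dc must be positive")
    if not trajs:
        raise ValueError("need at least one trajectory")
    N = trajs[0].n_monomers
    if separations is None:
        separations = np.unique(
            np.round(np.logspace(0, math.log10(N - 1), 40)).astype(int)
        )
    seps = np.asarray(sorted(set(int(s) for s in separations)))
    pc = np.empty((len(trajs), seps.size))
    for r, traj in enumerate(trajs):
        idx = _window_slice(traj, window)
        idx = idx[:: max(1, idx.size // max_snapshots)]
        coords = traj.positions_nm()[idx]
        for si, s in enumerate(seps):
            if s == 0:
                pc[r, si] = 1.0
                continue
            d = coords[:, s:, :] - coords[:, :-s, :]
            q = np.sum(d * d, axis=-1)
            pc[r, si] = np.mean(q < dc * dc)
    mean = pc.mean(axis=0)
    nrep = len(trajs)
    err = pc.std(axis=0, ddof=1) / math.sqrt(nrep) if nrep > 1 else np.zeros_like(mean)
    scale = float(nu) if nu else 1.0
    return ObservableSeries(
        abscissa=seps * scale,
        values=mean,
        stderr=err,
        n_samples=np.full(seps.size, nrep),
        label="Pc",
    )


def fit_power_law(
    series: ObservableSeries, fit_range: tuple[float, float]
) -> PowerLawFit:
    """Least-squares power law on log-log coordinates inside ``fit_range``."""
    lo, hi = fit_range
    mask = (
        (series.abscissa >= lo)
        & (series.abscissa <= hi)
        & (series.abscissa > 0)
        & np.isfinite(series.values)
    )
    if np.any(series.values[mask] <= 0):
        raise ValueError("nonpositive values inside the fit range")
    if mask.sum() < 5:
        raise ValueError(f"need >= 5 points in {fit_range}, have {int(mask.sum())}")
    res = stats.linregress(
        np.log10(series.abscissa[mask]), np.log10(series.values[mask])
    )
    return PowerLawFit(
        exponent=float(res.slope),
        amplitude=float(10**res.intercept),
        stderr=float(res.stderr),
        window=(lo, hi),
        n_points=int(mask.sum()),
    )


def intermediate_time_window(
    g1: ObservableSeries, lk_nm: float, re2_nm2: float
) -> tuple[float, float]:
    """Fit window for the intermediate-time (Rouse-like) g1 regime.

    Lower edge: first lag with g1 >= lk^2 (the chain has equilibrated at
    the Kuhn scale); upper edge: last lag with g1 <= Re^2/6 (~ the squared
    gyration radius, a Rouse-time estimate).  Raises if the window spans
    less than half a decade.
    """
    lo_candidates = g1.abscissa[g1.values >= lk_nm**2]
    hi_candidates = g1.abscissa[g1.values <= re2_nm2 / 6.0]
    if lo_candidates.size == 0 or hi_candidates.size == 0:
        raise ValueError("g1 does not bracket the intermediate regime")
    lo, hi = float(lo_candidates[0]), float(hi_candidates[-1])
    if hi / lo < math.sqrt(10.0):
        raise ValueError(
            f"intermediate window [{lo:g}, {hi:g}] narrower than half a decade"
        )
    return lo, hi


def structure_fit_window(
    kuhn_ratio: float, b_nm: float, box_edge_nm: float
) -> tuple[float, float]:
    """Separation window (monomers) for fitting structural scaling laws:
    from a few Kuhn segments to the box-crossing scale.

    Lower edge: s_lo = max(8, 4 * lk/b) — below a few Kuhn segments the
    correlation hole and lattice discreteness steepen Pc(s) beyond its
    asymptotic law (the same reason the g1 window starts at the Kuhn
    scale).  Upper edge: the separation whose ideal-chain extent reaches
    the box edge, s_box = box_edge^2 / ((12/13) (lk/b) b^2) — beyond it
    periodic-image artifacts and vanishing contact counts corrupt the
    tail — capped at 10 * s_lo (one decade).  Both edges are closed
    forms, independent of the measured curves.  Raises if less than half
    a decade survives.
    """
    lo = max(8.0, 4.0 * kuhn_ratio)
    s_box = box_edge_nm**2 / ((12.0 / 13.0) * max(kuhn_ratio, 1.0) * b_nm**2)
    hi = min(10.0 * lo, s_box)
    if hi / lo < math.sqrt(10.0):
        raise ValueError(
            f"structure window [{lo:g}, {hi:g}] narrower than half a decade"
        )
    return lo, hi


def time_map(
    g1_series: ObservableSeries,
    fit_window: tuple[float, float],
    reference_amplitude: float = REFERENCE_G1_AMPLITUDE,
) -> TimeMapping:
    """Seconds per MCS by matching g1 to ``0.01 (tau t)^0.5`` um^2.

    ``g1_series`` must be in nm^2 vs MCS.  The estimator minimizes
    sum_log-t [log g1 - log(A (tau t)^0.5)]^2 over tau, which equals an
    amplitude match at the geometric midpoint of the window; when the local
    exponent differs from 0.5 the result is reported with that exponent
    attached so the mismatch is visible.
    """
    lo, hi = fit_window
    mask = (g1_series.abscissa >= lo) & (g1_series.abscissa <= hi)
    if mask.sum() < 2:
        raise ValueError("fit window must contain at least two g1 points")
    t = g1_series.abscissa[mask]
    if t[-1] / t[0] < 10.0:
        raise ValueError("fit window must span at least one decade")
    g1_um2 = g1_series.values[mask] * 1e-6
    if np.any(g1_um2 <= 0):
        raise ValueError("g1 must be positive inside the window")
    # log tau* = mean of 2*(log g1 - log A - 0.5 log t)
    log_tau = np.mean(
        2.0 * (np.log10(g1_um2) - math.log10(reference_amplitude)) - np.log10(t)
    )
    slope = stats.linregress(np.log10(t), np.log10(g1_um2)).slope
    return TimeMapping(
        sec_per_mcs=float(10**log_tau),
        reference_amplitude=reference_amplitude,
        fit_window=(lo, hi),
        local_exponent=float(slope),
    )
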