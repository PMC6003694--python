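"""Closed-form physics of the coarse-graining calculus.

A chromosome is described at a fine scale as a semi-flexible self-avoiding
walk of beads of ``nu0`` bp and size ``b0`` nm with Kuhn length ``lk0``,
packed at a volumic density ``rho`` (bp/nm^3).  Its topological regime is
set by the ratio between the contour length and the entanglement length
``L_e``, estimated from the phenomenological melt relation

    L_e = l_k * (c / (rho_k * l_k^3))**2,      rho_k = (rho/nu) * (b/l_k),

with ``c ~ 19``.  Coarse-graining a factor ``n`` while conserving both
``L/L_e`` and the total volume on an fcc lattice (site volume b^3/sqrt(2))
fixes the coarse bond length and stiffness:

    b    = (sqrt(2) * n * Phi / rho_FS)**(1/3),     rho_FS = rho / nu0,
    lk/b = ((b0/Le0) * n * c^2 / Phi^2)**(1/3),

where the lattice volume fraction ``Phi`` is the control parameter.  The
bending rigidity ``kappa`` realizing a given lk/b on the fcc stored-length
chain follows from the exact 12-direction Boltzmann average of cos(theta)
with per-angle energy E(theta) = kappa*(1 - cos theta).

Note on calibration: evaluating the entanglement relation literally with
c = 19 and the reference fiber parameters underestimates the published
entanglement sizes by a constant factor ~1.6-1.8.  Presets therefore carry
an explicit calibrated ``ne0`` (bp) anchored at the preset density, and the
relation is used only for its rho**-2 scaling; presets without ``ne0`` fall
back to the raw relation with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ChromatinPreset",
    "CGParams",
    "EntanglementReport",
    "PRESETS",
    "UnreachableRigidityError",
    "nuclear_density",
    "entanglement",
    "naive_cg_phi_ratio",
    "solve_cg_geometry",
    "mean_cos_theta",
    "kuhn_ratio_from_kappa",
    "kappa_from_kuhn_ratio",
    "phantom_end_to_end",
    "build_cg_table",
]

#: Hard ceiling of lk/b on the fcc stored-length chain: (1 + 12/13)/(1 - 12/13).
KUHN_RATIO_CAP = 25.0


class UnreachableRigidityError(ValueError):
    """Requested stiffness exceeds what the fcc lattice chain can realize."""


@dataclass(frozen=True)
class ChromatinPreset:
    """Reference (fine-scale) fiber and density parameters for one system.

    Parameters
    ----------
    rho : float
        Chromatin volumic density, bp/nm^3.
    nu0 : float
        Fine-scale monomer content, bp.
    b0 : float
        Fine-scale bond length, nm.
    lk0 : float
        Fine-scale Kuhn length, nm.
    c : float
        Dimensionless entanglement constant (~19).
    ne0 : float or None
        Calibrated entanglement size in bp at density ``rho``.  If None,
        the raw entanglement relation is used (with a warning).
    """

    rho: float
    nu0: float = 200.0
    b0: float = 10.6
    lk0: float = 55.4
    c: float = 19.0
    ne0: float | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.nu0 <= 0 or self.b0 <= 0 or self.c <= 0:
            raise ValueError("rho, nu0, b0 and c must be positive")
        if self.lk0 < self.b0:
            raise ValueError("lk0 must be >= b0")
        if self.ne0 is not None and self.ne0 <= 0:
            raise ValueError("ne0 must be positive when given")

    @property
    def rho_fs(self) -> float:
        """Density in fine-scale monomers per nm^3."""
        return self.rho / self.nu0

    @property
    def nk0(self) -> float:
        """Fine-scale Kuhn size, bp."""
        return self.nu0 * self.lk0 / self.b0

    @property
    def phi0(self) -> float:
        """Fine-scale lattice volume fraction, rho_FS * b0^3 / sqrt(2).

        Cosmetic output only: the geometry solver works from ``rho_fs``
        directly.  The published fine-scale fractions (0.043 fly / 0.023
        yeast) imply b0 ~ 11.1 nm rather than the printed 10.6 nm; the
        small mismatch is reported as-is, not reconciled.
        """
        return self.rho_fs * self.b0**3 / math.sqrt(2.0)

    @property
    def le0(self) -> float | None:
        """Calibrated entanglement length, nm (None if uncalibrated)."""
        if self.ne0 is None:
            return None
        return self.ne0 * self.b0 / self.nu0


#: Calibrated presets: nucleosomal fiber (200 bp, b0=10.6 nm, lk0=55.4 nm)
#: at the typical density of each system, with the published entanglement
#: sizes as calibration anchors.
PRESETS: dict[str, ChromatinPreset] = {
    "yeast": ChromatinPreset(rho=0.005, ne0=920e3),
    "drosophila": ChromatinPreset(rho=0.009, ne0=285e3),
    "mammal": ChromatinPreset(rho=0.015, ne0=102e3),
}


@dataclass
class CGParams:
    """One coarse-graining level and its derived lattice parameters."""

    nu: float  # bp per CG monomer
    n: int  # CG factor nu/nu0
    phi: float  # lattice volume fraction
    b: float  # bond length, nm
    lk: float  # Kuhn length, nm
    kappa: float  # bending rigidity, kT
    nk: float  # Kuhn size, bp (= nu * lk / b)
    sec_per_mcs: float | None = None  # filled by the time mapping

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("n must be a positive integer")
        if not (0 < self.phi <= 2):
            raise ValueError("phi must lie in (0, 2]")
        if self.b <= 0:
            raise ValueError("b must be positive")
        ratio = self.lk / self.b
        if not (1.0 - 1e-9 <= ratio < KUHN_RATIO_CAP):
            raise ValueError(f"lk/b = {ratio:.3f} outside [1, {KUHN_RATIO_CAP})")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def with_time(self, sec_per_mcs: float) -> "CGParams":
        return replace(self, sec_per_mcs=sec_per_mcs)


@dataclass(frozen=True)
class EntanglementReport:
    """Entanglement scales of a chain at a given density."""

    le: float  # entanglement length, nm
    ne: float  # entanglement size, bp
    rho_k: float  # Kuhn-segment density, nm^-3
    ratio: float  # L / L_e
    calibrated: bool  # whether ne came from a calibrated anchor


def nuclear_density(
    genome_size: float,
    nuclear_volume: float | None = None,
    nuclear_diameter: float | None = None,
) -> float:
    """Chromatin volumic density: genome size over nuclear volume.

    Parameters
    ----------
    genome_size : float
        Genome content of the nucleus, bp.
    nuclear_volume : float, optional
        Nuclear volume in nm^3.  Exactly one of volume/diameter must be given.
    nuclear_diameter : float, optional
        Nuclear diameter in nm; implies a spherical volume (4/3) pi (d/2)^3.

    Returns
    -------
    float
        Density in bp/nm^3.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if (nuclear_volume is None) == (nuclear_diameter is None):
        raise ValueError("give exactly one of nuclear_volume or nuclear_diameter")
    if nuclear_volume is None:
        if nuclear_diameter <= 0:
            raise ValueError("nuclear_diameter must be positive")
        nuclear_volume = (4.0 / 3.0) * math.pi * (nuclear_diameter / 2.0) ** 3
    if nuclear_volume <= 0:
        raise ValueError("nuclear_volume must be positive")
    return genome_size / nuclear_volume


def _raw_entanglement_length(preset: ChromatinPreset, rho: float) -> float:
    """Uncalibrated L_e from the melt relation at density ``rho``."""
    rho_k = (rho / preset.nu0) * (preset.b0 / preset.lk0)
    denom = rho_k * preset.lk0**3
    if denom <= 0:
        raise ValueError("rho_k * lk0^3 must be positive")
    return preset.lk0 * (preset.c / denom) ** 2


def entanglement(
    preset: ChromatinPreset,
    chain_length: float,
    rho: float | None = None,
) -> EntanglementReport:
    """Entanglement length/size and the L/L_e ratio for a chain.

    If the preset carries a calibrated ``ne0``, the entanglement size at
    the query density is ``ne0 * (preset.rho / rho)**2`` (the rho**-2
    scaling of the melt relation at fixed fiber parameters); otherwise the
    raw relation is evaluated, with a warning about its normalization.

    Parameters
    ----------
    preset : ChromatinPreset
    chain_length : float
        Chain length in bp.
    rho : float, optional
        Query density, bp/nm^3 (defaults to the preset density).
    """
    if chain_length <= 0:
        raise ValueError("chain_length must be positive")
    if rho is None:
        rho = preset.rho
    if rho <= 0:
        raise ValueError("rho must be positive")
    rho_k = (rho / preset.nu0) * (preset.b0 / preset.lk0)
    if preset.ne0 is not None:
        ne = preset.ne0 * (preset.rho / rho) ** 2
        le = ne * preset.b0 / preset.nu0
        calibrated = True
    else:
        warnings.warn(
            "preset has no calibrated ne0; using the raw entanglement "
            "relation, whose normalization is uncertain to a factor ~2",
            stacklevel=2,
        )
        le = _raw_entanglement_length(preset, rho)
        ne = preset.nu0 * le / preset.b0
        calibrated = False
    return EntanglementReport(
        le=le, ne=ne, rho_k=rho_k, ratio=chain_length / ne, calibrated=calibrated
    )


def naive_cg_phi_ratio(n: float, stiffness_ratio: float) -> float:
    """Volume-fraction inflation Phi/Phi0 of the naive coarse-graining.

    The naive strategy (drop the rigidity, set the coarse bead size to the
    end-to-end distance of its fine-scale subchain) inflates the lattice
    volume fraction by n**(1/2) * (lk0/b0)**(3/2), which quickly exceeds 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if stiffness_ratio < 1:
        raise ValueError("stiffness_ratio must be >= 1")
    return math.sqrt(n) * stiffness_ratio**1.5


def solve_cg_geometry(
    preset: ChromatinPreset, n: int, phi: float
) -> tuple[float, float]:
    """Bond length and Kuhn length of the coarse-grained lattice chain.

    Conservation of the box volume on the fcc lattice (site volume
    b^3/sqrt(2), double occupancy allowed) gives
    ``b = (sqrt(2) n Phi / rho_FS)**(1/3)``; conservation of L/L_e gives
    ``lk/b = ((b0/Le0) n c^2 / Phi^2)**(1/3)``.

    Returns
    -------
    (b, lk) : tuple of float
        Bond length and Kuhn length, nm.

    Raises
    ------
    UnreachableRigidityError
        If the implied lk/b reaches the lattice cap of 25.
    """
    if n < 1 or int(n) != n:
        raise ValueError("n must be a positive integer")
    if not (0 < phi <= 2):
        raise ValueError("phi must lie in (0, 2]")
    if preset.le0 is None:
        raise ValueError("solve_cg_geometry requires a preset with calibrated ne0")
    b = (math.sqrt(2.0) * n * phi / preset.rho_fs) ** (1.0 / 3.0)
    ratio = ((preset.b0 / preset.le0) * n * preset.c**2 / phi**2) ** (1.0 / 3.0)
    if ratio >= KUHN_RATIO_CAP:
        raise UnreachableRigidityError(
            f"required lk/b = {ratio:.2f} >= {KUHN_RATIO_CAP} is not "
            "realizable on the fcc stored-length chain; increase phi or "
            "reduce the coarse-graining factor"
        )
    if ratio < 1.0:
        ratio = 1.0  # flexible limit: lattice chain cannot be softer
    return b, ratio * b


def mean_cos_theta(kappa: float) -> float:
    """Boltzmann average of cos(theta) over the 12 fcc bond directions.

    The successor of a bond on the fcc lattice makes an angle theta with
    cos(theta) in {1, 1/2, 0, -1/2, -1} with multiplicities {1, 4, 2, 4, 1};
    each choice is weighted by exp(-kappa*(1 - cos theta)).
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    e1 = math.exp(-kappa / 2.0)
    e2 = math.exp(-kappa)
    e3 = math.exp(-1.5 * kappa)
    e4 = math.exp(-2.0 * kappa)
    num = 1.0 + 2.0 * e1 - 2.0 * e3 - e4
    den = 1.0 + 4.0 * e1 + 2.0 * e2 + 4.0 * e3 + e4
    return num / den


def _x_of_kappa(kappa: float) -> float:
    return (12.0 / 13.0) * mean_cos_theta(kappa)


def kuhn_ratio_from_kappa(kappa: float) -> float:
    """lk/b of the fcc stored-length chain at bending rigidity ``kappa``.

    With x = (12/13)<cos theta>, the ratio is (1+x)/(1-x): 1 at kappa=0,
    approaching 25 as kappa -> infinity (x -> 12/13).
    """
    x = _x_of_kappa(kappa)
    return (1.0 + x) / (1.0 - x)


def kappa_from_kuhn_ratio(target: float) -> float:
    """Bending rigidity (kT) realizing a target lk/b; inverse of the above."""
    if not (1.0 <= target < KUHN_RATIO_CAP):
        raise UnreachableRigidityError(
            f"lk/b = {target} outside the realizable range [1, {KUHN_RATIO_CAP})"
        )
    if target == 1.0:
        return 0.0
    hi = 1.0
    while kuhn_ratio_from_kappa(hi) < target:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - target < 25 always brackets
            raise UnreachableRigidityError(f"cannot bracket lk/b = {target}")
    return brentq(
        lambda k: kuhn_ratio_from_kappa(k) - target, 0.0, hi, xtol=1e-13, rtol=1e-14
    )


def phantom_end_to_end(n_monomers: int, kappa: float, b: float) -> float:
    """Mean squared end-to-end distance of the phantom fcc stored-length chain.

    <Re^2> = (12/13) b^2 [ (N-1)(1+x)/(1-x) - 2x(1-x^(N-1))/(1-x)^2 ],
    with x = (12/13)<cos theta>.  The x -> 0 limit ((12/13) b^2 (N-1)) is
    taken analytically to avoid 0/0.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    n_bonds = n_monomers - 1
    if n_bonds == 0:
        return 0.0
    x = _x_of_kappa(kappa)
    pref = (12.0 / 13.0) * b * b
    if abs(x) < 1e-14:
        return pref * n_bonds
    return pref * (
        n_bonds * (1.0 + x) / (1.0 - x)
        - 2.0 * x * (1.0 - x**n_bonds) / (1.0 - x) ** 2
    )


def _phi_from_kuhn_ratio(preset: ChromatinPreset, n: int, ratio: float) -> float:
    """Invert the lk/b relation for Phi at fixed coarse-graining."""
    return math.sqrt((preset.b0 / preset.le0) * n * preset.c**2 / ratio**3)


def build_cg_table(
    preset: ChromatinPreset,
    resolutions: Sequence[float],
    phis: Sequence[float] | None = None,
    nks: Sequence[float] | None = None,
) -> list[CGParams]:
    """Coarse-graining parameter table (one row per requested level).

    Each row is specified by a resolution ``nu`` (bp per monomer) and either
    a lattice volume fraction ``phi`` or a Kuhn size ``nk`` (bp); in the
    latter case the Phi <-> N_k relation is inverted.  ``sec_per_mcs`` is
    left unset (filled later by the time mapping).
    """
    if (phis is None) == (nks is None):
        raise ValueError("give exactly one of phis or nks")
    knobs = phis if phis is not None else nks
    if len(knobs) != len(resolutions):
        raise ValueError("resolutions and phis/nks must have equal length")
    if preset.le0 is None:
        raise ValueError("build_cg_table requires a preset with calibrated ne0")
    rows: list[CGParams] = []
    for nu, knob in zip(resolutions, knobs):
        n = nu / preset.nu0
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError(f"nu = {nu} is not an integer multiple of nu0")
        n = int(round(n))
        if phis is not None:
            phi = float(knob)
        else:
            ratio = float(knob) / nu  # nk = nu * lk / b
            if not (1.0 <= ratio < KUHN_RATIO_CAP):
                raise UnreachableRigidityError(
                    f"nk = {knob} implies lk/b = {ratio:.2f} outside [1, 25)"
                )
            phi = _phi_from_kuhn_ratio(preset, n, ratio)
            if phi > 2:
                raise ValueError(
                    f"nk = {knob} at nu = {nu} needs phi = {phi:.2f} > 2"
                )
        b, lk = solve_cg_geometry(preset, n, phi)
        kappa = kappa_from_kuhn_ratio(min(lk / b, KUHN_RATIO_CAP - 1e-9))
        rows.append(
            CGParams(nu=nu, n=n, phi=phi, b=b, lk=lk, kappa=kappa, nk=nu * lk / b)
        )
    return rows


def cg_table_frame(rows: Sequence[CGParams]):
    """Tabulate CGParams rows as a pandas DataFrame (for the CLI / reports)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "CG_bp": [r.nu for r in rows],
            "phi": [r.phi for r in rows],
            "Nk_bp": [r.nk for r in rows],
            "b_nm": [r.b for r in rows],
            "lk_nm": [r.lk for r in rows],
            "kappa_kT": [r.kappa for r in rows],
            "sec_per_MCS": [r.sec_per_mcs for r in rows],
        }
    )
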