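"""Closed-form physics: density, entanglement, CG solver, stiffness maps."""

import math

import numpy as np
import pytest

from chromocg import cg_theory as cg
from chromocg.cg_theory import (
    PRESETS,
    ChromatinPreset,
    UnreachableRigidityError,
    build_cg_table,
    entanglement,
    kappa_from_kuhn_ratio,
    kuhn_ratio_from_kappa,
    mean_cos_theta,
    naive_cg_phi_ratio,
    nuclear_density,
    phantom_end_to_end,
    solve_cg_geometry,
)

# 12 fcc directions seen from a fixed previous bond: cos(theta) values and
# multiplicities, used as the brute-force Boltzmann enumeration oracle.
FCC_COS = np.array([1.0, 0.5, 0.0, -0.5, -1.0])
FCC_MULT = np.array([1, 4, 2, 4, 1])


def enumerated_mean_cos(kappa):
    w = FCC_MULT * np.exp(-kappa * (1.0 - FCC_COS))
    return float(np.sum(FCC_COS * w) / np.sum(w))


class TestNuclearDensity:
    @pytest.mark.parametrize(
        "genome, kwargs, expected, atol",
        [
            (6e9, {"nuclear_diameter": 9000.0}, 0.015, 1e-3),  # human-like
            (12.2e6, {"nuclear_volume": 2.6e9}, 0.005, 5e-4),  # haploid yeast
            (300e6, {"nuclear_diameter": 4000.0}, 0.009, 5e-4),  # fly embryo
        ],
    )
    def test_reference_densities(self, genome, kwargs, expected, atol):
        assert nuclear_density(genome, **kwargs) == pytest.approx(expected, abs=atol)

    def test_diameter_means_sphere(self):
        d = 1000.0
        v = 4.0 / 3.0 * math.pi * 500.0**3
        assert nuclear_density(1e6, nuclear_diameter=d) == pytest.approx(
            nuclear_density(1e6, nuclear_volume=v)
        )

    @pytest.mark.parametrize(
        "genome, kwargs",
        [
            (0.0, {"nuclear_volume": 1.0}),
            (1e6, {"nuclear_volume": -1.0}),
            (1e6, {}),
            (1e6, {"nuclear_volume": 1.0, "nuclear_diameter": 1.0}),
        ],
    )
    def test_invalid_arguments(self, genome, kwargs):
        with pytest.raises(ValueError):
            nuclear_density(genome, **kwargs)


class TestEntanglement:
    def test_yeast_value_from_fly_calibration(self):
        # same fiber, density scaled down to the yeast value
        rep = entanglement(PRESETS["drosophila"], 750e3, rho=0.005)
        assert rep.ne / 1e3 == pytest.approx(920, rel=0.01)

    def test_fly_ratio_at_20_mbp(self):
        rep = entanglement(PRESETS["drosophila"], 20e6)
        assert rep.ratio == pytest.approx(70.2, rel=0.01)

    def test_ratio_one_at_chain_equal_ne(self):
        ne = PRESETS["yeast"].ne0
        assert entanglement(PRESETS["yeast"], ne).ratio == pytest.approx(1.0)

    def test_rho_minus_two_scaling_exact(self):
        p = PRESETS["mammal"]
        r1 = entanglement(p, 1e6, rho=p.rho)
        r2 = entanglement(p, 1e6, rho=3.0 * p.rho)
        assert r1.ne / r2.ne == pytest.approx(9.0, rel=1e-12)

    def test_uncalibrated_preset_warns_and_scales(self):
        p = ChromatinPreset(rho=0.009)
        with pytest.warns(UserWarning, match="calibrated"):
            rep = entanglement(p, 1e6)
        assert rep.ne > 0 and not rep.calibrated
        with pytest.warns(UserWarning):
            rep2 = entanglement(p, 1e6, rho=0.018)
        assert rep.ne / rep2.ne == pytest.approx(4.0, rel=1e-12)

    def test_rho_k_definition(self):
        p = PRESETS["drosophila"]
        rep = entanglement(p, 1e6)
        assert rep.rho_k == pytest.approx((p.rho / p.nu0) * (p.b0 / p.lk0))


class TestNaivePhiRatio:
    @pytest.mark.parametrize(
        "n, ratio, expected", [(5, 5, 25.0), (1, 1, 1.0), (4, 1, 2.0)]
    )
    def test_values(self, n, ratio, expected):
        assert naive_cg_phi_ratio(n, ratio) == pytest.approx(expected)

    def test_agrees_with_volume_conservation_when_lk_equals_b(self):
        # naive CG bead size b = sqrt(n b0 lk0); pushing it through the
        # volume-conservation relation Phi = rho_FS b^3 / (sqrt(2) n) must
        # reproduce the same Phi inflation
        p = PRESETS["drosophila"]
        for n in (2, 5, 17):
            b_naive = math.sqrt(n * p.b0 * p.lk0)
            phi = (p.rho_fs / n) * b_naive**3 / math.sqrt(2.0)
            assert phi / p.phi0 == pytest.approx(
                naive_cg_phi_ratio(n, p.lk0 / p.b0), rel=1e-12
            )


class TestCgGeometry:
    @pytest.mark.parametrize(
        "n, phi, b_ref, lk_ref",
        [
            (50, 0.97, 115.3, 274.0),
            (10, 0.049, 24.9, 252.0),
            (25, 0.24, 57.6, 271.0),
            (10, 0.039, 23.1, 273.0),
        ],
    )
    def test_fly_table_rows(self, n, phi, b_ref, lk_ref):
        b, lk = solve_cg_geometry(PRESETS["drosophila"], n, phi)
        assert b == pytest.approx(b_ref, rel=0.015)
        assert lk == pytest.approx(lk_ref, rel=0.015)

    def test_phi_scaling_laws(self):
        # b ~ phi^(1/3) and lk/b ~ phi^(-2/3) at fixed n
        p = PRESETS["drosophila"]
        b1, lk1 = solve_cg_geometry(p, 50, 0.4)
        f = 1.7
        b2, lk2 = solve_cg_geometry(p, 50, 0.4 * f)
        assert b2 / b1 == pytest.approx(f ** (1 / 3), rel=1e-12)
        assert (lk2 / b2) / (lk1 / b1) == pytest.approx(f ** (-2 / 3), rel=1e-12)

    def test_reference_scale_self_consistency(self):
        # at n = 1 with Phi chosen by volume conservation the bond length
        # comes back exactly; the Kuhn length agrees only up to the known
        # normalization tension of the entanglement relation (~10%)
        p = PRESETS["drosophila"]
        phi_star = p.rho_fs * p.b0**3 / math.sqrt(2.0)
        b, lk = solve_cg_geometry(p, 1, phi_star)
        assert b == pytest.approx(p.b0, rel=1e-12)
        assert lk == pytest.approx(p.lk0, rel=0.10)

    def test_unreachable_rigidity(self):
        with pytest.raises(UnreachableRigidityError):
            solve_cg_geometry(PRESETS["drosophila"], 1000, 0.1)

    def test_requires_calibrated_preset(self):
        with pytest.raises(ValueError, match="ne0"):
            solve_cg_geometry(ChromatinPreset(rho=0.009), 10, 0.5)


class TestStiffnessMaps:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(kappa=st.floats(0.0, 50.0, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_closed_form_equals_enumeration_property(self, kappa):
        assert abs(mean_cos_theta(kappa) - enumerated_mean_cos(kappa)) < 1e-12

    @given(target=st.floats(1.0, 24.9, allow_nan=False))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_inverse_round_trip_property(self, target):
        assert kuhn_ratio_from_kappa(kappa_from_kuhn_ratio(target)) == pytest.approx(
            target, abs=1e-8
        )

    def test_closed_form_equals_enumeration(self):
        rng = np.random.default_rng(7)
        for kappa in rng.uniform(0.0, 20.0, size=50):
            assert abs(mean_cos_theta(kappa) - enumerated_mean_cos(kappa)) < 1e-12

    def test_limits(self):
        assert mean_cos_theta(0.0) == pytest.approx(0.0, abs=1e-15)
        assert mean_cos_theta(200.0) == pytest.approx(1.0, abs=1e-12)
        assert kuhn_ratio_from_kappa(0.0) == pytest.approx(1.0)
        assert kuhn_ratio_from_kappa(500.0) == pytest.approx(25.0, rel=1e-9)

    def test_negative_kappa_invalid(self):
        with pytest.raises(ValueError):
            mean_cos_theta(-0.1)

    def test_monotone_and_bounded(self):
        grid = np.linspace(0.0, 30.0, 200)
        vals = np.array([kuhn_ratio_from_kappa(k) for k in grid])
        assert np.all(np.diff(vals) > 0)
        assert vals[0] >= 1.0 and vals[-1] < 25.0

    def test_round_trip(self):
        for target in np.linspace(1.0, 24.5, 30):
            kappa = kappa_from_kuhn_ratio(target)
            assert kuhn_ratio_from_kappa(kappa) == pytest.approx(target, abs=1e-8)

    def test_cap_errors(self):
        with pytest.raises(UnreachableRigidityError):
            kappa_from_kuhn_ratio(25.0)
        with pytest.raises(UnreachableRigidityError):
            kappa_from_kuhn_ratio(0.5)


class TestPhantomChain:
    def test_single_monomer(self):
        assert phantom_end_to_end(1, 3.0, 2.0) == 0.0

    def test_flexible_limit_exact(self):
        # kappa = 0: freely jointed with stored length, <Re^2> = (12/13) b^2 (N-1)
        for n in (2, 10, 100):
            assert phantom_end_to_end(n, 0.0, 1.5) == pytest.approx(
                (12 / 13) * 1.5**2 * (n - 1), rel=1e-14
            )

    def test_large_n_slope(self):
        kappa = 2.0
        x = (12 / 13) * mean_cos_theta(kappa)
        slope = (
            phantom_end_to_end(20001, kappa, 1.0) - phantom_end_to_end(20000, kappa, 1.0)
        )
        assert slope == pytest.approx((12 / 13) * (1 + x) / (1 - x), rel=1e-6)

    def test_against_markov_sampling_oracle(self):
        # 13-state phantom chain: each bond is zero w.p. 1/13, otherwise a
        # direction drawn with Boltzmann weight relative to the last
        # non-zero bond (uniform after a zero); this chain realizes
        # <u_i.u_j> = (12/13) b^2 x^|i-j| exactly.
        from chromocg.lattice import NEIGHBOR_OFFSETS

        kappa, n_mono, n_samp = 2.0, 100, 100_000
        rng = np.random.default_rng(42)
        dirs = NEIGHBOR_OFFSETS.astype(float)
        cos = dirs @ dirs.T / 2.0
        W = np.exp(-kappa * (1.0 - cos))
        W /= W.sum(axis=1, keepdims=True)
        cum = np.cumsum(W, axis=1)
        state = np.full(n_samp, -1)  # -1: no remembered direction
        end = np.zeros((n_samp, 3))
        for _ in range(n_mono - 1):
            zero = rng.random(n_samp) < 1.0 / 13.0
            u = rng.random(n_samp)
            fresh = state < 0
            nxt = np.empty(n_samp, dtype=int)
            nxt[fresh] = rng.integers(0, 12, size=int(fresh.sum()))
            if (~fresh).any():
                rows = cum[state[~fresh]]
                nxt[~fresh] = (rows < u[~fresh, None]).sum(axis=1)
            step = np.where(zero[:, None], 0.0, dirs[nxt])
            end += step
            state = np.where(zero, -1, nxt)
        re2 = np.sum(end * end, axis=1) * 0.5  # grid units -> b^2 units
        pred = phantom_end_to_end(n_mono, kappa, 1.0)
        sem = re2.std(ddof=1) / math.sqrt(n_samp)
        assert abs(re2.mean() - pred) < 3 * sem


class TestCgTable:
    def test_fly_10kbp_row(self):
        rows = build_cg_table(PRESETS["drosophila"], [10_000], phis=[0.97])
        assert rows[0].nk / 1e3 == pytest.approx(23.8, rel=0.02)
        assert rows[0].sec_per_mcs is None

    def test_nk_phi_round_trip(self):
        rows = build_cg_table(PRESETS["drosophila"], [10_000], phis=[0.97])
        back = build_cg_table(PRESETS["drosophila"], [10_000], nks=[rows[0].nk])
        assert back[0].phi == pytest.approx(0.97, rel=1e-9)
        assert back[0].b == pytest.approx(rows[0].b, rel=1e-9)
        assert back[0].lk == pytest.approx(rows[0].lk, rel=1e-9)

    def test_kappa_consistent_with_ratio(self):
        rows = build_cg_table(
            PRESETS["drosophila"], [2000, 5000, 10_000], phis=[0.049, 0.24, 0.97]
        )
        for r in rows:
            assert kuhn_ratio_from_kappa(r.kappa) == pytest.approx(
                r.lk / r.b, abs=1e-8
            )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_cg_table(PRESETS["drosophila"], [2000], phis=[0.1, 0.2])
        with pytest.raises(ValueError):
            build_cg_table(PRESETS["drosophila"], [2000], phis=[0.1], nks=[2e4])
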