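"""Epigenome I/O, synthetic annotation, contact maps and kinetics."""

import numpy as np
import pandas as pd
import pytest

from chromocg.conformation import init_conformation
from chromocg.engine import EnergyModel, KmcConfig, run, run_replicas
from chromocg.epigenome import (
    STATE_ALPHABET,
    ContactMap,
    EpigenomeAnnotation,
    contact_map,
    load_epigenome,
    map_correlation,
    pair_kinetics,
    pc_by_state,
    ratio_timecourse,
    synthetic_epigenome,
)
from chromocg.lattice import FccLattice
from conftest import make_static_trajectory


class TestSyntheticEpigenome:
    def test_single_state_single_block(self):
        ann = synthetic_epigenome(100, 10, state_freqs={"black": 1.0}, seed=0)
        assert len(ann.intervals) == 1
        row = ann.intervals.iloc[0]
        assert (row["start"], row["end"], row["state"]) == (0, 100 * 10_000, "black")

    def test_mean_domain_length(self):
        ann = synthetic_epigenome(10_000, 10.0, seed=1, nu=1)
        lengths = (ann.intervals["end"] - ann.intervals["start"]).to_numpy()
        assert lengths.mean() == pytest.approx(10.0, rel=0.10)

    def test_state_frequencies_recovered(self):
        ann = synthetic_epigenome(100_000, 10.0, seed=2, nu=1)
        cover = ann.intervals.assign(
            length=ann.intervals["end"] - ann.intervals["start"]
        ).groupby("state")["length"].sum()
        freqs = (cover / cover.sum()).to_dict()
        from chromocg.epigenome import DEFAULT_STATE_FREQS

        for state, p in DEFAULT_STATE_FREQS.items():
            assert freqs[state] == pytest.approx(p, abs=0.02)

    def test_no_adjacent_same_state_domains(self):
        ann = synthetic_epigenome(5000, 5.0, seed=3, nu=1)
        states = ann.intervals["state"].to_numpy()
        assert np.all(states[1:] != states[:-1])

    def test_deterministic_per_seed(self):
        a = synthetic_epigenome(1000, 8.0, seed=7)
        b = synthetic_epigenome(1000, 8.0, seed=7)
        pd.testing.assert_frame_equal(a.intervals, b.intervals)

    def test_degenerate_freqs_rejected(self):
        with pytest.raises(ValueError):
            synthetic_epigenome(100, 10, state_freqs={"a": 0.5, "b": 0.4}, seed=0)


class TestLoadEpigenome:
    def test_uniform_interval(self):
        ann = EpigenomeAnnotation(
            pd.DataFrame(
                [{"chrom": "c", "start": 0, "end": 50_000, "state": "PcG"}]
            )
        )
        states = load_epigenome(ann, ("c", 0, 50_000), nu=10_000)
        assert states.tolist() == [STATE_ALPHABET.index("PcG")] * 5

    def test_majority_rule(self):
        ann = EpigenomeAnnotation(
            pd.DataFrame(
                [
                    {"chrom": "c", "start": 0, "end": 6000, "state": "active"},
                    {"chrom": "c", "start": 6000, "end": 10_000, "state": "HP1"},
                ]
            )
        )
        states = load_epigenome(ann, ("c", 0, 10_000), nu=10_000)
        assert states.tolist() == [STATE_ALPHABET.index("active")]

    def test_euchromatic_color_labels_merge_to_active(self):
        ann = EpigenomeAnnotation(
            pd.DataFrame(
                [
                    {"chrom": "c", "start": 0, "end": 10_000, "state": "YELLOW"},
                    {"chrom": "c", "start": 10_000, "end": 20_000, "state": "RED"},
                ]
            )
        )
        states = load_epigenome(ann, ("c", 0, 20_000), nu=10_000)
        assert states.tolist() == [0, 0]

    def test_uncovered_monomer_gets_default_with_warning(self):
        ann = EpigenomeAnnotation(
            pd.DataFrame([{"chrom": "c", "start": 0, "end": 10_000, "state": "HP1"}])
        )
        with pytest.warns(UserWarning, match="uncovered"):
            states = load_epigenome(ann, ("c", 0, 30_000), nu=10_000)
        assert states.tolist() == [1, 3, 3]

    def test_unknown_label_raises(self):
        ann = EpigenomeAnnotation(
            pd.DataFrame([{"chrom": "c", "start": 0, "end": 10_000, "state": "wat"}])
        )
        with pytest.raises(ValueError, match="unknown state"):
            load_epigenome(ann, ("c", 0, 10_000), nu=10_000)

    def test_bed_round_trip_reproduces_generator_truth(self, tmp_path):
        n, nu = 400, 10_000
        ann = synthetic_epigenome(n, 12.0, seed=5, nu=nu)
        path = tmp_path / "epi.bed"
        ann.to_bed(path)
        states = load_epigenome(str(path), ("chrSim", 0, n * nu), nu=nu)
        truth = np.empty(n, dtype=int)
        for _, row in ann.intervals.iterrows():
            truth[row["start"] // nu : row["end"] // nu] = STATE_ALPHABET.index(
                row["state"]
            )
        assert np.array_equal(states, truth)


class TestContactMap:
    def test_frozen_straight_chain_is_banded(self, small_lattice):
        conf = init_conformation("line", 8, small_lattice)
        traj = make_static_trajectory(small_lattice, conf.unfolded)
        cmap = contact_map([traj], dc=np.sqrt(2.0) * small_lattice.b)
        m = cmap.matrix
        assert np.allclose(np.diag(m), 1.0)
        # sqrt(2) b reaches only nearest-neighbor sites: off-diagonals > 1 empty
        assert np.allclose(m[np.abs(np.subtract.outer(range(8), range(8))) > 1], 0.0)
        assert np.all(np.diag(m, k=1) == 1.0)

    def test_window_union_is_weighted_average(self, small_lattice):
        rng = np.random.default_rng(0)
        conf = init_conformation("hedgehog", 30, small_lattice, seed=1)
        traj = run(conf, EnergyModel(), KmcConfig(n_mcs=400, snapshot_every=10, seed=2))
        dc = np.sqrt(2.0) * small_lattice.b
        m1 = contact_map([traj], dc=dc, window=(0, 190)).matrix
        m2 = contact_map([traj], dc=dc, window=(200, 400)).matrix
        m_all = contact_map([traj], dc=dc, window=(0, 400)).matrix
        w1, w2 = 20, 21  # snapshot counts in each window
        assert np.allclose(m_all, (w1 * m1 + w2 * m2) / (w1 + w2), atol=1e-12)

    def test_map_correlation_identities(self, rng):
        a = np.abs(rng.normal(size=(20, 20)))
        a = (a + a.T) / 2
        ca = ContactMap(matrix=a, bin_size_bp=1)
        assert map_correlation(ca, ca) == pytest.approx(1.0)
        flipped = ContactMap(matrix=a.max() - a, bin_size_bp=1)
        assert map_correlation(ca, flipped) == pytest.approx(-1.0)

    def test_independent_noise_maps_uncorrelated(self, rng):
        n = 60
        mats = []
        for _ in range(2):
            m = np.abs(rng.normal(size=(n, n)))
            mats.append(ContactMap(matrix=(m + m.T) / 2, bin_size_bp=1))
        r = map_correlation(*mats)
        n_entries = n * (n - 1) / 2
        assert abs(r) < 3.0 / np.sqrt(n_entries)

    def test_grid_mismatch_rejected(self, rng):
        a = np.eye(4)
        with pytest.raises(ValueError):
            map_correlation(
                ContactMap(matrix=a, bin_size_bp=1),
                ContactMap(matrix=np.eye(5), bin_size_bp=1),
            )


@pytest.fixture(scope="module")
def copolymer_ensembles():
    """Small 4-state block copolymer at E_i = 0 and E_i = -1."""
    n = 160
    lat = FccLattice(S=4)  # Phi ~ 0.6
    ann = synthetic_epigenome(n, 10.0, seed=4, nu=1)
    states = load_epigenome(ann, ("chrSim", 0, n), nu=1)
    out = {}
    for e_i in (0.0, -1.0):
        model = (
            EnergyModel.homotypic(kappa=0.0, e_i=e_i)
            if e_i
            else EnergyModel(kappa=0.0)
        )

        def gen(seed):
            conf = init_conformation("hedgehog", n, lat, seed=seed)
            conf.states = states
            return conf

        out[e_i] = run_replicas(
            gen, model, KmcConfig(n_mcs=30_000, snapshot_every=100, seed=11), 4
        )
    return states, lat, out


class TestCopolymerObservables:
    DC = np.sqrt(2.0)

    def test_counting_identity(self, copolymer_ensembles):
        states, lat, ens = copolymer_ensembles
        pc, p_intra, p_inter = pc_by_state(
            ens[-1.0], dc=self.DC, states=states, window=(15_000, 30_000)
        )
        n = len(states)
        for si, s in enumerate(pc.abscissa.astype(int)):
            same = int((states[s:] == states[:-s]).sum())
            diff = (n - s) - same
            mix = 0.0
            if same:
                mix += same * p_intra.values[si]
            if diff:
                mix += diff * p_inter.values[si]
            assert mix / (n - s) == pytest.approx(pc.values[si], abs=1e-12)

    def test_neutral_chain_has_no_state_contrast(self, copolymer_ensembles):
        states, lat, ens = copolymer_ensembles
        pc, p_intra, p_inter = pc_by_state(
            ens[0.0], dc=self.DC, states=states, window=(15_000, 30_000),
            separations=[2, 4, 8, 16, 32],
        )
        ok = np.isfinite(p_intra.values) & np.isfinite(p_inter.values)
        ratio = p_intra.values[ok] / p_inter.values[ok]
        assert np.all((ratio > 0.6) & (ratio < 1.6))

    def test_attraction_enriches_intra_and_depletes_inter(self, copolymer_ensembles):
        states, lat, ens = copolymer_ensembles
        seps = [4, 8, 16, 32, 64]
        pc, p_intra, p_inter = pc_by_state(
            ens[-1.0], dc=self.DC, states=states, window=(15_000, 30_000),
            separations=seps,
        )
        ok = np.isfinite(p_intra.values) & np.isfinite(p_inter.values) & (pc.values > 0)
        assert np.all(p_intra.values[ok] / pc.values[ok] > 1.0)
        assert np.all(p_inter.values[ok] / pc.values[ok] < 1.0)

    def test_block_diagonal_map_enrichment_vs_neutral(self, copolymer_ensembles):
        states, lat, ens = copolymer_ensembles
        same = np.equal.outer(states, states)
        off = np.abs(np.subtract.outer(np.arange(len(states)), np.arange(len(states)))) >= 2
        m_att = contact_map(ens[-1.0], dc=self.DC, window=(15_000, 30_000)).matrix
        m_neu = contact_map(ens[0.0], dc=self.DC, window=(15_000, 30_000)).matrix
        assert m_att[same & off].mean() > m_neu[same & off].mean()

    def test_intra_ratio_rises_from_homogeneous_start(self, copolymer_ensembles):
        states, lat, ens = copolymer_ensembles
        tc = ratio_timecourse(
            ens[-1.0], dc=self.DC, states=states, nu=1.0,
            distance_bands=[(2, 20)],
        )
        early = tc[tc["time"] <= 1000]["intra_over_pc"].mean()
        late = tc[tc["time"] >= 20_000]["intra_over_pc"].mean()
        assert late > early

    def test_slowing_down_with_attraction(self, copolymer_ensembles):
        from chromocg.observables import msd_monomer

        states, lat, ens = copolymer_ensembles
        lag = np.array([10_000.0])
        g1_neutral = msd_monomer(ens[0.0], lags=lag).values[0]
        g1_sticky = msd_monomer(ens[-1.0], lags=lag).values[0]
        assert g1_sticky < g1_neutral


class TestPairKinetics:
    def test_telegraph_signal_exact(self):
        d = np.array([5, 5, 1, 1, 1, 5, 5, 5, 1, 5, 1, 1], dtype=float)
        kin = pair_kinetics(d, threshold=2.0, dt=3.5)
        assert kin.tau_first == pytest.approx(2 * 3.5)
        assert kin.tau_c == [3 * 3.5, 1 * 3.5, 2 * 3.5]
        assert kin.tau_s == [3 * 3.5, 1 * 3.5]
        assert not kin.censored
        # duration-sum identity
        total = kin.tau_first + sum(kin.tau_c) + sum(kin.tau_s) + kin.trailing
        assert total == pytest.approx(kin.span)

    def test_always_below(self):
        kin = pair_kinetics(np.zeros(10), threshold=1.0, dt=2.0)
        assert kin.tau_first == 0.0
        assert kin.tau_c == [20.0]
        assert kin.tau_s == []

    def test_never_below_is_censored(self):
        kin = pair_kinetics(np.full(7, 9.0), threshold=1.0)
        assert kin.censored and kin.tau_first is None
        assert kin.tau_c == [] and kin.tau_s == []
        assert kin.censored_fraction == 1.0

    def test_identity_on_random_series(self, rng):
        d = rng.uniform(0, 2, size=500)
        kin = pair_kinetics(d, threshold=1.0, dt=0.5)
        total = kin.tau_first + sum(kin.tau_c) + sum(kin.tau_s) + kin.trailing
        assert total == pytest.approx(kin.span, abs=1e-9)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(bits=st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_duration_sum_identity_property(self, bits):
        d = np.where(np.array(bits), 0.0, 2.0)
        kin = pair_kinetics(d, threshold=1.0, dt=1.0)
        first = kin.tau_first if kin.tau_first is not None else 0.0
        total = first + sum(kin.tau_c) + sum(kin.tau_s) + kin.trailing
        assert total == pytest.approx(kin.span)
        assert len(kin.tau_s) == max(0, len(kin.tau_c) - 1)
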