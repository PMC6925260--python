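"""Generators: determinism, ground-truth consistency, validation."""

import math

import numpy as np
import pytest

from lbdens.constants import KB_KCAL_MOL_K as KB
from lbdens.synthetic import (
    BondSchedule,
    BoostSpec,
    LandscapeSpec,
    ResidueUptakeTruth,
    WellSpec,
    gen_amd_ensemble,
    gen_cest_profile,
    gen_hdx_dataset,
    gen_mini_protein_trajectory,
    gen_spectrum,
    gen_titration,
)


class TestGenAmdEnsemble:
    def test_fixed_seed_bit_identical(self, two_well_boosted_spec):
        a = gen_amd_ensemble(two_well_boosted_spec, 500, seed=42)
        b = gen_amd_ensemble(two_well_boosted_spec, 500, seed=42)
        np.testing.assert_array_equal(a.cv1, b.cv1)
        np.testing.assert_array_equal(a.cv2, b.cv2)
        np.testing.assert_array_equal(a.dv, b.dv)

    def test_single_well_unimodal_unbiased(self):
        spec = LandscapeSpec(wells=[WellSpec((2.0, 2.0), 0.0, (0.25, 0.25))])
        ens = gen_amd_ensemble(spec, 10_000, seed=0)
        assert (ens.dv == 0).all()
        assert ens.cv1.mean() == pytest.approx(2.0, abs=0.02)
        assert ens.cv1.std() == pytest.approx(0.25, rel=0.05)
        assert ens.cv2.std() == pytest.approx(0.25, rel=0.05)

    def test_unbiased_occupancy_matches_boltzmann_ratio(self, unbiased_ensemble):
        """Two wells 1 kcal/mol apart populate as exp(-1/kBT) within 3 SE."""
        ens = unbiased_ensemble
        d_deep = (ens.cv1 - 1) ** 2 + (ens.cv2 - 3) ** 2
        d_shallow = (ens.cv1 - 3) ** 2 + (ens.cv2 - 1) ** 2
        in_shallow = d_shallow < d_deep
        p = in_shallow.mean()
        expected = math.exp(-1.0 / (KB * 298.0))
        p_exp = expected / (1 + expected)
        se = math.sqrt(p_exp * (1 - p_exp) / len(ens))
        assert abs(p - p_exp) <= 3 * se

    def test_boost_positive_and_capped(self, boosted_ensemble):
        assert (boosted_ensemble.dv >= 0).all()
        assert boosted_ensemble.dv.max() <= BoostSpec().max_boost + 1e-9
        assert boosted_ensemble.dv.max() == pytest.approx(5.0, abs=0.05)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(wells=[]),
            dict(wells=[WellSpec((0, 0), 0.0, (0.0, 0.1))]),
            dict(wells=[WellSpec((0, 0), 1.0)]),  # no reference-depth well
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            LandscapeSpec(**bad)

    def test_zero_frames_rejected(self, two_well_spec):
        with pytest.raises(ValueError):
            gen_amd_ensemble(two_well_spec, 0, seed=0)


class TestGenMiniProteinTrajectory:
    def test_schedule_length_mismatch_rejected(self):
        sched = BondSchedule(pairs=[(3, 8)], states=[np.ones(4, bool)])
        with pytest.raises(ValueError, match="n_frames"):
            gen_mini_protein_trajectory(10, schedule=sched, n_frames=6)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            gen_mini_protein_trajectory(5, n_frames=2)

    def test_fixed_output_is_deterministic(self):
        sched = BondSchedule(pairs=[(3, 8)], states=[np.array([1, 0, 1], bool)])
        a = gen_mini_protein_trajectory(10, schedule=sched)
        b = gen_mini_protein_trajectory(10, schedule=sched)
        np.testing.assert_array_equal(a.xyz, b.xyz)

    def test_bonded_frames_meet_geometry(self):
        sched = BondSchedule(pairs=[(3, 8)], states=[np.array([1, 0], bool)])
        traj = gen_mini_protein_trajectory(10, schedule=sched)
        xyz = traj.xyz * 10.0  # angstrom
        names = {(a.residue.resSeq, a.name): a.index for a in traj.topology.atoms}
        nz, hz, oe = names[(3, "NZ")], names[(3, "HZ1")], names[(8, "OE1")]
        d_bond = np.linalg.norm(xyz[0, nz] - xyz[0, oe])
        d_free = np.linalg.norm(xyz[1, nz] - xyz[1, oe])
        assert d_bond == pytest.approx(2.9, abs=1e-6)
        assert d_free >= 4.5
        v1 = xyz[0, nz] - xyz[0, hz]
        v2 = xyz[0, oe] - xyz[0, hz]
        ang = math.degrees(
            math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        assert ang == pytest.approx(165.0, abs=0.1)


class TestGenSpectrum:
    def test_single_peak_integral(self):
        s = gen_spectrum([(-120.0, 47.0, 1.0, 0.0)], 0.0, 4096, (-140, -100),
                         470.0, seed=0)
        area = np.trapezoid(s.intensity[::-1], s.ppm[::-1])
        assert area == pytest.approx(1.0, rel=2e-3)

    def test_two_region_integrals_match_fractions(self):
        # widely separated peaks: per-region integrals recover 0.72/0.28
        s = gen_spectrum(
            [(-110.0, 47.0, 0.72, 0.0), (-130.0, 47.0, 0.28, 0.0)],
            0.0, 8192, (-150, -90), 470.0, seed=0,
        )
        x, y = s.ppm[::-1], s.intensity[::-1]
        left = x < -120
        a1 = np.trapezoid(y[~left], x[~left])
        a2 = np.trapezoid(y[left], x[left])
        assert a1 == pytest.approx(0.72, abs=0.005)
        assert a2 == pytest.approx(0.28, abs=0.005)

    def test_zero_peaks_pure_noise(self):
        s = gen_spectrum([], 0.5, 1024, (-125, -115), 470.0, seed=1)
        assert abs(s.intensity.mean()) < 5 * 0.5 / math.sqrt(1024)

    @pytest.mark.parametrize(
        "peaks,npoints,sweep",
        [
            ([(-120, 47.0, 0.9, 0.0)], 1024, (-125, -115)),  # fractions != 1
            ([(-120, -1.0, 1.0, 0.0)], 1024, (-125, -115)),  # bad width
            ([(-120, 47.0, 1.0, 0.0)], 32, (-125, -115)),  # too few points
            ([(-120, 47.0, 1.0, 0.0)], 1024, (-120, -120)),  # zero sweep
        ],
    )
    def test_invalid_inputs_rejected(self, peaks, npoints, sweep):
        with pytest.raises(ValueError):
            gen_spectrum(peaks, 0.0, npoints, sweep, 470.0, seed=0)

    def test_seeded_noise_reproducible(self):
        a = gen_spectrum([], 1.0, 128, (-125, -115), 470.0, seed=9)
        b = gen_spectrum([], 1.0, 128, (-125, -115), 470.0, seed=9)
        np.testing.assert_array_equal(a.intensity, b.intensity)


class TestGenCestProfile:
    def test_no_exchange_off_resonance_leaves_major_state(self):
        # saturating at the minor shift with kex = 0 attenuates the major
        # state only through direct off-resonance saturation; exchange
        # depletes it much further
        p = gen_cest_profile(0.0, (0.9, 0.1), (0.0, -200.0), 2.4, (30.0, 30.0),
                             [-200.0], [1.0], seed=0)
        q = gen_cest_profile(20.0, (0.9, 0.1), (0.0, -200.0), 2.4, (30.0, 30.0),
                             [-200.0], [1.0], seed=0)
        assert p.intensities[0] > 0.8
        assert q.intensities[0] < p.intensities[0] - 0.2

    def test_fast_exchange_long_saturation_depletes(self):
        p = gen_cest_profile(500.0, (0.9, 0.1), (0.0, -200.0), 2.4,
                             (30.0, 30.0), [-200.0], [3.0], seed=0)
        q = gen_cest_profile(0.0, (0.9, 0.1), (0.0, -200.0), 2.4,
                             (30.0, 30.0), [-200.0], [3.0], seed=0)
        assert p.intensities[0] < 0.5 * q.intensities[0]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_cest_profile(-1.0, (0.9, 0.1), (0.0, -200.0), 2.4,
                             (30.0, 30.0), [0.0], [1.0], seed=0)


class TestGenTitration:
    def test_rt_zero_reads_free_anisotropy(self):
        t, _ = gen_titration(100.0, 0.35, 0.05, 50.0, [0.0, 1, 2, 3, 4],
                             0.0, 0.0, seed=0)
        assert t.A_obs[0] == pytest.approx(0.05, abs=1e-12)

    def test_saturation_approaches_bound_anisotropy(self):
        t, _ = gen_titration(100.0, 0.35, 0.05, 50.0, [1e9, 1, 2, 3, 4],
                             0.0, 0.0, seed=0)
        assert t.A_obs[0] == pytest.approx(0.35, abs=1e-4)

    def test_outliers_flagged_and_displaced(self):
        t, flags = gen_titration(100.0, 0.35, 0.05, 50.0,
                                 [5000 / 2**i for i in range(12)],
                                 0.002, 2 / 12, seed=0)
        assert flags.sum() == 2
        clean, _ = gen_titration(100.0, 0.35, 0.05, 50.0,
                                 [5000 / 2**i for i in range(12)],
                                 0.002, 0.0, seed=0)
        disp = np.abs(t.A_obs - clean.A_obs)[flags]
        assert (disp >= 10 * 0.002 - 1e-12).all()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            gen_titration(100.0, 0.35, 0.05, 50.0, [], 0.0, 0.0, seed=0)


class TestGenHdxDataset:
    def make_truth(self, value=0.5):
        tp = np.array([10.0, 60.0, 300.0])
        return ResidueUptakeTruth(tp, {r: np.full(3, value) for r in range(1, 21)})

    def test_uniform_truth_uniform_reading(self):
        ds = gen_hdx_dataset(self.make_truth(0.5), [(1, 10, "A" * 10)], 0.0,
                             recovery=1.0, d_content=1.0, seed=0)
        assert np.allclose(ds.data["percentD"], 50.0)

    def test_recovery_and_content_scale_observation(self):
        # full exchange observed at 0.70 x 0.80 = 56%
        ds = gen_hdx_dataset(self.make_truth(1.0), [(1, 10, "A" * 10)], 0.0,
                             recovery=0.70, d_content=0.80, seed=0)
        assert np.allclose(ds.data["percentD"], 56.0)

    def test_out_of_range_peptide_rejected(self):
        with pytest.raises(ValueError, match="outside truth range"):
            gen_hdx_dataset(self.make_truth(), [(15, 24, "A" * 10)], 0.0, seed=0)

    def test_nonmonotone_truth_rejected(self):
        tp = np.array([10.0, 60.0])
        with pytest.raises(ValueError, match="nondecreasing"):
            ResidueUptakeTruth(tp, {1: np.array([0.5, 0.4])})
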