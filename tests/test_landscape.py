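"""Reweighting estimators, PMF construction and well identification."""

import math

import numpy as np
import pytest

from lbdens.constants import KB_KCAL_MOL_K as KB
from lbdens.landscape import (
    LandscapeGrid,
    TrajectoryEnsemble,
    Well,
    build_pmf,
    extract_well_frames,
    find_wells,
    reweight_frames,
)

KT298 = KB * 298.0


def make_ensemble(cv1, cv2, dv, T=298.0):
    return TrajectoryEnsemble(np.asarray(cv1, float), np.asarray(cv2, float),
                              np.asarray(dv, float), temperature=T)


class TestReweightFrames:
    def test_zero_boost_gives_uniform_weights(self):
        ens = make_ensemble([0, 1, 2, 3], [0, 0, 0, 0], [0, 0, 0, 0])
        for est in ("exponential", "maclaurin", "cumulant2"):
            w = reweight_frames(ens, est)
            np.testing.assert_allclose(w, 0.25)

    def test_two_frame_exponential_ratio(self):
        # dV = kT ln 2 doubles the second frame's weight: 1/3 vs 2/3
        ens = make_ensemble([0, 1], [0, 0], [0.0, KT298 * math.log(2)])
        w = reweight_frames(ens, "exponential")
        np.testing.assert_allclose(w, [1 / 3, 2 / 3], rtol=1e-12)

    def test_maclaurin_converges_to_exponential_for_small_boost(self):
        rng = np.random.default_rng(0)
        dv = rng.uniform(0, KT298, 50)  # dV <= 1 kT
        ens = make_ensemble(rng.normal(size=50), rng.normal(size=50), dv)
        w_exp = reweight_frames(ens, "exponential")
        w_mac = reweight_frames(ens, "maclaurin", order=30)
        np.testing.assert_allclose(w_mac, w_exp, rtol=1e-10)

    def test_exponential_overflow_signaled(self):
        ens = make_ensemble([0, 1], [0, 0], [0.0, 1000.0])
        with pytest.raises(OverflowError, match="cumulant2"):
            reweight_frames(ens, "exponential")

    def test_boost_offset_invariance(self):
        # adding a constant to all dV cannot change normalized weights
        rng = np.random.default_rng(1)
        dv = rng.uniform(0, 2, 40)
        ens_a = make_ensemble(rng.normal(size=40), rng.normal(size=40), dv)
        ens_b = make_ensemble(ens_a.cv1, ens_a.cv2, dv + 1.7)
        for est in ("exponential", "cumulant2"):
            np.testing.assert_allclose(
                reweight_frames(ens_a, est), reweight_frames(ens_b, est), rtol=1e-9
            )

    def test_invalid_estimator_rejected(self):
        ens = make_ensemble([0], [0], [0])
        with pytest.raises(ValueError):
            reweight_frames(ens, "bogus")


class TestBuildPmf:
    def test_uniform_two_bins_flat_pmf(self):
        ens = make_ensemble([0.05, 0.15], [0.05, 0.05], [0, 0])
        grid = build_pmf(ens, bin_width=0.1)
        occ = grid.pmf[grid.occupied]
        np.testing.assert_allclose(occ, 0.0, atol=1e-12)

    def test_80_20_split_closed_form(self):
        # p = {0.8, 0.2}: dPMF = -kT ln(0.25) ~ 0.8205 kcal/mol at 298 K
        cv1 = np.array([0.05] * 8 + [0.15] * 2)
        ens = make_ensemble(cv1, np.zeros(10), np.zeros(10))
        grid = build_pmf(ens, bin_width=0.1)
        vals = np.sort(grid.pmf[grid.occupied])
        assert vals[0] == 0.0
        expected = -KT298 * math.log(0.25)
        assert vals[1] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.8205, abs=2e-4)

    def test_unoccupied_bins_are_nan_not_zero(self):
        ens = make_ensemble([0.05, 0.35], [0.05, 0.05], [0, 0])
        grid = build_pmf(ens, bin_width=0.1)
        assert np.isnan(grid.pmf[~grid.occupied]).all()
        assert grid.prob.sum() == pytest.approx(1.0)

    def test_reweighting_identity_zero_boost(self, unbiased_ensemble):
        """dV = 0: the reweighted PMF equals the plain-histogram PMF exactly."""
        w = reweight_frames(unbiased_ensemble, "exponential")
        grid_w = build_pmf(unbiased_ensemble, w, 0.1)
        grid_u = build_pmf(unbiased_ensemble, None, 0.1)
        np.testing.assert_allclose(grid_w.prob, grid_u.prob, atol=1e-15)
        np.testing.assert_array_equal(grid_w.occupied, grid_u.occupied)
        np.testing.assert_allclose(
            grid_w.pmf[grid_w.occupied], grid_u.pmf[grid_u.occupied], atol=1e-10
        )

    def test_degenerate_single_bin_warns(self):
        ens = make_ensemble([0.05, 0.06], [0.05, 0.06], [0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            build_pmf(ens, bin_width=1.0)


def brute_force_minima(grid: LandscapeGrid):
    """Oracle: exhaustive 8-neighbor local-minimum scan."""
    occ = grid.occupied
    out = []
    ni, nj = grid.pmf.shape
    for i in range(ni):
        for j in range(nj):
            if not occ[i, j]:
                continue
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < ni and 0 <= b < nj and occ[a, b]:
                        if grid.pmf[a, b] < grid.pmf[i, j]:
                            ok = False
            if ok:
                out.append((i, j))
    return out


class TestFindWells:
    def test_single_well_found_at_center(self, two_well_spec):
        from lbdens.synthetic import LandscapeSpec, WellSpec, gen_amd_ensemble

        spec = LandscapeSpec(wells=[WellSpec((1.0, 1.0), 0.0)])
        ens = gen_amd_ensemble(spec, 30_000, seed=3)
        grid = build_pmf(ens, None, 0.1)
        wells = find_wells(grid, max_energy=0.5, min_separation=0.5)
        assert len(wells) == 1
        assert wells[0].energy == 0.0
        assert abs(wells[0].center[0] - 1.0) <= 0.15
        assert abs(wells[0].center[1] - 1.0) <= 0.15

    def test_two_wells_match_brute_force_and_order(self, unbiased_ensemble):
        grid = build_pmf(unbiased_ensemble, None, 0.1)
        wells = find_wells(grid, max_energy=1.5, min_separation=0.5)
        assert len(wells) == 2
        assert wells[0].energy == 0.0
        # deep well near (1,3), shallow near (3,1)
        assert math.hypot(wells[0].center[0] - 1, wells[0].center[1] - 3) < 0.3
        assert math.hypot(wells[1].center[0] - 3, wells[1].center[1] - 1) < 0.3
        oracle = brute_force_minima(grid)
        for w in wells:
            assert w.index in oracle

    def test_flat_landscape_tie_breaks_to_lowest_index(self):
        cv = np.array([0.05, 0.15, 0.25, 0.35])
        ens = make_ensemble(cv, [0.05] * 4, [0] * 4)
        grid = build_pmf(ens, bin_width=0.1)
        wells = find_wells(grid, max_energy=1.0)
        assert len(wells) == 1
        assert wells[0].index == (0, 0)

    def test_nothing_below_threshold_returns_empty(self, unbiased_ensemble):
        grid = build_pmf(unbiased_ensemble, None, 0.1)
        assert find_wells(grid, max_energy=-1.0) == []


class TestExtractWellFrames:
    def test_closed_boundary_and_oracle_count(self):
        rng = np.random.default_rng(4)
        cv1 = rng.uniform(0, 2, 2000)
        cv2 = rng.uniform(0, 2, 2000)
        # plant frames exactly at the center and on the corner of the square
        # (0.125 is exactly representable, so the closed bound is exact)
        cv1[0], cv2[0] = 1.0, 1.0
        cv1[1], cv2[1] = 1.125, 1.125
        ens = make_ensemble(cv1, cv2, np.zeros(2000))
        well = Well(center=(1.0, 1.0), index=(0, 0), energy=0.0)
        ids = set(extract_well_frames(ens, well, half_width=0.125))
        assert 0 in ids and 1 in ids  # center and closed corner included
        oracle = {
            i
            for i in range(2000)
            if abs(cv1[i] - 1.0) <= 0.125 and abs(cv2[i] - 1.0) <= 0.125
        }
        assert ids == oracle

    def test_empty_square_signaled(self):
        ens = make_ensemble([0.0], [0.0], [0.0])
        well = Well(center=(5.0, 5.0), index=(0, 0), energy=0.0)
        with pytest.raises(ValueError, match="unusable"):
            extract_well_frames(ens, well)


class TestEnsembleValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(cv1=[], cv2=[], dv=[]),
            dict(cv1=[0.0], cv2=[0.0], dv=[-1.0]),
            dict(cv1=[np.inf], cv2=[0.0], dv=[0.0]),
        ],
    )
    def test_invalid_ensembles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrajectoryEnsemble(
                np.asarray(kwargs["cv1"], float),
                np.asarray(kwargs["cv2"], float),
                np.asarray(kwargs["dv"], float),
            )
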