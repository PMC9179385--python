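"""TRE, Dice, gamma index (incl. brute-force oracle), DVH, replan trigger."""

import numpy as np
import pytest
from scipy import ndimage

from synthct.core_images import Grid3, ImageVolume, LandmarkSet, Modality, ROIMask
from synthct.dose_toy import DoseGrid
from synthct.metrics import (
    DVHStats,
    GammaCriteria,
    compute_dice,
    compute_dvh,
    compute_gamma,
    compute_tre,
    replan_decision,
)
from synthct.registration import DeformationField


def dose_on(grid, arr, rx=50.0):
    return DoseGrid(ImageVolume(grid, np.asarray(arr, float), Modality.DOSE_GYRBE), rx)


def smooth_random_dose(grid, seed, peak=45.0):
    rng = np.random.default_rng(seed)
    a = ndimage.gaussian_filter(rng.normal(size=grid.shape), 3.0)
    return (a - a.min()) / (a.max() - a.min()) * peak


# -- TRE ----------------------------------------------------------------------

class TestTRE:
    def test_identical_sets_give_zero(self):
        lms = LandmarkSet(["a", "b"], [[1, 2, 3], [4, 5, 6]])
        tre = compute_tre(lms, lms)
        assert tre.mean_mm == tre.rmse_mm == tre.max_mm == 0.0

    def test_three_four_five_triangle(self):
        a = LandmarkSet(["p"], [[0, 0, 0]])
        b = LandmarkSet(["p"], [[3, 4, 0]])
        tre = compute_tre(a, b)
        assert tre.mean_mm == tre.rmse_mm == tre.max_mm == pytest.approx(5.0)

    def test_two_pairs_mean_and_rmse(self):
        """Distances 1 and 7 mm: mean 4, rmse sqrt((1+49)/2) = 5."""
        a = LandmarkSet(["p", "q"], [[0, 0, 0], [0, 0, 0]])
        b = LandmarkSet(["p", "q"], [[1, 0, 0], [0, 7, 0]])
        tre = compute_tre(a, b)
        assert tre.mean_mm == pytest.approx(4.0)
        assert tre.rmse_mm == pytest.approx(5.0)
        assert tre.max_mm == pytest.approx(7.0)

    def test_rmse_is_root_mean_square_of_distances(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3)) * 30
        labels = [f"m{i}" for i in range(10)]
        a = LandmarkSet(labels, pts)
        b = LandmarkSet(labels, pts + rng.normal(size=(10, 3)))
        tre = compute_tre(a, b)
        assert tre.rmse_mm**2 == pytest.approx(np.mean(tre.per_landmark_mm**2))
        assert tre.max_mm >= tre.mean_mm

    def test_field_maps_ref_points_first(self):
        grid = Grid3.centered((10, 10, 10), (2, 2, 2))
        disp = np.broadcast_to([1.0, 0.0, 0.0], grid.shape + (3,)).copy()
        field = DeformationField(grid, disp)
        a = LandmarkSet(["p"], [[0, 0, 0]])
        b = LandmarkSet(["p"], [[1, 0, 0]])
        tre = compute_tre(a, b, field=field)
        assert tre.max_mm == pytest.approx(0.0, abs=1e-9)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_tre(LandmarkSet(["a"], [[0, 0, 0]]), LandmarkSet(["b"], [[0, 0, 0]]))


# -- Dice ---------------------------------------------------------------------

class TestDice:
    grid = Grid3((20, 20, 20), (1, 1, 1))

    def cube(self, lo, hi):
        vox = np.zeros(self.grid.shape, np.uint8)
        vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
        return ROIMask(self.grid, vox)

    def test_identical_masks(self):
        m = self.cube((2, 2, 2), (12, 12, 12))
        assert compute_dice(m, m) == 1.0

    def test_disjoint_masks(self):
        assert compute_dice(self.cube((0, 0, 0), (5, 5, 5)),
                            self.cube((10, 10, 10), (15, 15, 15))) == 0.0

    def test_half_overlapping_cubes(self):
        """Two 10x10x10 cubes overlapping in 10x10x5 -> 2*500/2000 = 0.5."""
        a = self.cube((0, 0, 0), (10, 10, 10))
        b = self.cube((0, 0, 5), (10, 10, 15))
        assert compute_dice(a, b) == pytest.approx(0.5)

    def test_empty_vs_empty_is_one_and_symmetry(self):
        e = ROIMask(self.grid, np.zeros(self.grid.shape, np.uint8))
        assert compute_dice(e, e) == 1.0
        a = self.cube((0, 0, 0), (8, 8, 8))
        b = self.cube((4, 4, 4), (12, 12, 12))
        assert compute_dice(a, b) == compute_dice(b, a)
        assert 0.0 <= compute_dice(a, b) <= 1.0

    def test_grid_mismatch_rejected(self):
        other = Grid3((20, 20, 20), (2, 2, 2))
        with pytest.raises(ValueError):
            compute_dice(self.cube((0, 0, 0), (5, 5, 5)),
                         ROIMask(other, np.zeros((20, 20, 20), np.uint8)))


# -- gamma --------------------------------------------------------------------

def brute_force_gamma(ref: DoseGrid, ev: DoseGrid, crit: GammaCriteria) -> np.ndarray:
    """Independent exhaustive oracle: per-voxel scan of the full fine offset
    lattice (step dta/10, radius 3*dta) with trilinear dose interpolation."""
    norm = ref.prescription_gyrbe if crit.normalization == "prescription" \
        else float(ref.voxels.max())
    dd = crit.dose_diff_pct / 100.0 * norm
    thr = crit.threshold_pct / 100.0 * ref.prescription_gyrbe
    sel = ref.voxels >= thr
    pts = ref.grid.voxel_centers()[sel]
    refv = ref.voxels[sel].astype(float)

    step = crit.dta_mm / 10.0
    n = int(round(3.0 * crit.dta_mm / step))
    ax = step * np.arange(-n, n + 1)
    O = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    O = O[np.linalg.norm(O, axis=1) <= 3.0 * crit.dta_mm + 1e-9]
    space2 = np.sum(O**2, axis=1) / crit.dta_mm**2

    ev_arr = ev.voxels.astype(float)
    out = np.zeros(len(pts))
    for k, (p, rv) in enumerate(zip(pts, refv)):
        idx = ev.grid.world_to_index(p[None, :] + O)
        de = ndimage.map_coordinates(ev_arr, idx.T, order=1, mode="nearest")
        out[k] = np.sqrt(np.min((de - rv) ** 2 / dd**2 + space2))
    full = np.zeros(ref.grid.shape)
    full[sel] = out
    return full, sel


class TestGamma:
    grid = Grid3.centered((16, 16, 16), (1.0, 1.0, 1.0))
    crit = GammaCriteria()  # 2 mm / 2%, 5% threshold

    def test_identical_doses_pass_everywhere_with_zero_gamma(self):
        d = dose_on(self.grid, np.full(self.grid.shape, 30.0))
        r = compute_gamma(d, d, self.crit)
        assert r.pass_rate_pct == 100.0
        assert r.gamma_map.voxels.max() == 0.0
        assert r.evaluated_voxels == int(np.prod(self.grid.shape))

    def test_uniform_one_percent_offset_gives_half_gamma(self):
        """Flat dose + 1% of Rx everywhere: spatial search cannot help, so
        gamma = (1%)/(2%) = 0.5 exactly."""
        flat = np.full(self.grid.shape, 30.0)
        r = compute_gamma(dose_on(self.grid, flat), dose_on(self.grid, flat + 0.5),
                          self.crit)
        evaluated = r.gamma_map.voxels
        np.testing.assert_allclose(evaluated, 0.5, atol=1e-12)
        assert r.pass_rate_pct == 100.0

    def test_uniform_three_percent_offset_fails_everywhere(self):
        flat = np.full(self.grid.shape, 30.0)
        r = compute_gamma(dose_on(self.grid, flat), dose_on(self.grid, flat + 1.5),
                          self.crit)
        np.testing.assert_allclose(r.gamma_map.voxels, 1.5, atol=1e-12)
        assert r.pass_rate_pct == 0.0

    def test_matches_brute_force_oracle_per_voxel(self):
        """Fast search vs exhaustive fine-lattice scan: <= 1e-3 per voxel."""
        ref_arr = smooth_random_dose(self.grid, 11)
        mod = 1 + 0.02 * np.sin(np.linspace(0, 5, self.grid.shape[2]))
        ev_arr = np.clip(ref_arr * mod[None, None, :] + 0.4, 0, None)
        ref_d, ev_d = dose_on(self.grid, ref_arr), dose_on(self.grid, ev_arr)
        fast = compute_gamma(ref_d, ev_d, self.crit)
        oracle, sel = brute_force_gamma(ref_d, ev_d, self.crit)
        np.testing.assert_allclose(
            fast.gamma_map.voxels[sel], oracle[sel], atol=1e-3
        )

    def test_pass_rate_monotone_when_criteria_loosened(self):
        ref_arr = smooth_random_dose(self.grid, 5)
        ev_arr = np.clip(ref_arr + 0.8 * np.cos(np.arange(16))[None, None, :], 0, None)
        ref_d, ev_d = dose_on(self.grid, ref_arr), dose_on(self.grid, ev_arr)
        base = compute_gamma(ref_d, ev_d, GammaCriteria(2.0, 2.0, 5.0))
        loose_dd = compute_gamma(ref_d, ev_d, GammaCriteria(3.0, 2.0, 5.0))
        loose_dta = compute_gamma(ref_d, ev_d, GammaCriteria(2.0, 3.0, 5.0))
        assert loose_dd.pass_rate_pct >= base.pass_rate_pct
        assert loose_dta.pass_rate_pct >= base.pass_rate_pct

    def test_threshold_excludes_low_dose_voxels(self):
        arr = np.full(self.grid.shape, 1.0)  # 2% of Rx=50 -> below 5% threshold
        arr[:8] = 30.0
        r = compute_gamma(dose_on(self.grid, arr), dose_on(self.grid, arr), self.crit)
        assert r.evaluated_voxels == int((arr >= 2.5).sum())

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            GammaCriteria(dose_diff_pct=0.0)
        with pytest.raises(ValueError):
            DoseGrid(ImageVolume(self.grid, np.zeros(self.grid.shape),
                                 Modality.DOSE_GYRBE), 0.0)


# -- DVH ----------------------------------------------------------------------

class TestDVH:
    def make(self, values, voxel_cc=0.1, rx=50.0):
        return DVHStats("roi", rx, np.sort(np.asarray(values, float))[::-1], voxel_cc)

    def test_uniform_dose_statistics(self):
        s = self.make([54.0] * 100, rx=54.0)
        assert s.Dmean == s.Dmax == s.Dpct(1.0) == 54.0
        assert s.Vpct(95.0) == 100.0

    def test_bimodal_sorting_example(self):
        """50 voxels at 60, 50 at 40, Rx 50: Dmean 50, V95 50%, D95 40."""
        s = self.make([60.0] * 50 + [40.0] * 50)
        assert s.Dmean == pytest.approx(50.0)
        assert s.Vpct(95.0) == pytest.approx(50.0)  # >= 47.5 GyRBE
        assert s.Dpct(95.0) == pytest.approx(40.0)
        assert s.Dmax == 60.0

    def test_d2cc_volume_sorting_example(self):
        """10 cc structure, hottest 2 cc at 30, rest at 10 -> D2cc = 30."""
        s = self.make([30.0] * 20 + [10.0] * 80, voxel_cc=0.1)
        assert s.volume_cc == pytest.approx(10.0)
        assert s.Dcc(2.0) == pytest.approx(30.0)
        assert s.Dcc(0.0) == s.Dmax

    def test_dpct_and_vpct_monotone_non_increasing(self):
        rng = np.random.default_rng(13)
        s = self.make(rng.random(500) * 60)
        xs = np.linspace(0.5, 100, 40)
        dp = [s.Dpct(x) for x in xs]
        vp = [s.Vpct(p) for p in np.linspace(1, 120, 40)]
        assert all(b <= a + 1e-12 for a, b in zip(dp, dp[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(vp, vp[1:]))

    def test_statistics_invariant_under_voxel_permutation(self):
        rng = np.random.default_rng(17)
        vals = rng.random(200) * 60
        a, b = self.make(vals), self.make(rng.permutation(vals))
        assert a.Dmean == pytest.approx(b.Dmean)
        assert a.Dpct(33.0) == pytest.approx(b.Dpct(33.0))
        assert a.Dcc(1.3) == pytest.approx(b.Dcc(1.3))

    def test_compute_dvh_from_volume_and_errors(self):
        grid = Grid3((10, 10, 10), (2, 2, 2))
        dose = dose_on(grid, np.full(grid.shape, 20.0), rx=50.0)
        vox = np.zeros(grid.shape, np.uint8)
        vox[:3] = 1
        s = compute_dvh(dose, ROIMask(grid, vox, "x"))
        assert s.Dmean == 20.0
        with pytest.raises(ValueError, match="empty"):
            compute_dvh(dose, ROIMask(grid, np.zeros(grid.shape, np.uint8), "e"))
        other = Grid3((10, 10, 10), (1, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            compute_dvh(dose, ROIMask(other, np.ones((10, 10, 10), np.uint8), "g"))

    def test_dvh_curve_is_cumulative(self):
        s = self.make([60.0] * 50 + [40.0] * 50)
        levels, vol = s.curve(50)
        assert vol[0] == 100.0
        assert all(b <= a for a, b in zip(vol, vol[1:]))


# -- replan trigger -----------------------------------------------------------

class TestReplan:
    def stats_with_v95(self, v95_pct, rx=50.0, n=100):
        hot = int(round(n * v95_pct / 100))
        vals = [rx] * hot + [0.5 * rx] * (n - hot)
        return DVHStats("CTV", rx, np.sort(np.asarray(vals))[::-1], 0.1)

    def test_six_point_drop_triggers(self):
        trig, line = replan_decision(self.stats_with_v95(98), self.stats_with_v95(92))
        assert trig
        assert "REPLAN" in line

    def test_one_point_drop_stays_silent(self):
        trig, _ = replan_decision(self.stats_with_v95(98), self.stats_with_v95(97))
        assert not trig

    def test_identical_stats_no_trigger(self):
        s = self.stats_with_v95(95)
        trig, _ = replan_decision(s, s)
        assert not trig

    def test_exact_five_point_drop_triggers(self):
        trig, _ = replan_decision(self.stats_with_v95(98), self.stats_with_v95(93))
        assert trig

    def test_structure_mismatch_rejected(self):
        a = self.stats_with_v95(98)
        b = self.stats_with_v95(92)
        b.structure = "PTV"
        with pytest.raises(ValueError):
            replan_decision(a, b)
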