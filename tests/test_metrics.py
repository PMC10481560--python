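"""DVH engine, dose indices, gamma analysis, complexity score and the exact
Wilcoxon test, each checked against an independent oracle or closed form."""

import itertools

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import rankdata, wilcoxon

from rectarc import (
    ArcPlan,
    BeamModel,
    ControlPoint,
    GammaCriteria,
    ROIMask,
    VoxelGrid,
    ClinicalGoal,
    StructureSet,
    conformity_index,
    cumulative_dvh,
    dose_at_volume,
    evaluate_goals,
    gamma_pass_rate,
    homogeneity_index,
    modulation_complexity,
    plan_sum,
    total_mu,
    volume_at_dose,
    wilcoxon_signed_rank_exact,
)
from rectarc.grid import EmptyMaskError

from conftest import small_geometry


def _roi(geom, mask, name="roi"):
    return ROIMask(name, geom, mask)


def _uniform_dose(geom, gy):
    return VoxelGrid(geom, np.full(geom.shape, gy))


class TestDVH:
    def test_uniform_dose_step(self, geom16):
        mask = np.zeros(geom16.shape, bool)
        mask[4:8] = True
        dvh = cumulative_dvh(_uniform_dose(geom16, 45.0), _roi(geom16, mask))
        assert dvh.cum_fraction[0] == 1.0
        assert volume_at_dose(dvh, 44.9)[0] == pytest.approx(100.0)
        assert volume_at_dose(dvh, 45.1)[0] == pytest.approx(0.0)

    def test_two_voxel_half_volume(self, geom16):
        dose = np.zeros(geom16.shape)
        mask = np.zeros(geom16.shape, bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        dose[0, 0, 0], dose[0, 0, 1] = 10.0, 20.0
        dvh = cumulative_dvh(VoxelGrid(geom16, dose), _roi(geom16, mask))
        assert volume_at_dose(dvh, 15.0)[0] == pytest.approx(50.0)

    def test_matches_per_voxel_counting_oracle(self, geom16):
        rng = np.random.default_rng(11)
        dose = VoxelGrid(geom16, rng.random(geom16.shape) * 50.0)
        mask = rng.random(geom16.shape) > 0.6
        dvh = cumulative_dvh(dose, _roi(geom16, mask))
        vals = dose.values[mask]
        for edge, frac in zip(dvh.bin_edges_gy, dvh.cum_fraction):
            assert frac == pytest.approx(np.mean(vals >= edge))

    def test_monotone_and_bounded(self, geom16):
        rng = np.random.default_rng(5)
        dose = VoxelGrid(geom16, rng.random(geom16.shape) * 30.0)
        dvh = cumulative_dvh(dose, _roi(geom16, np.ones(geom16.shape, bool)))
        assert np.all(np.diff(dvh.cum_fraction) <= 1e-12)
        assert dvh.cum_fraction[0] == 1.0
        assert dvh.cum_fraction[-1] == 0.0

    def test_empty_mask_raises(self, geom16):
        with pytest.raises(EmptyMaskError):
            cumulative_dvh(_uniform_dose(geom16, 1.0),
                           _roi(geom16, np.zeros(geom16.shape, bool)))


class TestDxVx:
    def test_uniform_dose_readout(self, geom16):
        mask = np.ones(geom16.shape, bool)
        dvh = cumulative_dvh(_uniform_dose(geom16, 45.0), _roi(geom16, mask))
        assert dose_at_volume(dvh, 93.0) == pytest.approx(45.0, abs=0.05)
        assert volume_at_dose(dvh, 45.0)[0] == pytest.approx(100.0)

    def test_linear_ramp_d50(self, geom16):
        # dose ramps 0 → 45 Gy across one axis: D50 ≈ 22.5 Gy
        ramp = np.linspace(0.0, 45.0, geom16.shape[0])[:, None, None]
        dose = VoxelGrid(geom16, np.broadcast_to(ramp, geom16.shape).copy())
        dvh = cumulative_dvh(dose, _roi(geom16, np.ones(geom16.shape, bool)))
        assert dose_at_volume(dvh, 50.0) == pytest.approx(22.5, abs=45.0 / 16)

    def test_dx_vx_round_trip(self, geom16):
        rng = np.random.default_rng(2)
        dose = VoxelGrid(geom16, rng.gamma(4.0, 5.0, geom16.shape))
        dvh = cumulative_dvh(dose, _roi(geom16, np.ones(geom16.shape, bool)))
        for x in (10.0, 50.0, 93.0, 98.0):
            dx = dose_at_volume(dvh, x)
            assert volume_at_dose(dvh, dx)[0] >= x - 1.0

    def test_out_of_range_x(self, geom16):
        dvh = cumulative_dvh(_uniform_dose(geom16, 1.0),
                             _roi(geom16, np.ones(geom16.shape, bool)))
        with pytest.raises(ValueError):
            dose_at_volume(dvh, 0.0)
        with pytest.raises(ValueError):
            dose_at_volume(dvh, 101.0)


class TestConformityHomogeneity:
    def test_exact_coverage_ci_one(self, geom16):
        mask = np.zeros(geom16.shape, bool)
        mask[4:10, 4:10, 4:10] = True
        dose = np.where(mask, 45.0, 10.0)
        assert conformity_index(VoxelGrid(geom16, dose), _roi(geom16, mask), 45.0) == 1.0

    def test_double_piv_ci_half(self):
        # TV = 100 cc fully covered by a 200 cc prescription isodose → 0.5
        geom = small_geometry(40, 2.0)  # 8 mm³ voxels
        flat = np.zeros(int(np.prod(geom.shape)), bool)
        tv = flat.copy()
        tv[:12500] = True          # 100 cc
        piv = flat.copy()
        piv[:25000] = True         # 200 cc, covering all of TV
        dose = np.where(piv.reshape(geom.shape), 46.0, 0.0)
        ci = conformity_index(VoxelGrid(geom, dose),
                              _roi(geom, tv.reshape(geom.shape)), 45.0)
        assert ci == pytest.approx(100.0**2 / (100.0 * 200.0))

    def test_empty_piv_warns_zero(self, geom16):
        mask = np.ones(geom16.shape, bool)
        with pytest.warns(UserWarning):
            ci = conformity_index(_uniform_dose(geom16, 1.0), _roi(geom16, mask), 45.0)
        assert ci == 0.0

    def test_uniform_dose_hi_zero(self, geom16):
        dvh = cumulative_dvh(_uniform_dose(geom16, 45.0),
                             _roi(geom16, np.ones(geom16.shape, bool)))
        # bounded by the 0.05 Gy DVH bin resolution
        assert homogeneity_index(dvh, 45.0) == pytest.approx(0.0, abs=0.0025)

    def test_hi_from_reported_near_min_near_max(self, geom16):
        # D2 = 104.6 %, D98 = 95.2 % of prescription → HI = 0.094
        n = np.prod(geom16.shape)
        vals = np.linspace(0.952, 1.046, n).reshape(geom16.shape) * 45.0
        dvh = cumulative_dvh(VoxelGrid(geom16, vals),
                             _roi(geom16, np.ones(geom16.shape, bool)))
        assert homogeneity_index(dvh, 45.0) == pytest.approx(0.094, abs=0.004)

    def test_hi_scale_invariance(self, geom16):
        rng = np.random.default_rng(8)
        vals = 40.0 + rng.random(geom16.shape) * 10.0
        roi = _roi(geom16, np.ones(geom16.shape, bool))
        hi1 = homogeneity_index(cumulative_dvh(VoxelGrid(geom16, vals), roi), 45.0)
        hi2 = homogeneity_index(cumulative_dvh(VoxelGrid(geom16, vals * 2), roi), 90.0)
        assert hi1 == pytest.approx(hi2, abs=2e-3)


class TestPlanSum:
    def test_identity_and_commutativity(self, geom16):
        rng = np.random.default_rng(0)
        a = VoxelGrid(geom16, rng.random(geom16.shape))
        b = VoxelGrid(geom16, rng.random(geom16.shape))
        zero = VoxelGrid(geom16, np.zeros(geom16.shape))
        assert np.array_equal(plan_sum(a, zero).values, a.values)
        assert np.array_equal(plan_sum(a, b).values, plan_sum(b, a).values)
        # spot-check voxels against manual addition
        for idx in [(0, 0, 0), (3, 7, 9), (15, 15, 15)]:
            assert plan_sum(a, b).values[idx] == a.values[idx] + b.values[idx]


class TestEvaluateGoals:
    def _structs(self, geom):
        s = StructureSet(geom)
        ptv = np.zeros(geom.shape, bool)
        ptv[4:10] = True
        bl = np.zeros(geom.shape, bool)
        bl[10:14] = True
        s.add(ROIMask("PTV_initial", geom, ptv))
        s.add(ROIMask("Bladder", geom, bl))
        return s

    def test_uniform_coverage_passes(self, geom16):
        structs = self._structs(geom16)
        goal = ClinicalGoal("PTV", "Dx", 93, ">", 98, "pct_rx", "initial")
        rep = evaluate_goals({"initial": _uniform_dose(geom16, 45.0)},
                             {"initial": 45.0}, structs, [goal])
        assert rep.ok and rep.results[0].achieved == pytest.approx(100.0, abs=0.2)

    def test_cold_oar_vx_passes_with_zero(self, geom16):
        structs = self._structs(geom16)
        goal = ClinicalGoal("Bladder", "Vx", 50, "<=", 0, "pct_volume", "initial")
        rep = evaluate_goals({"initial": _uniform_dose(geom16, 30.0)},
                             {"initial": 45.0}, structs, [goal])
        assert rep.ok and rep.results[0].achieved == 0.0

    def test_hot_disjoint_oar_fails(self, geom16):
        structs = self._structs(geom16)
        goal = ClinicalGoal("Bladder", "Vx", 45, "<", 30, "pct_volume", "initial")
        rep = evaluate_goals({"initial": _uniform_dose(geom16, 46.0)},
                             {"initial": 45.0}, structs, [goal])
        assert not rep.ok and rep.results[0].status == "fail"

    def test_hot_overlapping_oar_flagged(self, geom16):
        structs = self._structs(geom16)
        # make the bladder overlap the PTV: violation downgraded to a flag
        bl = structs["Bladder"].mask.copy()
        bl[9] = True
        structs = self._structs(geom16)
        structs._rois["Bladder"] = ROIMask("Bladder", geom16, bl)
        goal = ClinicalGoal("Bladder", "Vx", 45, "<", 30, "pct_volume", "initial")
        rep = evaluate_goals({"initial": _uniform_dose(geom16, 46.0)},
                             {"initial": 45.0}, structs, [goal])
        assert rep.ok and rep.results[0].status == "flagged"


def brute_force_gamma(ref: VoxelGrid, ev: VoxelGrid, criteria: GammaCriteria):
    """Exhaustive small-grid oracle with an independent interpolator."""
    ref_max = ref.values.max()
    dd = criteria.dose_diff_pct / 100 * ref_max
    dta = criteria.dta_mm
    step = criteria.step_fraction * dta
    radius = criteria.search_radius_factor * dta
    axes = [ev.geometry.axis_coords(i) for i in range(3)]
    interp = RegularGridInterpolator(axes, ev.values, bounds_error=False,
                                     fill_value=np.nan)
    k = int(np.floor(radius / step + 1e-9))
    axis = step * np.arange(-k, k + 1)
    offs = np.array(list(itertools.product(axis, axis, axis)))
    r2 = np.sum(offs**2, axis=1)
    keep = r2 <= radius**2 + 1e-9
    offs, r2 = offs[keep], r2[keep]
    gammas = []
    analyzed = ref.values >= criteria.low_dose_cutoff_fraction * ref_max
    for idx in np.argwhere(analyzed):
        p = ref.geometry.index_to_world(idx)
        dvals = interp(p[None, :] + offs)
        g2 = ((dvals - ref.values[tuple(idx)]) / dd) ** 2 + r2 / dta**2
        gammas.append(np.sqrt(np.nanmin(g2)))
    gammas = np.array(gammas)
    return 100.0 * np.mean(gammas <= 1.0 + 1e-9), gammas


class TestGamma:
    def test_identity_is_100(self, geom16):
        rng = np.random.default_rng(0)
        dose = VoxelGrid(geom16, 10.0 + rng.random(geom16.shape))
        res = gamma_pass_rate(dose, dose)
        assert res.pass_rate_pct == 100.0

    def test_two_percent_global_scaling_passes(self, geom16):
        rng = np.random.default_rng(1)
        dose = VoxelGrid(geom16, 10.0 + rng.random(geom16.shape))
        res = gamma_pass_rate(dose, dose.with_values(dose.values * 1.02))
        assert res.pass_rate_pct == 100.0

    def test_flat_five_percent_offset_fails_everywhere(self):
        geom = small_geometry(10, 2.0)
        ref = VoxelGrid(geom, np.full(geom.shape, 10.0))
        ev = VoxelGrid(geom, np.full(geom.shape, 10.5))
        res = gamma_pass_rate(ref, ev)
        assert res.pass_rate_pct == 0.0

    def test_matches_exhaustive_oracle(self):
        geom = small_geometry(7, 2.0)
        rng = np.random.default_rng(4)
        ref = VoxelGrid(geom, 8.0 + 2.0 * rng.random(geom.shape))
        ev = VoxelGrid(geom, ref.values + rng.normal(0.0, 0.25, geom.shape))
        crit = GammaCriteria()
        res = gamma_pass_rate(ref, ev, crit)
        want_rate, want_gammas = brute_force_gamma(ref, ev, crit)
        assert res.pass_rate_pct == pytest.approx(want_rate, abs=1e-9)
        got = res.gamma.values[~np.isnan(res.gamma.values)]
        assert np.allclose(np.sort(got), np.sort(want_gammas), atol=1e-6)

    def test_empty_reference_raises(self, geom16):
        with pytest.raises(ValueError):
            gamma_pass_rate(VoxelGrid(geom16, np.zeros(geom16.shape)),
                            VoxelGrid(geom16, np.zeros(geom16.shape)))


def _plan_from_apertures(openings, mus, machine=None):
    """openings: list per control point of (left, right) arrays."""
    cps = []
    n = len(openings)
    for i, ((left, right), mu) in enumerate(zip(openings, mus)):
        cps.append(ControlPoint(i * 360.0 / n, mu, np.asarray(left, float),
                                np.asarray(right, float)))
    return ArcPlan(cps, 0.0, (0.0, 0.0, 0.0), 45.0, machine or BeamModel())


class TestMCS:
    def test_fully_open_equal_mu_is_one(self):
        left = -np.full(10, 50.0)
        right = np.full(10, 50.0)
        plan = _plan_from_apertures([(left, right)] * 12, [10.0] * 12)
        assert modulation_complexity(plan) == pytest.approx(1.0)

    def test_bounded_on_random_plans(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            openings = []
            for _ in range(8):
                left = rng.uniform(-60, 0, 12)
                right = left + rng.uniform(0, 60, 12)
                openings.append((left, right))
            plan = _plan_from_apertures(openings, rng.uniform(0.1, 5.0, 8))
            mcs = modulation_complexity(plan)
            assert 0.0 <= mcs <= 1.0 + 1e-12

    def test_irregularity_decreases_mcs(self):
        full = (-np.full(10, 50.0), np.full(10, 50.0))
        half = [(-np.where(np.arange(10) % 2, 50.0, 5.0),
                 np.where(np.arange(10) % 2, 50.0, 5.0))] * 6
        plan_regular = _plan_from_apertures([full] * 6, [1.0] * 6)
        plan_ragged = _plan_from_apertures(half, [1.0] * 6)
        assert modulation_complexity(plan_ragged) < modulation_complexity(plan_regular)

    def test_mu_rescale_invariant(self):
        rng = np.random.default_rng(3)
        openings = []
        for _ in range(6):
            left = rng.uniform(-50, 0, 8)
            openings.append((left, left + rng.uniform(5, 50, 8)))
        mus = rng.uniform(0.5, 3.0, 6)
        p1 = _plan_from_apertures(openings, mus)
        p2 = _plan_from_apertures(openings, mus * 7.5)
        assert modulation_complexity(p1) == pytest.approx(modulation_complexity(p2))

    def test_zero_mu_raises(self):
        full = (-np.full(4, 10.0), np.full(4, 10.0))
        plan = _plan_from_apertures([full] * 8, [0.0] * 8)
        with pytest.raises(ValueError):
            modulation_complexity(plan)

    def test_total_mu(self):
        full = (-np.full(4, 10.0), np.full(4, 10.0))
        mus = [1.0, 2.5, 0.5, 3.0, 1.0, 1.0, 2.0, 1.0]
        plan = _plan_from_apertures([full] * 8, mus)
        assert total_mu(plan) == pytest.approx(sum(mus))
        doubled = _plan_from_apertures([full] * 8, [2 * m for m in mus])
        assert total_mu(doubled) == pytest.approx(2 * sum(mus))


def enumeration_wilcoxon(diffs):
    """Oracle: two-sided exact p over all 2^n sign assignments."""
    diffs = np.asarray(diffs, float)
    diffs = diffs[diffs != 0]
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    total = ranks.sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(ranks)):
        ws.append(float(np.sum(ranks[np.array(signs, bool)])))
    ws = np.array(ws)
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_five_positive_distinct(self):
        stat, p = wilcoxon_signed_rank_exact([(i + 1.0, 0.0) for i in range(5)])
        assert stat == 15.0
        assert p == pytest.approx(2 / 32)

    def test_antisymmetric_pair(self):
        _, p = wilcoxon_signed_rank_exact([(1.0, 0.0), (0.0, 1.0)])
        assert p == pytest.approx(1.0)

    def test_column_swap_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=8), rng.normal(size=8)
        w1, p1 = wilcoxon_signed_rank_exact(list(zip(a, b)))
        w2, p2 = wilcoxon_signed_rank_exact(list(zip(b, a)))
        assert p1 == pytest.approx(p2)
        ranks_total = rankdata(np.abs(a - b)).sum()
        assert w1 + w2 == pytest.approx(ranks_total)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        # half-integer values provoke ties in |differences|
        a = np.round(rng.normal(size=n) * 2) / 2
        b = np.round(rng.normal(size=n) * 2) / 2
        d = a - b
        if np.all(d == 0):
            return
        stat, p = wilcoxon_signed_rank_exact(list(zip(a, b)))
        w_want, p_want = enumeration_wilcoxon(d)
        assert stat == pytest.approx(w_want)
        assert p == pytest.approx(p_want, abs=1e-12)

    def test_cross_check_scipy_no_ties(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=9), rng.normal(size=9)
        _, p = wilcoxon_signed_rank_exact(list(zip(a, b)))
        assert p == pytest.approx(
            wilcoxon(a, b, mode="exact", alternative="two-sided").pvalue)

    def test_all_zero_differences_raise(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_exact([(1.0, 1.0), (2.0, 2.0)])
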