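"""Gamma index: analytic cases, oracle equivalence, invariances."""

import numpy as np
import pytest
from scipy import ndimage

from synctplan.gamma import (
    GammaCriteria,
    brute_force_gamma,
    gamma_map,
    pass_rate_table,
)
from synctplan.grid import VolumeGrid


def dose_blob(rng, n=16, sp=2.0):
    """Blob-like dose with smooth falloff, peak normalized to 1."""
    c = rng.uniform(n * 0.3, n * 0.7, 3)
    ii = np.indices((n, n, n)).astype(float)
    r2 = sum((ii[a] - c[a]) ** 2 for a in range(3))
    base = np.exp(-r2 / (2 * (n / 3.5) ** 2))
    base *= 1 + 0.1 * ndimage.gaussian_filter(rng.standard_normal((n, n, n)), 2)
    return VolumeGrid(base / base.max(), (sp, sp, sp))


def perturbed(ref, rng, dose_scale=0.015, shift_mm=0.5):
    pert = 1 + dose_scale * ndimage.gaussian_filter(
        rng.standard_normal(ref.shape), 2)
    shift = rng.uniform(-shift_mm, shift_mm, 3) / np.asarray(ref.spacing)
    ev = ndimage.shift(ref.values * pert, shift, order=1, mode="nearest")
    return ref.with_values(np.clip(ev, 0, None))


class TestAnalyticCases:
    def test_identity_all_zero_full_pass(self):
        rng = np.random.default_rng(1)
        ref = dose_blob(rng)
        for dd, dta in ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0)):
            res = gamma_map(ref, ref.copy(), GammaCriteria(dd, dta, 10.0))
            assert res.pass_rate_pct == 100.0
            assert np.nanmax(res.gamma.values) < 1e-4  # zero at sampling precision

    def test_uniform_offset_no_spatial_compensation(self):
        u = VolumeGrid(np.ones((12, 12, 12)), (2.0, 2.0, 2.0))
        ev = u.with_values(np.full(u.shape, 1.03))
        res = gamma_map(u, ev, GammaCriteria(2.0, 2.0, 10.0))
        g = res.gamma_values
        assert np.allclose(g, 1.5, atol=1e-9)
        assert res.pass_rate_pct == 0.0

    def test_shifted_ramp_interior_gamma(self):
        # 1%-of-norm-per-mm ramp, evaluated shifted 1 mm: the continuous
        # minimum of sqrt(u^2/4 + (1-u)^2/4) is 1/(2*sqrt(2)) at u = 0.5 mm
        n = 32
        x = np.arange(n) + 0.5
        ref = VolumeGrid(
            np.broadcast_to((0.5 + 0.01 * x)[:, None, None], (n, n, n)).copy(),
            (1.0, 1.0, 1.0))
        ev = ref.with_values(
            np.broadcast_to((0.5 + 0.01 * (x - 1.0))[:, None, None],
                            (n, n, n)).copy())
        c = GammaCriteria(2.0, 2.0, 10.0, normalization="prescription",
                          prescription_gy=1.0)
        res = gamma_map(ref, ev, c)
        oracle = brute_force_gamma(ref, ev, c)
        interior = res.gamma.values[10:22, 10:22, 10:22]
        assert np.allclose(interior, 1 / (2 * np.sqrt(2)), atol=0.01)
        assert np.nanmax(np.abs(res.gamma.values - oracle.gamma.values)) < 1e-3

    def test_single_voxel_closed_form(self):
        # one above-threshold voxel: gamma from a dense manual scan of the
        # two-term formula
        ref = VolumeGrid(np.zeros((9, 9, 9)), (2.0, 2.0, 2.0))
        ref.values[4, 4, 4] = 1.0
        ev = ref.with_values(ref.values * 0.95)
        c = GammaCriteria(3.0, 3.0, 10.0, normalization="prescription",
                          prescription_gy=1.0)
        res = brute_force_gamma(ref, ev, c)
        # manual dense scan along displacements
        best = np.inf
        for ux in np.arange(-12, 12.01, 0.05):
            for uy in np.arange(-12, 12.01, 0.05):
                # trilinear interp of the single-spike evaluated dose
                fx, fy = abs(ux) / 2.0, abs(uy) / 2.0
                val = 0.95 * max(0.0, 1 - fx) * max(0.0, 1 - fy)
                g2 = (ux**2 + uy**2) / 9.0 + ((val - 1.0) / 0.03) ** 2
                best = min(best, g2)
        assert res.gamma.values[4, 4, 4] == pytest.approx(np.sqrt(best), abs=0.02)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            ref = dose_blob(rng)
            ev = perturbed(ref, rng)
            for dd, dta in ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0)):
                c = GammaCriteria(dd, dta, 10.0)
                a = gamma_map(ref, ev, c)
                b = brute_force_gamma(ref, ev, c)
                assert np.nanmax(np.abs(a.gamma.values - b.gamma.values)) <= 1e-3

    def test_coarse_only_is_upper_bound(self):
        rng = np.random.default_rng(11)
        ref = dose_blob(rng)
        ev = perturbed(ref, rng)
        c = GammaCriteria(2.0, 2.0, 10.0)
        coarse = gamma_map(ref, ev, c, refine=False)
        exact = gamma_map(ref, ev, c, refine=True)
        assert (coarse.gamma_values >= exact.gamma_values - 1e-12).all()
        assert coarse.pass_rate_pct <= exact.pass_rate_pct + 1e-12


class TestInvariances:
    def test_pass_rate_monotone_in_criteria(self):
        rng = np.random.default_rng(3)
        ref = dose_blob(rng)
        ev = perturbed(ref, rng, dose_scale=0.03, shift_mm=1.0)
        rates = [gamma_map(ref, ev, GammaCriteria(dd, dta, 10.0)).pass_rate_pct
                 for dd, dta in ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))]
        assert rates[0] <= rates[1] <= rates[2]

    def test_asymmetric_under_swap(self):
        rng = np.random.default_rng(5)
        ref = dose_blob(rng)
        ev = perturbed(ref, rng, dose_scale=0.05, shift_mm=1.5)
        c = GammaCriteria(2.0, 2.0, 10.0)
        ab = gamma_map(ref, ev, c)
        ba = gamma_map(ev, ref, c)
        assert not np.allclose(np.nan_to_num(ab.gamma.values),
                               np.nan_to_num(ba.gamma.values))

    def test_small_dose_difference_always_passes(self):
        # dose difference below dd at zero displacement -> gamma <= 1
        # regardless of the search cap
        rng = np.random.default_rng(6)
        ref = dose_blob(rng)
        ev = ref.with_values(ref.values * 1.015)
        c = GammaCriteria(2.0, 2.0, 10.0, search_cap=0.5)
        res = gamma_map(ref, ev, c)
        assert res.pass_rate_pct == 100.0

    def test_threshold_excludes_low_dose(self):
        rng = np.random.default_rng(9)
        ref = dose_blob(rng)
        res = gamma_map(ref, ref.copy(), GammaCriteria(2.0, 2.0, 10.0))
        low = ref.values < 0.1 * ref.values.max()
        assert np.isnan(res.gamma.values[low]).all()
        assert not res.evaluated_mask.values[low].any()


class TestErrors:
    def test_all_below_threshold(self):
        v = VolumeGrid(np.full((8, 8, 8), 0.05), (2, 2, 2))
        c = GammaCriteria(2, 2, 10, normalization="prescription",
                          prescription_gy=1.0)
        with pytest.raises(ValueError, match="threshold"):
            gamma_map(v, v, c)

    def test_zero_normalization(self):
        z = VolumeGrid(np.zeros((8, 8, 8)), (2, 2, 2))
        with pytest.raises(ValueError, match="zero|compare"):
            gamma_map(z, z, GammaCriteria(2, 2, 10))

    def test_brute_force_grid_size_limit(self):
        big = VolumeGrid(np.ones((40, 40, 40)), (2, 2, 2))
        with pytest.raises(ValueError, match="too large"):
            brute_force_gamma(big, big)

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            GammaCriteria(dd_pct=0.0)
        with pytest.raises(ValueError):
            GammaCriteria(threshold_pct=100.0)
        with pytest.raises(ValueError):
            GammaCriteria(normalization="prescription")


class TestPassRateTable:
    def _frame(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["plan_id", "size_class",
                                           "location_class", "criterion",
                                           "pass_rate"])

    def test_two_plans_mean_and_sd(self):
        df = self._frame([(0, "small", "apex", "2%/2mm", 98.0),
                          (1, "small", "ribs", "2%/2mm", 100.0)])
        out = pass_rate_table(df)
        total = out[out.group == "total"].iloc[0]
        assert total["mean_2%/2mm"] == pytest.approx(99.0)
        assert total["sd_2%/2mm"] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_single_plan_sd_flagged_zero(self):
        df = self._frame([(0, "medium", "spine", "2%/2mm", 99.0)])
        out = pass_rate_table(df)
        row = out[out.group == "medium"].iloc[0]
        assert row["sd_2%/2mm"] == 0.0
        assert "SD undefined" in row["flag"]

    def test_identical_plans_all_criteria_100(self):
        rows = [(i, "large", "apex", c, 100.0)
                for i in range(3) for c in ("1%/1mm", "2%/2mm", "3%/3mm")]
        out = pass_rate_table(self._frame(rows))
        total = out[out.group == "total"].iloc[0]
        for c in ("1%/1mm", "2%/2mm", "3%/3mm"):
            assert total[f"mean_{c}"] == 100.0 and total[f"sd_{c}"] == 0.0
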