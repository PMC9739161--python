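"""The four service models against element-wise and closed-form oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
import sympy

from conftest import make_catraster, make_raster

from ecoisland import services as svc
from ecoisland.grid import GridSpec, Raster


def const_raster(v, shape=(3, 3)):
    return make_raster(np.full(shape, float(v)))


class TestWaterRetention:
    def test_direct_arithmetic(self):
        q = svc.water_retention(const_raster(2000), const_raster(800),
                                const_raster(900))
        np.testing.assert_allclose(q.values, 300.0)

    def test_balanced_inputs_give_zero(self):
        p = const_raster(1500)
        q = svc.water_retention(p, const_raster(600), const_raster(900))
        np.testing.assert_allclose(q.values, 0.0)

    def test_random_rasters_elementwise(self):
        rng = np.random.default_rng(0)
        p, r, et = (make_raster(rng.random((5, 5)) * 2000) for _ in range(3))
        q = svc.water_retention(p, r, et)
        np.testing.assert_array_equal(q.values, p.values - r.values - et.values)

    def test_negatives_retained_and_reported(self):
        q = svc.water_retention(const_raster(100), const_raster(80),
                                const_raster(90))
        assert (q.values < 0).all()
        assert svc.negative_fraction(q) == 1.0

    def test_nodata_propagates(self):
        p = make_raster([[2000.0, -9999.0]])
        q = svc.water_retention(p, make_raster([[100.0, 100.0]]),
                                make_raster([[100.0, 100.0]]))
        assert not q.mask[0, 1]


class TestRunoff:
    def test_zero_coefficient_zero_runoff(self):
        lu = make_catraster(np.full((3, 3), 2, dtype=int))
        r = svc.runoff_from_coefficients(const_raster(1000), lu, {2: 0.0})
        np.testing.assert_allclose(r.values, 0.0)

    def test_unit_coefficient_returns_precipitation(self):
        lu = make_catraster(np.full((3, 3), 5, dtype=int))
        p = const_raster(1234)
        r = svc.runoff_from_coefficients(p, lu, {5: 1.0})
        np.testing.assert_allclose(r.values, p.values)
        # limit: water retention collapses to -ET
        et = const_raster(700)
        q = svc.water_retention(p, r, et)
        np.testing.assert_allclose(q.values, -et.values)

    def test_default_table_per_class_means(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(1, 7, size=(10, 10))
        lu = make_catraster(codes, legend={i: str(i) for i in range(1, 7)})
        p = make_raster(rng.random((10, 10)) * 1000 + 1000)
        table = svc.ServiceParams().runoff_coeffs
        r = svc.runoff_from_coefficients(p, lu, table)
        for cls, coeff in table.items():
            sel = codes == cls
            if sel.any():
                np.testing.assert_allclose(r.values[sel], coeff * p.values[sel])

    def test_missing_class_rejected(self):
        lu = make_catraster([[1, 2]], legend={1: "a", 2: "b"})
        with pytest.raises(KeyError):
            svc.runoff_from_coefficients(const_raster(1, (1, 2)), lu, {1: 0.3})

    def test_out_of_range_coefficient_rejected(self):
        lu = make_catraster([[1]])
        with pytest.raises(ValueError):
            svc.runoff_from_coefficients(const_raster(1, (1, 1)), lu, {1: 1.2})


class TestHargreaves:
    @staticmethod
    def monthly(tmin, tmax, shape=(1, 1)):
        return ([const_raster(tmin, shape) for _ in range(12)],
                [const_raster(tmax, shape) for _ in range(12)])

    def test_zero_range_gives_zero_pet(self):
        tn, tx = self.monthly(25.0, 25.0)
        pet = svc.hargreaves_pet(tn, tx, latitude=19.0)
        np.testing.assert_allclose(pet.values, 0.0)

    def test_monotone_in_mean_temperature(self):
        tn1, tx1 = self.monthly(20.0, 28.0)
        tn2, tx2 = self.monthly(22.0, 30.0)   # same range, warmer mean
        p1 = svc.hargreaves_pet(tn1, tx1, latitude=19.0)
        p2 = svc.hargreaves_pet(tn2, tx2, latitude=19.0)
        assert (p2.values > p1.values).all()

    def test_tmax_below_tmin_rejected(self):
        tn, tx = self.monthly(25.0, 20.0)
        with pytest.raises(ValueError):
            svc.hargreaves_pet(tn, tx, latitude=19.0)

    def test_single_cell_worked_case(self):
        # independent step-by-step evaluation at 19 deg N, fixed temperatures
        lat = 19.0
        tmin, tmax = 20.0, 30.0
        days = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
        doys = [15, 46, 74, 105, 135, 162, 198, 228, 258, 288, 318, 344]
        phi = math.radians(lat)
        total = 0.0
        for d, nd in zip(doys, days):
            dr = 1 + 0.033 * math.cos(2 * math.pi * d / 365)
            dec = 0.409 * math.sin(2 * math.pi * d / 365 - 1.39)
            ws = math.acos(-math.tan(phi) * math.tan(dec))
            ra = (24 * 60 / math.pi) * 0.0820 * dr * (
                ws * math.sin(phi) * math.sin(dec)
                + math.cos(phi) * math.cos(dec) * math.sin(ws))
            total += 0.0023 * (0.408 * ra) * (25.0 + 17.8) * math.sqrt(10.0) * nd
        tn, tx = self.monthly(tmin, tmax)
        pet = svc.hargreaves_pet(tn, tx, latitude=lat)
        assert pet.values[0, 0] == pytest.approx(total, rel=1e-12)


class TestRusleFactors:
    def test_flat_dem_floor_values(self):
        dem = const_raster(100.0, (6, 6))
        l, s = svc.ls_factors(dem)
        np.testing.assert_allclose(s.values, 0.03)
        np.testing.assert_allclose(l.values, 1.0)

    def test_full_cover_c_at_floor(self):
        params = svc.ServiceParams()
        ndvi = const_raster(params.ndvi_veg, (2, 2))
        c = svc.cover_factor(ndvi, params.ndvi_soil, params.ndvi_veg,
                             params.c_decay)
        np.testing.assert_allclose(c.values, math.exp(-params.c_decay))

    def test_bare_soil_c_is_one(self):
        c = svc.cover_factor(const_raster(0.05, (2, 2)))
        np.testing.assert_allclose(c.values, 1.0)

    def test_erosivity_single_cell_oracle(self):
        # independent evaluation of the Wischmeier monthly sum
        monthly = np.linspace(40, 260, 12)
        annual = monthly.sum()
        want = sum(1.735 * 10 ** (1.5 * math.log10(p * p / annual) - 0.8188)
                   for p in monthly)
        stack = np.array([np.full((1, 1), p) for p in monthly])
        r = svc.rainfall_erosivity(stack, GridSpec(1, 1, 30.0))
        assert r.values[0, 0] == pytest.approx(want, rel=1e-12)

    def test_erodibility_single_cell_oracle(self):
        san, sil, cla, oc = 40.0, 35.0, 25.0, 1.8
        sn1 = 1 - san / 100
        want = 0.1317 * (
            (0.2 + 0.3 * math.exp(-0.0256 * san * (1 - sil / 100)))
            * (sil / (cla + sil)) ** 0.3
            * (1 - 0.25 * oc / (oc + math.exp(3.72 - 2.95 * oc)))
            * (1 - 0.7 * sn1 / (sn1 + math.exp(-5.51 + 22.9 * sn1))))
        k = svc.soil_erodibility(const_raster(san, (1, 1)),
                                 const_raster(sil, (1, 1)),
                                 const_raster(cla, (1, 1)),
                                 const_raster(oc, (1, 1)))
        assert k.values[0, 0] == pytest.approx(want, rel=1e-12)

    def test_slope_segments(self):
        # 5 % slope -> gentle segment; 20 % -> steep segment
        for slope, expect_steep in ((0.05, False), (0.20, True)):
            dem_vals = np.outer(np.arange(6) * slope * 30.0, np.ones(6))
            _, s = svc.ls_factors(make_raster(dem_vals))
            theta = math.atan(slope)
            want = (16.8 * math.sin(theta) - 0.5 if expect_steep
                    else 10.8 * math.sin(theta) + 0.03)
            assert s.values[2, 2] == pytest.approx(want, rel=1e-9)


class TestSoilLoss:
    @staticmethod
    def random_factors(seed=0, shape=(4, 4)):
        rng = np.random.default_rng(seed)
        return svc.RusleFactors(
            r=make_raster(rng.random(shape) * 300),
            k=make_raster(rng.random(shape) * 0.05),
            l=make_raster(1 + rng.random(shape)),
            s=make_raster(rng.random(shape) * 3),
            c=make_raster(rng.random(shape)),
            p=make_raster(rng.random(shape)),
        )

    def test_product_oracle(self):
        f = svc.RusleFactors(*(const_raster(v, (1, 1)) for v in
                               (100, 0.3, 1.2, 2, 0.2, 0.5)))
        a = svc.soil_loss_actual(f)
        assert a.values[0, 0] == pytest.approx(100 * 0.3 * 1.2 * 2 * 0.2 * 0.5)

    def test_any_zero_factor_zeroes_loss(self):
        f = self.random_factors()
        f.c = make_raster(np.zeros((4, 4)))
        np.testing.assert_allclose(svc.soil_loss_actual(f).values, 0.0)

    def test_full_cover_no_practice_equals_potential(self):
        f = self.random_factors()
        f.c = make_raster(np.ones((4, 4)))
        f.p = make_raster(np.ones((4, 4)))
        np.testing.assert_allclose(svc.soil_loss_actual(f).values,
                                   svc.soil_loss_potential(f).values)
        np.testing.assert_allclose(svc.soil_conservation(f).values, 0.0)

    def test_zero_cover_conserves_everything(self):
        f = self.random_factors()
        f.c = make_raster(np.zeros((4, 4)))
        np.testing.assert_allclose(svc.soil_conservation(f).values,
                                   svc.soil_loss_potential(f).values)

    def test_conservation_is_potential_minus_actual(self):
        f = self.random_factors(seed=5)
        ape = svc.soil_loss_potential(f).values
        aae = svc.soil_loss_actual(f).values
        np.testing.assert_allclose(svc.soil_conservation(f).values, ape - aae,
                                   rtol=1e-12)

    def test_non_negative_given_cp_bounds(self):
        for seed in range(10):
            f = self.random_factors(seed)
            assert (svc.soil_conservation(f).values >= -1e-12).all()


class TestCarbonOxygen:
    def test_zero_radiation_zero_npp(self):
        npp = svc.casa_npp(const_raster(0.8), const_raster(0.0),
                           const_raster(24.0), const_raster(0.6))
        np.testing.assert_allclose(npp.values, 0.0)

    def test_sparse_ndvi_zero_npp(self):
        params = svc.ServiceParams()
        npp = svc.casa_npp(const_raster(params.ndvi_min - 0.01),
                           const_raster(5000.0), const_raster(24.0),
                           const_raster(0.6), params)
        np.testing.assert_allclose(npp.values, 0.0)

    def test_single_cell_oracle_through_scalars(self):
        params = svc.ServiceParams()
        ndvi, srad, t, ws = 0.5, 5000.0, 24.0, 0.6
        fpar = min(max((ndvi - params.ndvi_min)
                       / (params.ndvi_max - params.ndvi_min), 0.0), 1.0) \
            * params.fpar_max
        apar = srad * fpar * 0.5
        topt = params.t_opt
        ts1 = 0.8 + 0.02 * topt - 0.0005 * topt**2
        ts2 = 1.1814 / ((1 + math.exp(0.2 * (topt - 10 - t)))
                        * (1 + math.exp(0.3 * (-topt - 10 + t))))
        eps = params.eps_max * ts1 * ts2 * (0.5 + 0.5 * ws)
        npp = svc.casa_npp(const_raster(ndvi, (1, 1)),
                           const_raster(srad, (1, 1)),
                           const_raster(t, (1, 1)),
                           const_raster(ws, (1, 1)), params)
        assert npp.values[0, 0] == pytest.approx(apar * eps, rel=1e-12)

    def test_negative_radiation_rejected(self):
        with pytest.raises(ValueError):
            svc.casa_npp(const_raster(0.5), const_raster(-1.0),
                         const_raster(24.0), const_raster(0.5))

    def test_soil_respiration_worked_value_sympy(self):
        # arbitrary-precision evaluation of the printed formula
        t, p, bd, h, delta = 24, sympy.Rational(3, 2), sympy.Rational(13, 10), 20, 30
        w = sympy.Rational(58, 100) * bd * h * (1 - sympy.Rational(delta, 100)) / 10
        rs_exact = (sympy.Rational(155, 100) * sympy.exp(sympy.Rational(31, 1000) * t)
                    * p / (p + sympy.Rational(68, 100)) * w / (w + sympy.Rational(223, 100)))
        got = svc.soil_respiration(24.0, 1.5, 1.3, 20.0, 30.0)
        assert got == pytest.approx(float(rs_exact.evalf(30)), rel=1e-12)

    def test_soil_respiration_monotone_in_t_and_p(self):
        assert svc.soil_respiration(-50.0, 1.5, 1.3) < \
            svc.soil_respiration(0.0, 1.5, 1.3)
        assert svc.soil_respiration(24.0, 1.0, 1.3) < \
            svc.soil_respiration(24.0, 2.0, 1.3)

    def test_full_coarse_fraction_kills_respiration(self):
        assert svc.soil_respiration(24.0, 1.5, 1.3, 20.0, 100.0) == 0.0

    def test_heterotrophic_power_law(self):
        assert svc.heterotrophic_respiration(0.0) == 0.0
        assert svc.heterotrophic_respiration(1.0) == pytest.approx(0.592)
        assert svc.heterotrophic_respiration(2.0) == \
            pytest.approx(0.592 * 2**0.714, rel=1e-12)
        with pytest.raises(ValueError):
            svc.heterotrophic_respiration(-0.1)

    def test_rh_monotone_in_rs(self):
        rs = np.linspace(0, 5, 50)
        rh = svc.heterotrophic_respiration(rs)
        assert (np.diff(rh) > 0).all()

    def test_nep_signs_and_oracle(self):
        rng = np.random.default_rng(2)
        npp = make_raster(rng.random((4, 4)) * 1000)
        rh = make_raster(rng.random((4, 4)) * 100)
        out = svc.nep(npp, rh)
        np.testing.assert_array_equal(out.values, npp.values - rh.values)
        zero = svc.nep(make_raster(np.zeros((2, 2))), make_raster(np.ones((2, 2))))
        assert (zero.values <= 0).all()

    def test_oxygen_release_stated_coefficient_and_linearity(self):
        assert svc.oxygen_release(const_raster(100.0)).values[0, 0] == \
            pytest.approx(119.0)
        a = const_raster(50.0)
        b = const_raster(70.0)
        qa = svc.oxygen_release(a).values
        qb = svc.oxygen_release(b).values
        qab = svc.oxygen_release(const_raster(120.0)).values
        np.testing.assert_allclose(qab, qa + qb)
        with pytest.raises(ValueError):
            svc.oxygen_release(const_raster(-1.0))


class TestIslandTotals:
    def test_one_mm_on_one_km2(self):
        # 1 mm over 1 km2 -> 1000 m3
        spec_vals = np.full((10, 10), 1.0)     # 10x10 cells of 100 m
        layer = make_raster(spec_vals, cell_size=100.0)
        stack = svc.island_totals([layer], "water_retention", [1980])
        assert stack.totals[0] * 1e9 == pytest.approx(1000.0)

    def test_soil_unit_conversion(self):
        # 1 t/ha on one 100 m cell (1 ha) -> 1 t
        layer = make_raster([[1.0]], cell_size=100.0)
        stack = svc.island_totals([layer], "soil_conservation", [1980])
        assert stack.totals[0] * 1e9 == pytest.approx(1.0)

    def test_carbon_unit_conversion(self):
        # 1 g/m2 over 1 km2 -> 1 t
        layer = make_raster(np.full((10, 10), 1.0), cell_size=100.0)
        stack = svc.island_totals([layer], "carbon_sequestration", [1980])
        assert stack.totals[0] * 1e6 == pytest.approx(1.0)

    def test_random_stack_accumulation_oracle(self):
        rng = np.random.default_rng(4)
        layers = [make_raster(rng.random((5, 5)) * 500, cell_size=30.0)
                  for _ in range(3)]
        layers[0].values[0, 0] = -9999.0
        stack = svc.island_totals(layers, "water_retention", [1980, 1990, 1995])
        for layer, total in zip(layers, stack.totals):
            acc = sum(layer.values[r, c] for r in range(5) for c in range(5)
                      if layer.values[r, c] != -9999.0)
            assert total == pytest.approx(acc * 1e-3 * 900.0 / 1e9)

    def test_change_is_last_minus_first(self):
        st = svc.ingest_totals("water_retention", [1, 2, 3], [10.0, 12.0, 9.0])
        assert st.change == pytest.approx(-1.0)
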