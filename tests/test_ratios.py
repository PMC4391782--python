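import numpy as np
import pytest

import mineralmap as mm
from mineralmap.ratios import (bicolor_overlay, density_plot, line_profile,
                               map_math, masked_stats, md_vs_ratio_correlation,
                               ratio_with_denominator)


def emap(data, element="Ca", units="mmol/cm3", **kw):
    return mm.ElementMap(element=element, data=np.asarray(data, dtype=float),
                         units=units, **kw)


class TestMapMath:
    def test_stoichiometric_apatite_ratio(self):
        ca = emap(np.full((4, 4), 10.0))
        p = emap(np.full((4, 4), 6.0), element="P")
        rm = map_math(ca, p, "/")
        assert np.allclose(rm.data, 10.0 / 6.0)
        assert rm.valid.all()

    def test_self_division_is_one(self):
        ca = emap(np.random.default_rng(0).uniform(1, 5, (4, 4)))
        rm = map_math(ca, ca, "/")
        assert np.allclose(rm.data[rm.valid], 1.0)

    def test_zero_denominator_invalid_and_excluded(self):
        ca = emap(np.ones((2, 2)))
        p = emap(np.array([[1.0, 0.0], [1.0, 1.0]]), element="P")
        rm = map_math(ca, p, "/")
        assert rm.valid.sum() == 3
        st = masked_stats(rm)
        assert st.n_pixels == 3

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            map_math(emap(np.ones((2, 2))), emap(np.ones((2, 2)), units="counts"))

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            map_math(emap(np.ones((2, 2))), emap(np.ones((3, 3))))

    def test_add_subtract_multiply(self):
        a = emap(np.full((2, 2), 4.0))
        b = emap(np.full((2, 2), 2.0), element="P")
        assert np.all(map_math(a, b, "+").data == 6.0)
        assert np.all(map_math(a, b, "-").data == 2.0)
        assert np.all(map_math(a, b, "*").data == 8.0)


class TestMaskedStats:
    def test_constant_field_methods_agree(self):
        ca = emap(np.full((4, 4), 3.0))
        p = emap(np.full((4, 4), 2.0), element="P")
        rm = ratio_with_denominator(ca, p)
        m1 = masked_stats(rm, method="mean-of-ratios")
        m2 = masked_stats(rm, method="ratio-of-means")
        assert m1.mean == pytest.approx(1.5)
        assert m2.mean == pytest.approx(1.5)
        assert m1.sd == 0.0

    def test_two_valued_mean_of_ratios(self):
        data = np.ones((2, 2))
        data[0] = 3.0
        rm = map_math(emap(data), emap(np.ones((2, 2)), element="P"), "/")
        assert masked_stats(rm, method="mean-of-ratios").mean == pytest.approx(2.0)

    def test_ratio_of_means_uses_denominator_weights(self):
        ca = emap(np.array([[2.0, 8.0]]))
        p = emap(np.array([[1.0, 2.0]]), element="P")
        rm = ratio_with_denominator(ca, p)
        st = masked_stats(rm, method="ratio-of-means")
        assert st.mean == pytest.approx((2.0 + 8.0) / (1.0 + 2.0))

    def test_all_invalid_mask_rejected(self):
        rm = map_math(emap(np.ones((2, 2))), emap(np.zeros((2, 2)), element="P"), "/")
        with pytest.raises(ValueError, match="valid"):
            masked_stats(rm)

    def test_generator_ratio_recovery_within_spread(self):
        """Noisy dentin-like maps: masked mean within 2 sd of the generator ratio."""
        spec = mm.ElementFieldSpec(shape=(128, 128), noise_cv=0.10, scene={
            "kind": "uniform", "ratio_ca_p": 1.49, "ratio_ca_p_sd": 0.21})
        maps, _ = mm.make_xrf_maps(spec, seed=12, elements=("Ca", "P"))
        q = mm.quantify_xrf(maps, {el: mm.default_standard(el) for el in maps},
                            mm.default_context())
        st = masked_stats(mm.ratio_map(q, "Ca", "P"))
        assert st.mean == pytest.approx(1.49, abs=2 * 0.21)


class TestDensityPlot:
    def test_proportional_maps_single_peak_spread(self):
        rng = np.random.default_rng(1)
        a = emap(rng.normal(10.0, 0.5, (64, 64)))
        b = emap(a.data / 1.5, element="P")
        dp = density_plot(a, b, bins=16)
        assert dp.character == "spread"
        assert len(dp.peaks) == 1
        assert dp.counts.sum() == a.data.size

    def test_bimodal_mixture_two_peaks_localized(self):
        rng = np.random.default_rng(2)
        a = np.concatenate([rng.normal(2.0, 0.05, 2000),
                            rng.normal(8.0, 0.05, 2000)]).reshape(40, 100)
        b = np.ones_like(a)
        dp = density_plot(emap(a), emap(b, element="P"), bins=16)
        assert dp.character == "localized"
        assert len(dp.peaks) == 2

    def test_counts_conserved_under_mask(self):
        rng = np.random.default_rng(3)
        a = emap(rng.random((16, 16)))
        b = emap(rng.random((16, 16)), element="P")
        mask = rng.random((16, 16)) > 0.4
        dp = density_plot(a, b, mask=mask, bins=8)
        assert dp.counts.sum() == mask.sum()

    def test_inputs_not_modified(self):
        a = emap(np.arange(16.0).reshape(4, 4))
        b = emap(np.arange(16.0).reshape(4, 4) + 1.0, element="P")
        before = (a.data.copy(), b.data.copy())
        density_plot(a, b, bins=4)
        bicolor_overlay(a, b)
        assert np.array_equal(a.data, before[0]) and np.array_equal(b.data, before[1])


class TestBicolorOverlay:
    def test_zero_second_map_pure_first_channel(self):
        a = emap(np.linspace(0, 1, 16).reshape(4, 4))
        b = emap(np.zeros((4, 4)), element="Zn")
        rgb, meta = bicolor_overlay(a, b)
        assert np.all(rgb[..., 0] == 0.0)  # red channel (Zn) empty
        assert rgb[..., 2].max() > 0  # blue channel (Ca) populated
        assert meta["normalization"]["Ca"]["channel"] == "blue"

    def test_identical_maps_equal_channels(self):
        a = emap(np.linspace(0, 1, 16).reshape(4, 4))
        b = emap(a.data.copy(), element="Zn")
        rgb, _ = bicolor_overlay(a, b)
        assert np.allclose(rgb[..., 0], rgb[..., 2])

    def test_band_pattern_lands_in_red_channel(self):
        spec = mm.ElementFieldSpec(shape=(64, 64), noise_cv=0.0, scene={
            "kind": "bands", "axis": 0, "period_px": 16,
            "rich": {"ratio_ca_zn": 595.0}, "poor": {"ratio_ca_zn": 1155.0}})
        maps, _ = mm.make_xrf_maps(spec, elements=("Ca", "Zn"))
        rgb, _ = bicolor_overlay(
            emap(maps["Ca"].data), emap(maps["Zn"].data, element="Zn"))
        col = rgb[:, 0, 0]  # red channel down a column crosses the bands
        assert np.array_equal(col[:16], col[16:32])
        assert np.ptp(col[:16]) > 0


class TestLineProfile:
    def test_constant_map_flat(self):
        prof = line_profile(emap(np.full((8, 8), 5.0)), [(0, 0), (7, 7)])
        assert np.allclose(prof.to_numpy(), 5.0)

    def test_ramp_linear(self):
        data = np.broadcast_to(np.arange(16.0), (4, 16)).copy()
        prof = line_profile(emap(data, pixel_size_um=1000.0), [(1, 0), (1, 15)])
        # pixel pitch 1 mm: value equals distance in mm
        assert np.allclose(prof.to_numpy(), prof.index.to_numpy())

    def test_banded_map_periodic(self):
        spec = mm.ElementFieldSpec(shape=(64, 8), noise_cv=0.0, scene={
            "kind": "bands", "axis": 0, "period_px": 16,
            "rich": {"ratio_ca_zn": 595.0}, "poor": {"ratio_ca_zn": 1155.0}})
        maps, _ = mm.make_xrf_maps(spec, elements=("Zn",))
        prof = line_profile(maps["Zn"], [(0, 4), (63, 4)]).to_numpy()
        assert np.allclose(prof[:16], prof[16:32])

    def test_polyline_outside_raster_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            line_profile(emap(np.zeros((4, 4))), [(0, 0), (10, 10)])


class TestMdVsRatioCorrelation:
    def test_collinear_points_r_one(self):
        pts = [("a", 100.0, 1.0), ("b", 200.0, 2.0), ("c", 300.0, 3.0)]
        fit = md_vs_ratio_correlation(pts)
        assert fit["r"] == pytest.approx(1.0)
        assert np.allclose(fit["points"]["residual"], 0.0, atol=1e-9)

    def test_constant_ratio_zero_slope(self):
        pts = [("a", 100.0, 1.5), ("b", 200.0, 1.5), ("c", 300.0, 1.5)]
        fit = md_vs_ratio_correlation(pts)
        assert fit["slope"] == 0.0 and fit["r"] == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="three"):
            md_vs_ratio_correlation([("a", 1.0, 1.0), ("b", 2.0, 2.0)])

    def test_tissue_panel_positive_correlation(self):
        """Mean MD vs Ca/P across dentin zones and normal tissues rises."""
        pts = [("lesion_zone_1", 500.0, 0.32),
               ("lesion_zone_2", 800.0, 0.46),
               ("bone", 1115.0, 1.68),
               ("cementum", 1290.0, 1.51),
               ("dentin", 1535.0, 1.49)]
        fit = md_vs_ratio_correlation(pts)
        assert fit["r"] > 0.5
        assert fit["slope"] > 0
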