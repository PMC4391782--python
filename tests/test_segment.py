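import numpy as np
import pytest

import mineralmap as mm
from mineralmap.segment import (DentinZoneClass, SeedLocus, flood_from_markers,
                                gradient_magnitude, histogram2d, locus_markers,
                                segment_stats, select_seed_loci, slice_profile,
                                watershed_segment)

from conftest import oracle_flood, random_flood_case


class TestGradientMagnitude:
    def test_constant_volume_zero(self):
        assert np.all(gradient_magnitude(np.full((4, 4, 4), 3.0)) == 0.0)

    @pytest.mark.parametrize("method", ["central", "sobel"])
    def test_linear_ramp_interior_slope(self, method):
        z = np.arange(8, dtype=float) * 2.5
        vol = np.broadcast_to(z[:, None, None], (8, 8, 8)).copy()
        g = gradient_magnitude(vol, method=method)
        assert np.allclose(g[1:-1], 2.5)

    def test_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(1)
        vol = rng.random((4, 4, 4))
        g = gradient_magnitude(vol)
        # brute force: per-voxel central difference on the edge-padded array
        pad = np.pad(vol, 1, mode="edge")
        for z in range(4):
            for y in range(4):
                for x in range(4):
                    dz = (pad[z + 2, y + 1, x + 1] - pad[z, y + 1, x + 1]) / 2
                    dy = (pad[z + 1, y + 2, x + 1] - pad[z + 1, y, x + 1]) / 2
                    dx = (pad[z + 1, y + 1, x + 2] - pad[z + 1, y + 1, x]) / 2
                    assert g[z, y, x] == pytest.approx(np.sqrt(dz**2 + dy**2 + dx**2))

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError):
            gradient_magnitude(np.zeros((1, 4, 4)))


class TestHistogram2D:
    def test_constant_volume_single_bin(self):
        vol = np.full((4, 4, 4), 5.0)
        h = histogram2d(vol, gradient_magnitude(vol), bins=(8, 8))
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 64

    def test_counts_conserved_under_mask(self):
        rng = np.random.default_rng(2)
        vol = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.5
        h = histogram2d(vol, gradient_magnitude(vol), bins=(16, 8), mask=mask)
        assert h.counts.sum() == mask.sum()

    def test_two_plateaus_occupy_two_low_gradient_columns(self):
        vol = np.zeros((8, 8, 8))
        vol[4:] = 100.0
        h = histogram2d(vol, gradient_magnitude(vol), bins=(10, 4))
        low_grad = h.counts[:, 0]
        assert (low_grad > 0).sum() == 2  # the two material modes
        assert h.counts[:, 1:].sum() > 0  # interface voxels at high gradient

    def test_empty_mask_rejected(self):
        vol = np.zeros((4, 4, 4))
        with pytest.raises(ValueError, match="mask"):
            histogram2d(vol, gradient_magnitude(vol), mask=np.zeros_like(vol, bool))


class TestSeedLoci:
    def test_single_material_one_locus(self):
        vol = np.full((8, 8, 8), 42.0)
        h = histogram2d(vol, gradient_magnitude(vol), bins=(16, 4))
        loci = select_seed_loci(h)
        assert len(loci) == 1

    def test_two_plateaus_bracketed(self):
        rng = np.random.default_rng(3)
        vol = np.where(np.arange(16)[:, None, None] < 8, 0.0, 100.0) \
            + rng.normal(0, 1.0, (16, 16, 16))
        h = histogram2d(vol, gradient_magnitude(vol), bins=(64, 16))
        loci = select_seed_loci(h, min_mass_frac=1e-3)
        assert len(loci) == 2
        lo, hi = sorted(loci, key=lambda l: l.intensity_lo)
        assert lo.intensity_lo <= 0.0 <= lo.intensity_hi
        assert hi.intensity_lo <= 100.0 <= hi.intensity_hi

    def test_manual_boxes_validated(self):
        vol = np.full((4, 4, 4), 1.0)
        h = histogram2d(vol, gradient_magnitude(vol))
        a = SeedLocus(1, 0.0, 2.0, 0.0, 1.0)
        b = SeedLocus(2, 1.0, 3.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="overlap"):
            select_seed_loci(h, mode="manual", boxes=[a, b])

    def test_manual_equals_auto_downstream(self):
        rng = np.random.default_rng(4)
        vol = np.where(np.arange(16)[:, None, None] < 8, 0.0, 100.0) \
            + rng.normal(0, 1.0, (16, 16, 16))
        g = gradient_magnitude(vol)
        h = histogram2d(vol, g, bins=(64, 16))
        auto = select_seed_loci(h, min_mass_frac=1e-3)
        manual = select_seed_loci(h, mode="manual", boxes=auto)
        la = watershed_segment(vol, auto, gradmag=g)
        lb = watershed_segment(vol, manual, gradmag=g)
        assert np.array_equal(la.labels, lb.labels)


class TestWatershed:
    def test_single_locus_labels_everything(self):
        vol = np.full((4, 4, 4), 10.0)
        lm = watershed_segment(vol, [SeedLocus(1, 9.0, 11.0, -0.5, 0.5)])
        assert np.all(lm.labels == 1)

    def test_1d_two_basin_boundary_at_crest(self):
        """Profile 1,1,5,1,1: flooding from each basin splits at the crest."""
        land = np.array([1.0, 1.0, 5.0, 1.0, 1.0]).reshape(1, 1, 5)
        markers = np.zeros_like(land, dtype=np.int32)
        markers[0, 0, 0] = 1
        markers[0, 0, 4] = 2
        labels = flood_from_markers(land, markers)
        assert list(labels.ravel()) == [1, 1, 1, 2, 2]  # crest claimed by earliest push
        assert np.array_equal(labels, oracle_flood(land, markers))

    def test_partition_of_mask(self):
        rng = np.random.default_rng(5)
        land, markers, mask = random_flood_case(rng)
        labels = flood_from_markers(rng.random(land.shape), markers, mask)
        reachable = oracle_flood(np.zeros(land.shape), markers, mask) > 0
        assert np.all((labels > 0) == ((mask) & reachable))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        land, markers, mask = random_flood_case(rng, max_voxels=400)
        assert np.array_equal(flood_from_markers(land, markers, mask),
                              oracle_flood(land, markers, mask))

    def test_offset_invariance(self):
        """Adding a constant shifts segment means but not labels."""
        rng = np.random.default_rng(6)
        vol = np.where(np.arange(12)[:, None, None] < 6, 0.0, 100.0) \
            + rng.normal(0, 1.0, (12, 12, 12))
        g = gradient_magnitude(vol)
        h = histogram2d(vol, g, bins=(64, 16))
        loci = select_seed_loci(h, min_mass_frac=1e-3)
        lm1 = watershed_segment(vol, loci, gradmag=g)
        shifted = [SeedLocus(l.locus_id, l.intensity_lo + 77.0, l.intensity_hi + 77.0,
                             l.gradient_lo, l.gradient_hi) for l in loci]
        lm2 = watershed_segment(vol + 77.0, shifted,
                                gradmag=gradient_magnitude(vol + 77.0))
        assert np.array_equal(lm1.labels, lm2.labels)
        line = mm.CalibrationModel(slope=1.0, intercept=0.0)
        s1 = segment_stats(lm1, vol, line)
        s2 = segment_stats(lm2, vol + 77.0, line)
        for a, b in zip(s1, s2):
            assert b.mean_hu == pytest.approx(a.mean_hu + 77.0)

    def test_empty_marker_locus_named(self):
        vol = np.full((4, 4, 4), 10.0)
        with pytest.raises(ValueError, match="locus 3"):
            locus_markers(vol, gradient_magnitude(vol),
                          [SeedLocus(3, 100.0, 200.0, 0.0, 1.0)])


class TestSegmentStats:
    def test_constant_region(self, true_line):
        vol = np.full((4, 4, 4), 12169.0909090909)
        labels = mm.LabelMap(labels=np.ones(vol.shape, dtype=np.int32))
        (st,) = segment_stats(labels, vol, true_line, voxel_size_um=3.84)
        assert st.mean_hu == pytest.approx(12169.0909090909)
        assert st.sd_hu == pytest.approx(0.0, abs=1e-9)
        assert st.mean_md == pytest.approx(1290.0)
        assert st.volume_mm3 == pytest.approx(64 * (3.84e-3) ** 3)

    def test_partition_counts_sum(self, true_line):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        labels[2:] = 2
        sts = segment_stats(mm.LabelMap(labels=labels), np.zeros((4, 4, 4)), true_line)
        assert sum(s.n_voxels for s in sts) == 64

    def test_sd_converts_by_abs_slope(self, true_line):
        rng = np.random.default_rng(7)
        vol = rng.normal(10000.0, 100.0, (6, 6, 6))
        labels = mm.LabelMap(labels=np.ones(vol.shape, dtype=np.int32))
        (st,) = segment_stats(labels, vol, true_line)
        assert st.sd_md == pytest.approx(abs(true_line.slope) * st.sd_hu)

    def test_noise_free_two_region_means_exact(self, quiet_acq, true_line):
        spec = mm.TissuePhantomSpec(shape=(16, 16, 16), regions=[
            mm.RegionSpec(1, {"kind": "box", "lo": (0, 0, 0), "hi": (0.5, 1, 1)},
                          md_mean=897.5),
            mm.RegionSpec(2, {"kind": "box", "lo": (0.5, 0, 0), "hi": (1, 1, 1)},
                          md_mean=1535.0)])
        vol, gt = mm.make_tissue_volume(spec, acq=quiet_acq)
        hu = mm.scale_to_hu(vol, quiet_acq.air_intensity, quiet_acq.water_intensity)
        sts = segment_stats(mm.LabelMap(labels=gt.labels), hu, true_line)
        assert sts[0].mean_md == pytest.approx(897.5, abs=1e-9)
        assert sts[1].mean_md == pytest.approx(1535.0, abs=1e-9)


class TestSliceProfile:
    def test_constant_flat(self):
        prof = slice_profile(np.full((5, 3, 3), 2.0))
        assert np.allclose(prof, 2.0)

    def test_step_two_levels(self):
        vol = np.zeros((8, 3, 3))
        vol[4:] = 9.0
        prof = slice_profile(vol)
        assert list(prof) == [0.0] * 4 + [9.0] * 4


class TestDentinZones:
    @pytest.mark.parametrize("hu,zone", [
        (10000.0, "hypomineralized"),
        (14000.0, "near_normal"),
        (15500.0, "hypermineralized"),
        (3545.0, "hypomineralized"),      # lower boundary inclusive
        (13475.0, "hypomineralized"),     # upper boundary inclusive
        (13600.0, "unclassified"),        # gap between intervals
        (14900.0, "unclassified"),
    ])
    def test_boundary_probing(self, hu, zone):
        assert DentinZoneClass().classify(hu) == zone

    def test_overlapping_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DentinZoneClass(cutoffs={"a": (0.0, 10.0), "b": (5.0, 20.0)})

    def test_classify_assigns_segments(self, true_line):
        sts = [mm.SegmentStats(label_id=1, n_voxels=10, volume_mm3=1.0,
                               mean_hu=14000.0, sd_hu=0.0, mean_md=1491.4,
                               sd_md=0.0, md_min=1491.4, md_max=1491.4)]
        out = mm.classify_dentin_zones(sts)
        assert out[0].zone == "near_normal"


class TestIterativeRefinement:
    def test_distinct_plateaus_stay_separate(self, true_line):
        rng = np.random.default_rng(8)
        vol = np.where(np.arange(12)[:, None, None] < 6, 0.0, 100.0) \
            + rng.normal(0, 1.0, (12, 12, 12))
        _, sts, loci = mm.iterate_segmentation(vol, true_line, bins=(64, 16),
                                               min_mass_frac=1e-3)
        assert len(sts) == 2 and len(loci) == 2

    def test_statistically_identical_segments_merge(self, true_line):
        """Loci that split one homogeneous population (here by gradient range
        only) produce indistinguishable segments, which the acceptance loop
        merges into one."""
        rng = np.random.default_rng(9)
        vol = rng.normal(0.0, 1.0, (10, 10, 10))
        g_hi = float(gradient_magnitude(vol).max()) + 1.0
        loci = [SeedLocus(1, -5.0, 5.0, 0.0, 0.7),
                SeedLocus(2, -5.0, 5.0, 0.7001, g_hi)]
        _, sts, out_loci = mm.iterate_segmentation(vol, true_line,
                                                   initial_loci=loci,
                                                   max_sample=200)
        assert len(out_loci) == 1 and len(sts) == 1
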