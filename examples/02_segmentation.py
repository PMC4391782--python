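"""Watershed segmentation of a diseased-dentin lesion volume.

Builds a 64^3 two-region volume (hypomineralized cap over normal dentin,
50 HU noise, 1-voxel blur), seeds a watershed from the low-gradient modes of
the intensity/gradient 2D histogram, and reports per-segment mineral
statistics, dentin zone classes and the overlap with ground truth.
"""
import mineralmap as mm

calib = mm.instrument_line()
vol, gt, acq = mm.lesion_volume_case(seed=7, shape=(64, 64, 64))
labels, stats, loci = mm.segment_volume(vol, calib,
                                        air_intensity=acq.air_intensity,
                                        water_intensity=acq.water_intensity)
mm.classify_dentin_zones(stats)

print(f"auto-selected {len(loci)} seed loci:")
for l in loci:
    print(f"  locus {l.locus_id}: HU [{l.intensity_lo:.0f}, {l.intensity_hi:.0f}]")
print("segments:")
for s in stats:
    print(f"  label {s.label_id}: n={s.n_voxels}  MD {s.mean_md:.0f} +/- "
          f"{s.sd_md:.0f} mg/cc  zone={s.zone}")
for s, true_label in zip(sorted(stats, key=lambda s: s.mean_md), (1, 2)):
    dice = mm.dice_coefficient(labels.labels == s.label_id,
                               gt.labels == true_label)
    print(f"  Dice vs ground-truth region {true_label}: {dice:.3f}")
# Two segments should emerge: a hypomineralized cap (~900 mg/cc) and normal
# dentin (~1535 mg/cc); Dice near 1 means the boundary sits on the true
# interface despite noise and blur.
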