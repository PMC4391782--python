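# mineralmap

Correlative analysis of mineral density and elemental composition in
calcified tissues (alveolar bone, cementum, dentin, enamel, carious lesions,
dental calculus) from two modalities:

* **benchtop micro-CT**, which measures x-ray attenuation per ~3.84 µm voxel
  and, after phantom calibration, yields hydroxyapatite-equivalent mineral
  density (MD, mg/cc) in 3D; and
* **synchrotron microprobe XRF**, which maps per-pixel Ca, P and Zn
  fluorescence and, after standards calibration and thickness correction,
  yields volume concentrations (mmol/cm³) and molar ratios (Ca/P, Ca/Zn).

The package is for researchers who want to move beyond a single mean density
per specimen: it discretizes heterogeneous tissue volumes into statistically
distinct mineral-density segments and correlates each segment with its
elemental footprint. A synthetic-data module emulates both instruments with
known ground truth, so the entire pipeline is testable without instrument
data.

## The models

**HU convention and calibration.** Raw intensities are affinely rescaled so
air maps to 0 HU and water to 1000 HU (standard Hounsfield + 1000). Phantoms
of known density (0–3080 mg/cc) scanned alongside the specimens give an
ordinary-least-squares line

    MD(mg/cc) = a · HU + b

fitted MD-on-HU; the packaged generator's instrument line is
`a = 0.11, b = −48.6`. A gravimetric (ash) density line over the same
phantoms provides an independent check; the pipeline reports the pointwise
residual between the two lines and the Pearson correlation of their
predictions.

**Segmentation.** The joint 2D histogram of voxel intensity vs gradient
magnitude separates material phases (low-gradient modes) from interfaces
(high-gradient arches). Seed loci — rectangles over the modes, picked
automatically or by hand — initialize a marker-based watershed that floods
the gradient-magnitude landscape, placing segment boundaries on gradient
crests. Per-segment HU statistics convert to MD through the calibration
line; dentin segments are classed hypomineralized / near-normal /
hypermineralized by HU cutoffs (3 545–13 475 / 13 755–14 740 / >15 000).

**XRF quantification.** Counts ÷ thin-film-standard gain gives area
concentration (mmol/cm²); dividing by the self-absorption effective
thickness

    t_eff = (1 − exp(−µ·t)) / µ,   µ = (1/L_in)/sin θ_in + (1/L_f)/sin θ_out

(with L the absorption lengths at the incident energy and at the element's
fluorescence line) gives volume concentration (mmol/cm³). Ratio maps,
masked ROI statistics, joint-density plots, bicolor overlays and line
profiles then tie Ca/P and Ca/Zn to the segmented mineral densities.

## Worked example

```python
import mineralmap as mm

calib = mm.instrument_line()
vol, gt, acq = mm.lesion_volume_case(seed=7, shape=(64, 64, 64))
labels, stats, loci = mm.segment_volume(
    vol, calib, air_intensity=acq.air_intensity,
    water_intensity=acq.water_intensity)
mm.classify_dentin_zones(stats)
for s in stats:
    print(s.label_id, s.n_voxels, round(s.mean_md), s.zone)
```

prints

```
1 106494 906 hypomineralized
2 155650 1529 near_normal
```

i.e. the watershed recovered the two generated regions — a hypomineralized
carious cap (true mean 897.5 mg/cc) over normal dentin (true mean
1535 mg/cc) — and classed them by the HU cutoffs; the Dice overlap with the
ground-truth labels is 1.000 for both. The `examples/` directory contains
one narrative script per capability (calibration, segmentation, XRF
quantification, ratio analysis, statistics/report); each prints the numbers
it computes and a line on what they mean.

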