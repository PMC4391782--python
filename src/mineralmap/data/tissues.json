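{
  "_comment": "Default mineral-density parameters (mg/cc, hydroxyapatite-equivalent) for the mineralized tissues of the human dentoalveolar complex. md_mean/md_range are study means/ranges from calibrated benchtop micro-CT of 40-60 year-old male donors; md_sd is the voxel-level spread used by the synthetic generator, chosen so that +/-2 sd spans md_range; sem is the reported standard deviation of the tissue mean (null where not reported).",
  "tissues": {
    "enamel":                   {"md_mean": 2957.5, "md_sd": 68.75,  "md_range": [2820, 3095], "sem": null},
    "dentin":                   {"md_mean": 1535.0, "md_sd": 27.5,   "md_range": [1480, 1590], "sem": null},
    "cementum":                 {"md_mean": 1290.0, "md_sd": 25.0,   "md_range": [1240, 1340], "sem": 15.0},
    "diseased_cementum":        {"md_mean": 1150.0, "md_sd": 30.0,   "md_range": [1100, 1220], "sem": 50.0},
    "bone":                     {"md_mean": 1115.0, "md_sd": 211.25, "md_range": [570, 1415],  "sem": 30.0},
    "hypomineralized_dentin":   {"md_mean": 897.5,  "md_sd": 276.25, "md_range": [345, 1450],  "sem": null},
    "hypermineralized_dentin":  {"md_mean": 2277.5, "md_sd": 231.25, "md_range": [1815, 2740], "sem": null},
    "calculus":                 {"md_mean": 1525.0, "md_sd": 120.0,  "md_range": [1290, 1770], "sem": 40.0}
  },
  "instrument_line": {"slope": 0.11, "intercept": -48.6,
                      "_comment": "HU -> mg/cc line of the emulated benchtop unit (air = 0 HU, water = 1000 HU convention)"},
  "ash_line": {"slope": 0.11, "intercept": -17.3,
               "_comment": "gravimetric (ash) mineral density vs HU line for the same phantom set"},
  "phantom_densities_mgcc": [0, 250, 500, 747, 750, 1136, 3080],
  "acquisition": {"voxel_size_um": 3.84, "noise_sd_hu": 50.0, "blur_sigma_vox": 1.0,
                  "noise_model": "additive Gaussian in HU, applied after the PSF blur",
                  "rng": "numpy PCG64 via numpy.random.default_rng(seed)"},
  "dentin_zone_cutoffs_hu": {"hypomineralized": [3545, 13475],
                             "near_normal": [13755, 14740],
                             "hypermineralized": [15000, null]}
}
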