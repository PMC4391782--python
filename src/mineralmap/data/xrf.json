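{
  "_comment": "Defaults for XRF quantification. Molar ratios (dimensionless) are study means +/- sd over masked ROIs. Absorption lengths are representative 1/e depths in a hydroxyapatite-dominated matrix at the 10 keV incident energy and at each K-alpha fluorescence line; they are user inputs, not computed from stoichiometry. Gains emulate thin-film-standard detector calibration (counts per mmol/cm^2).",
  "ratios": {
    "ca_p": {
      "dentin":            {"mean": 1.49, "sd": 0.21},
      "bone":              {"mean": 1.68, "sd": 0.20},
      "cementum":          {"mean": 1.51, "sd": 0.22},
      "cementum_zn_rich":  {"mean": 1.51, "sd": 0.13},
      "cementum_zn_poor":  {"mean": 1.52, "sd": 0.13},
      "lesion_zone_1":     {"mean": 0.32, "sd": 0.05},
      "lesion_zone_2":     {"mean": 0.46, "sd": 0.04}
    },
    "ca_zn": {
      "cementum":          {"mean": 990.0,  "sd": 430.0},
      "acellular_cementum":{"mean": 595.0,  "sd": 50.0},
      "cellular_cementum": {"mean": 1155.0, "sd": 165.0},
      "bone":              {"mean": 2765.0, "sd": 905.0},
      "bone_interface":    {"mean": 855.0,  "sd": 125.0}
    }
  },
  "incident_energy_kev": 10.0,
  "line_energies_kev": {"Ca": 3.69, "P": 2.01, "Zn": 8.64},
  "absorption_length_incident_um": 110.0,
  "absorption_lengths_um": {"Ca": 9.0, "P": 4.0, "Zn": 75.0},
  "incidence_angle_deg": 45.0,
  "takeoff_angle_deg": 45.0,
  "gains_counts_per_mmolcm2": {"Ca": 200000.0, "P": 200000.0, "Zn": 2000000.0},
  "detection_floor_mmolcm3": {"Ca": 0.0, "P": 1e-4, "Zn": 1e-6},
  "ca_base_mmol_cm3": 10.0,
  "thickness_um": 5.0,
  "noise_cv": 0.10
}
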