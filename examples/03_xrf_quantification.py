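"""XRF quantification: counts -> area -> volume concentrations.

Forward-models raw Ca/P/Zn count maps of a uniform dentin-like specimen
(5 um thick, 10 keV incident beam), then inverts them via thin-film-standard
gains and self-absorption thickness correction, recovering the true
volume concentrations.
"""
import numpy as np

import mineralmap as mm

spec = mm.ElementFieldSpec(shape=(64, 64), noise_cv=0.0, scene={
    "kind": "uniform", "ratio_ca_p": 1.49, "ratio_ca_zn": 595.0})
maps, gt = mm.make_xrf_maps(spec)
ctx = mm.default_context()
standards = {el: mm.default_standard(el) for el in maps}

quantified = mm.quantify_xrf(maps, standards, ctx)
for el in ("Ca", "P", "Zn"):
    mu = ctx.total_attenuation_per_um(el)
    t_eff = mm.effective_thickness(ctx, el)
    true = gt.fields[el].mean()
    rec = quantified[el].data.mean()
    print(f"{el}: mu = {mu:.3f}/um  t_eff = {t_eff:.2f} um (of "
          f"{ctx.thickness_um:.0f} um)  true {true:.4f} -> recovered "
          f"{rec:.4f} mmol/cm^3  (rel err {abs(rec - true) / true:.2e})")
# t_eff < t quantifies how much fluorescence the specimen itself absorbs
# (strongest for the soft P line); dividing the area concentration by t_eff
# rather than t is what makes the recovery exact.
print(f"counts in raw Ca map: mean {maps['Ca'].data.mean():.0f} "
      f"(gain {standards['Ca'].counts_per_mmolcm2:.0f} counts per mmol/cm^2)")
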