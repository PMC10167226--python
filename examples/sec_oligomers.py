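"""SEC oligomer sizing and the Trp-fluorescence exposure reporter.

Generates a synthetic chromatogram whose peak corresponds to a 25-mer with
a full width at half maximum spanning 18-30 subunits (a wild-type-like
oligomer distribution), estimates the subunit count from the calibrated
peak position, and locates the emission maxima of two Trp fluorescence
spectra: the red shift from 323 to 330 nm reports a more polar, solvent-
exposed Trp environment after monomers assemble into oligomers.
"""
import numpy as np

import loopchap as lc

chrom, cal, truth = lc.gen_sec(lc.GeneratorConfig(seed=5))
est = lc.estimate_subunits(chrom, cal, truth["monomer_mw"])
print(f"SEC peak at {est.peak_volume:.2f} mL -> MW {est.mw_peak/1000:.0f} kDa"
      f" -> {est.subunits_peak} subunits"
      f" (FWHM range {est.subunits_range[0]}-{est.subunits_range[1]})")

wl = np.arange(300.0, 401.0)
monomer = np.exp(-0.5 * ((wl - 323.0) / 20.0) ** 2)
oligomer = np.exp(-0.5 * ((wl - 330.0) / 20.0) ** 2)
em_mono = lc.emission_max(wl, monomer)
em_olig = lc.emission_max(wl, oligomer)
print(f"Trp emission maximum: monomer {em_mono:.0f} nm, "
      f"oligomer {em_olig:.0f} nm (red shift {em_olig - em_mono:+.0f} nm)")
print("\nThe red shift on oligomerisation indicates the loop anchor position"
      "\nbecomes more solvent-exposed in the assembled chaperone.")
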