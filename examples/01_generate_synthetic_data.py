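"""Generate a paired MIR/XRF soil-spectra dataset with known structure.

The generator draws latent "chemical" factors per sample and renders
them as Gaussian absorption bands (MIR, 4000-650 cm^-1) and element
emission peaks over a continuum (XRF, 0-30 keV).  The seven soil
attributes (pH, OC, P, K, Mg, Ca, MC) mix MIR-visible and XRF-exclusive
factors; `complementarity` is the fraction of attribute signal variance
carried only by the XRF block.
"""

from soilfusion import SynthConfig, generate, attribute_ranges

config = SynthConfig(n_samples=196, complementarity=0.5, seed=42)
dataset = generate(config)

print(f"MIR block: {dataset.mir.values.shape[0]} samples x "
      f"{dataset.mir.values.shape[1]} channels "
      f"({dataset.mir.axis[0]:.0f} -> {dataset.mir.axis[-1]:.0f} cm^-1)")
print(f"XRF block: {dataset.xrf.values.shape[0]} samples x "
      f"{dataset.xrf.values.shape[1]} channels "
      f"({dataset.xrf.axis[0]:.1f} -> {dataset.xrf.axis[-1]:.1f} keV)")
print()
print("Attribute summary (min/max/mean/sd per soil attribute):")
print(attribute_ranges(dataset).round(2).to_string())
print()
print("Each row is one soil attribute; the marginal mean and spread are "
      "patterned on a typical European agricultural field survey.")
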