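"""Enhance a histology-style image by cubic re-weighting of its SWT detail
coefficients, and show how the high-frequency energy budget changes."""

import numpy as np

import histoswt as hs

# one synthetic graded-texture image stands in for a histology tile
spec = hs.SyntheticSpec(n_per_class=(1, 0, 0), image_size=(64, 64), seed=42)
image = hs.generate_graded_dataset(spec).samples[0].image

# best-known tuned constants: y = 0.0091 w^3 + 0.0301 w^2 + 0.0086 w + 0.3444, db2
params = hs.REFERENCE_TUNED_PARAMS
enhanced = hs.enhance(image, params)

before = hs.detail_energy(image, params.wavelet)
after = hs.detail_energy(enhanced, params.wavelet)
roundtrip = np.abs(hs.enhance(image, hs.IDENTITY_PARAMS) - image).max()

print(f"detail-subband energy before enhancement: {before:8.3f}")
print(f"detail-subband energy after enhancement:  {after:8.3f}")
print(f"identity-mapping round-trip error:        {roundtrip:.2e}")
print()
print("The cubic mapping attenuates and re-weights the LH/HL/HH coefficients")
print("(the c*w term scales them, a*w^3 boosts large coefficients relative to")
print("small ones), so the reconstructed image keeps its anatomy but with a")
print("rebalanced high-frequency budget; identity constants reproduce the")
print("input to machine precision.")
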