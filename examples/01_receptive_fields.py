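"""Receptive fields of the simplified encoders.

The support-set and segmentation encoders are deliberately near-sighted:
dropping the multi-scale attention branches and using 1x1 FFN kernels
(except one 3x3 depthwise conv per stage) pins the field of view to small
fractions of the input, so each feature vector describes its immediate
neighbourhood and cross-attention maps stay spatially specific.
"""

from icseg.encoders import (EncoderConfig, empirical_receptive_field,
                            theoretical_receptive_field)

config = EncoderConfig.from_preset("full")
analytic = theoretical_receptive_field(config, input_size=256)
empirical = empirical_receptive_field(EncoderConfig.from_preset("tiny"),
                                      input_size=256)

print("level    analytic RF        gradient-masked RF")
for level, (px, frac) in analytic.items():
    print(f"{level:8s} {px:4d} px ({100 * frac:5.2f}%)   {empirical[level][0]:4d} px")
print("\nEach row: how many input pixels influence one feature at that level.")
print("The two columns must agree exactly; percentages are of the 256-px axis.")
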