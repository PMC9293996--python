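"""Patch geometry of the anisotropic U-Net.

The network uses only valid (unpadded) convolutions, so every input patch
shrinks by a fixed symmetric margin. This script propagates the default
training input extent through the architecture and compares the parameter
count against the corresponding full-3D variant.
"""

import hepaseg as hs

cfg = hs.NetworkConfig()
g = hs.compute_patch_geometry(cfg, (236, 236, 72))
print(f"input patch : {g.input_extent}")
print(f"output patch: {g.output_extent}")
print(f"margin/side : {g.margin}  (input = output + 2*margin, per axis)")

aniso = hs.count_parameters(cfg)
full = hs.count_parameters(cfg, full3d=True)
print(f"parameters  : {aniso:,} anisotropic vs {full:,} full 3D "
      f"({100 * aniso / full:.0f} %)")
print("The margin is architecture-determined: the same margin applies to any")
print("admissible input extent, which is what makes tiled inference exact.")
print("margin for 220x220x60 input:",
      hs.compute_patch_geometry(cfg, (220, 220, 60)).margin)
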