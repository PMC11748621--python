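"""Describe the named network architectures and their parameter budgets.

Prints the layer table of the Type 1 DSC network (Model 2) at full
acquisition scale and compares learnable-parameter totals across all models,
showing that global average pooling (Model 4) removes the large
flatten-to-dense block.
"""

from chemimage.dscnn import ARCHITECTURE_NAMES, build_architecture

full = (256, 256, 106)

print(build_architecture("model2", full).describe())
print()

print(f"{'architecture':<12s} {'params @256x256x106':>20s}")
for name in ARCHITECTURE_NAMES:
    arch = build_architecture(name, full)
    print(f"{name:<12s} {arch.n_params():>20,d}")
print("\nModel 4 is the lightest of Models 2-5: 3-D global average pooling "
      "collapses each feature volume to one number before the dense head.")
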