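"""Cosine-squared vs EXPO weight curves over one widened gate.

Builds both curves for a 400-projection gate, prints anchor values and the
full width at half maximum of each curve: the EXPO exponential (Ef = 2)
narrows the effective temporal window, which is the mechanism behind its
sharper moving boundaries.
"""

import numpy as np

from expo4dct import build_weight_curve, effective_temporal_width
from expo4dct.io import weight_curve_table

total = 400
cos2 = build_weight_curve(total, "cosine_squared")
expo = build_weight_curve(total, "expo", steepness=2.0)

mid = cos2.mid_phase_index
for off in (0, total // 4, total // 2):
    print(f"offset {off:>3}: cos2 {cos2.weights[mid + off - 1 if off == total // 2 else mid + off]:.4f}"
          f"  expo {expo.weights[mid + off - 1 if off == total // 2 else mid + off]:.4f}")

w_c = effective_temporal_width(cos2)
w_e = effective_temporal_width(expo)
print(f"\neffective temporal width (FWHM of the curve):")
print(f"  cosine-squared: {w_c:.1f} projections ({w_c / total:.2f} of the gate)")
print(f"  EXPO (Ef=2.0):  {w_e:.1f} projections ({w_e / total:.2f} of the gate)")
print(f"  narrowing: {100 * (1 - w_e / w_c):.0f}% fewer effective projections")

# per-ray normalization demo: conjugate angles repeat every half rotation
labels = np.arange(total) % 180
table = weight_curve_table(expo, group_labels=labels)
table.to_csv("weight_curve_expo.csv", index=False)
print("\nwrote weight_curve_expo.csv (index, raw, per-ray normalized weight)")
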