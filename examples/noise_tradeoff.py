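"""The price of sharper boundaries: background noise, scheme vs scheme.

Acquires the moving phantom with Gaussian projection noise several times
(matched seeds: both schemes reconstruct the same noisy data) and prints
the background-ROI mean and standard deviation in HU.  EXPO concentrates
per-ray weight on fewer projections, so its noise sd is consistently
higher while the mean CT number barely moves.
"""

from expo4dct import noise_study

table = noise_study(n_pairs=8, seed=0)
sd = table.pivot(index="pair", columns="scheme", values="sd_hu").round(2)
mu = table.pivot(index="pair", columns="scheme", values="mean_hu").round(1)
print("background ROI noise sd [HU]:")
print(sd.to_string())
ratio = (sd["expo"] / sd["cosine_squared"]).mean()
dmu = (mu["expo"] - mu["cosine_squared"]).abs().max()
print(f"\nmean sd ratio EXPO / cos2: {ratio:.3f}")
print(f"largest |mean HU difference|: {dmu:.2f} HU (negligible vs ~950 HU contrast)")
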