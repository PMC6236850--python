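"""Residual motion blur per phase: cosine-squared vs EXPO.

Simulates the S-I sinusoid phantom (20 mm and 30 mm disks, 30 mm
peak-to-peak excursion) at 10 bpm / pitch 0.10 — a configuration that
violates the breathing-period condition, so the gate widens and the
temporal weighting matters.  Prints the residual blur (FWHM less static
size) of the 20 mm disk for every phase under both weightings; positive
numbers are motion blur, and the EXPO column should sit below the
cosine-squared column, most visibly at the transitional phases (2-3, 7-9).
"""

from expo4dct import GridSpec, ScannerGeometry, blur_sweep

table = blur_sweep(
    suite="si_sinusoid_grid",
    grid=GridSpec(128, 500.0),
    base_geometry=ScannerGeometry(projections_per_rotation=360),
    bpm_values=(10.0,),
    pitches=(0.10,),
    seed=0,
)
disk = table[table["object_id"] == "disk20"]
wide = disk.pivot(index="phase", columns="scheme", values="residual_mm").round(2)
print("residual blur [mm] of the 20 mm disk (10 bpm, pitch 0.10):")
print(wide.to_string())
gap = (wide["cosine_squared"] - wide["expo"]).mean()
print(f"\nmean improvement with EXPO: {gap:.2f} mm "
      f"(gate widened by {disk['window_widening_s'].iloc[0]:.2f} s)")
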