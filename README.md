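# expo4dct

A desk-scale virtual 4DCT system for studying **temporal gating-window
weighting** in respiration-correlated CT reconstruction: a moving digital
phantom, time-stamped parallel-beam acquisition, retrospective phase
sorting, and phase-resolved filtered backprojection under the
conventional **cosine-squared** taper and the **EXPO** (exponential)
weighting, together with the evaluation machinery (residual-blur FWHM,
difference maps, MIP/minIP/AVG-CT, ROI noise statistics) needed to
quantify the trade-off the EXPO weighting makes: sharper moving
boundaries at the cost of slightly higher noise.

It is written for medical-physics researchers who want the mechanism —
not a vendor console — on their desk: every stage is an importable
function, every run is seeded and reproducible, and the full factorial
phantom study runs in well under a minute on one CPU.

## The model

In low-pitch helical 4DCT, a voxel at the edge of the field of view stays
inside the collimated beam for the transit time

    Z_m = (R_S − FOV/2) · COLL / R_S,   V = PF · COLL / RT,   TT = Z_m / V,

so full illumination over one breathing cycle requires `BP ≤ TT`.  When
the breathing period violates this bound, the reconstruction gate for
each phase widens beyond the half-rotation (π) minimum by
`T_w = BP − RT/PF · (1 − FOV/(2 R_S))` seconds, and the extra, temporally
redundant projections blur moving anatomy.  Over a gate of `I_t`
projections centered on the phase point `I_m`, the two weightings are

    cos²(i)  = cos²( π (i − I_m) / I_t )
    EXPO(i)  = cos²(i) · exp( −|i − I_h| · E_f / I_t ),    E_f = 2.0,

normalized within ray-redundancy groups (gantry angles coinciding mod π)
before ramp-filtered backprojection.  The exponential narrows the
effective temporal window by ~28% at `E_f = 2`, which tightens moving
boundaries; concentrating the per-ray weight on fewer projections raises
the noise.  Blur is quantified as the FWHM of a small moving object less
its static size, per phase and scheme.

## Worked example

`examples/blur_comparison.py` simulates the S-I sinusoid phantom (20 mm
and 30 mm disks, 3 cm excursion) at 10 bpm and pitch 0.10 — the
breathing-period bound is 2.81 s against a 6 s period, so the gate widens
by 3.19 s — and measures residual blur per phase:

```
residual blur [mm] of the 20 mm disk (10 bpm, pitch 0.10):
scheme  cosine_squared  expo
phase
0                 0.07 -0.06
1                 1.40  0.96
2                 7.35  4.90
3                 7.35  4.90
4                 1.40  0.96
5                 0.07 -0.06
6                 1.40  0.97
7                 7.36  4.90
8                 7.36  4.90
9                 1.40  0.97

mean improvement with EXPO: 1.18 mm (gate widened by 3.19 s)
```

Residual blur peaks at the transitional phases (2–3, 7–8), where the
boundary moves fastest, and EXPO cuts it by roughly a third there; at the
near-stationary extremes (phases 0 and 5) both schemes already match the
static size.  `examples/noise_tradeoff.py` shows the other side of the
trade: on matched noisy acquisitions EXPO's background sd is ~7% higher
while ROI means move by under 0.1 HU.  `examples/gating_budget.py` and
`examples/weight_curves.py` print the temporal budget table and the
weight-curve narrowing.

## Command line

```bash
expo4dct simulate    --config cfg.yaml --out run.h5
expo4dct reconstruct --in run.h5 --scheme both --out recon/
expo4dct analyze     --cos2 recon/cosine_squared --expo recon/expo \
                     --config cfg.yaml --out report.csv
expo4dct suite       --name si_sinusoid_grid --out results/
```

Configs are YAML (sections `scanner`, `grid`, `phantom`, `waveform`,
`weighting`, `reconstruction`, `metrics`; see
`expo4dct.config.default_config_dict()`), sinograms are HDF5 containers
with a per-projection metadata CSV, reconstructions are HU-scaled NIfTI
volumes, reports are CSV.

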