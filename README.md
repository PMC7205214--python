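# retipulse

Retinal vascular pulse-wave amplitude analysis from fundus video, using
modified photoplethysmography (mPPG).

The retinal veins and arteries pulsate with the cardiac cycle. Because
hemoglobin absorbs strongly at the isosbestic wavelength (~550 nm, the green
channel), the mean green intensity of a vessel segment in a fundus video
oscillates with the blood-column volume, and the size of that oscillation —
the pulse amplitude — decays predictably with distance along the vessel.
`retipulse` turns fundus-video frame stacks into per-vessel and per-pixel-
cluster pulse amplitudes, maps them spatially, and models how the amplitude
attenuates with distance from the optic disc and amplifies under
ophthalmodynamometric force (ODF, a calibrated compression of the globe that
raises intraocular pressure). It is aimed at researchers quantifying retinal
hemodynamics — vessel-wall compliance, spontaneous venous pulsation, the
effect of induced intraocular-pressure changes — from ordinary slit-lamp
video recordings.

## The model

Each recording spans three cardiac cycles (~70 frames at 25 fps). Frame *i*
of cycle *c* is assigned the phase time *t = i/n_c + (c − 1)* where *n_c* is
the cycle's frame count. The mean green series *y(t)* of a vessel template
or pixel cluster is fitted by harmonic regression with a drift spline and
AR(1) errors:

```
y(t) = μ + Σ_{n=1,2} [ a_n cos(2πnt) + b_n sin(2πnt) ]
         + s₁ t + s₂ (t−1)₊ + s₃ (t−2)₊ + e_t,      e_t = ρ e_{t−1} + u_t
```

ρ is estimated by REML profiling with GLS coefficients at each candidate;
AIC (restricted likelihood, k = p + 2) selects the harmonic order. The pulse
size is the **harmonic regression wave amplitude** HRW_a: the peak-to-trough
excursion of the fitted periodic component over one cycle. Amplitudes are
log₁₀-transformed and modelled by a linear mixed-effects interaction model
with random intercept and slope per eye,

```
log₁₀ HRW_a = I₀ + C_VD·V_Dist + C_ODF·ODF + C_VD×ODF·V_Dist·ODF + (eye) + ε
```

where V_Dist is arc-length distance from the optic-disc center in disc
diameters (DD). Beer–Lambert photometry (A = −ln T) converts green-channel
transmittance into nominal optical path length, and a synthetic-data module
generates ground-truthed studies — per-cluster series and rendered frame
stacks of a pulsating vessel — with exactly this statistical structure.

## Worked example

Simulate a venous study at the default conditions (28 eyes, 9 ODF runs per
eye from 0–180 g, 20 positions per vessel) and fit the interaction model:

```python
from retipulse import (SyntheticStudyConfig, generate_attenuation_records,
                       fit_interaction, fit_marginal)

config = SyntheticStudyConfig(seed=0)            # 28 eyes x 9 runs x 20 points
records = generate_attenuation_records(config)   # one venous study
model = fit_interaction(records)
for term, est in model.fixed.items():
    print(f"{term:>9}: {est.estimate:+.5f} +/- {est.se:.5f}")
print(f"R2 marginal {model.r2_marginal:.2f}, conditional {model.r2_conditional:.2f}")
slope = fit_marginal(records, "v_dist")["slope"]
print(f"marginal attenuation: {slope.estimate:+.3f} /DD (SE {slope.se:.3f})")
```

```
       I0: +0.87438 +/- 0.02685
     C_VD: -0.27205 +/- 0.03394
    C_ODF: +0.00149 +/- 0.00008
 C_VDxODF: -0.00089 +/- 0.00014
R2 marginal 0.19, conditional 0.64
marginal attenuation: -0.352 /DD (SE 0.032)
```

The fit recovers the generating venous coefficients (0.90, −0.34, 0.0015,
−0.00084) within sampling error: amplitude decays by about 0.3–0.4 log₁₀
units per disc diameter (attenuation), grows with ODF (positive C_ODF), and
the negative interaction term says compression steepens the attenuation.
About a fifth of the variance is carried by the predictors and roughly
another half by between-eye differences.

The same analysis runs from images: `render_frames` rasterizes a recording,
`extract_cluster_series` reduces it to per-cluster series,
`HarmonicRegression` fits each, and `build_amplitude_map`/`export_heatmap`
produce false-color amplitude maps. A `retipulse` CLI wraps the stages
(`simulate`, `extract`, `fit`, `map`, `attenuation`, `all`).

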