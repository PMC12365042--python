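# respirhythm

Intermittent-flow respirometry rates, metabolic quotients and
circadian-rhythm analysis for real-time fish biomonitoring.

`respirhythm` is for ecotoxicologists and biomonitoring engineers who track
the physiology of small fish (e.g. juvenile zebrafish, *Danio rerio*) in
automated metabolic chambers: the instrument alternates flush and sealed
phases on a 450-s cycle, logs dissolved O₂ and CO₂ during the trailing 300-s
sealed window, and samples tank ammonia-N every two hours. From those raw
traces the package computes the five standard metabolic endpoints and
characterises their diel rhythm, so that sublethal stress (here, exposure to
the PAHs phenanthrene and pyrene) can be read off metabolic suppression and
rhythm damping long before overt toxicity.

## The computation

**Slopes.** Within each sealed window the concentration slope *Dᵢ*
(mg L⁻¹ s⁻¹) is a weighted average of *n* central differences around the
window-centre reading, with triangular weights — for *n* = 3, 5, 7:

```
n=3:  D = (X₊₁−X₋₁)/(t₊₁−t₋₁)
n=5:  D = [2(X₊₁−X₋₁)/(t₊₁−t₋₁) + (X₊₂−X₋₂)/(t₊₂−t₋₂)] / 3
n=7:  D = [3(X₊₁−X₋₁)/(t₊₁−t₋₁) + 2(X₊₂−X₋₂)/(t₊₂−t₋₂) + (X₊₃−X₋₃)/(t₊₃−t₋₃)] / 6
```

The estimator is exact on affine traces and, at a symmetric stencil, on
quadratics.

**Rates.** Slopes convert to mass-specific rates (mg kg⁻¹ h⁻¹) through the
chamber geometry,

```
VO₂ = −D_O₂ · (RespirVol − FishVol) · 3600 / FishWeight
```

and analogously (positive sign) for CO₂ excretion (CR) and ammonia-N
excretion (AE, from bi-hourly tank samples with the tank water volume in the
chamber-volume slot). The quotients are molar ratios:

```
RQ = (VCO₂/44) / (VO₂/32)        AQ = (VN/18) / (VO₂/32)
```

**Rhythm.** Hourly series are detrended (centred 24-h moving-average
baseline by default), and the normalised autocorrelation is scanned for its
best positive local maximum in an 18–30 h band. An 8×6 self-organizing map
trained on the z-scored hourly (OR, CR, AE, RQ, AQ) profiles is cut into six
clusters by Ward's minimum-variance linkage; clusters associate cleanly with
photophase or scotophase when the diel rhythm is intact.

**Statistics.** Treatment-vs-control and light-vs-dark contrasts use the
Mann-Whitney U test (exact enumeration for small samples, tie-corrected
normal approximation otherwise) alongside one-way ANOVA, with the usual
`*** p<0.001, ** p<0.01, * p<0.05` annotation.

Because chamber instrument data of this kind are rarely deposited, the
package ships a calibrated simulator (`respirhythm.sim`) whose presets
(`control`, `phe`, `pyr`) reproduce the published 7-day group means and the
qualitative exposure time-courses (an ammonia surge within 48 h, progressive
late CO₂-excretion suppression, damped diel amplitude under treatment).

## Worked example

```python
import respirhythm as rr

ds = rr.generate_dataset("control", days=7, tanks=3, seed=1)
results = rr.analyze_traceset(ds)          # traces -> rates per tank
print(rr.seven_day_means(results))

hours, orbar = rr.group_mean_series(results)["OR"]
summary = rr.rhythm_summary(orbar)
print("dominant period:", summary.dominant_period, "h")

flags = rr.label_phases(hours)
u, p = rr.mann_whitney(orbar[flags], orbar[~flags])
print(f"photophase {orbar[flags].mean():.0f} vs scotophase "
      f"{orbar[~flags].mean():.0f} mg/kg/h, p={p:.2e}")
```

prints

```
{'OR': 1795.14, 'CR': 128.05, 'AE': 57.07, 'RQ': 0.05, 'AQ': 0.05}
dominant period: 24 h
photophase 2101 vs scotophase 1184 mg/kg/h, p=5.08e-26
```

The recovered 7-day means sit within ~1% of the control calibration targets
(OR 1778.57, CR 127.97, AE 56.44 mg kg⁻¹ h⁻¹); the oxygen-consumption rhythm
is detected at exactly 24 h with a near-saturated ACF amplitude; and the
photophase mean exceeds the scotophase mean roughly 1.8-fold, strongly
significant on time-resolved observations.

The same pipeline is available from the shell:

```sh
respirhythm report --preset phe --seed 1 --out-dir report/
```

which simulates the phenanthrene group against a control reference, writes
trace/rate/rhythm/cluster tables and a summary with significance stars.

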