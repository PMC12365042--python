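# Methods

This note documents the models, estimators and numerical choices behind
`respirhythm`, the assumptions baked into its synthetic-data generator, and
what the passing tests do and do not establish about real instrument data.

## 1. The measurement model

An intermittent-flow respirometer alternates a flush phase with a sealed
measurement phase on a fixed cycle (450 s by default). During the sealed
trailing window (300 s) the chamber is a closed system, so dissolved O₂
falls and dissolved CO₂ rises linearly at rates proportional to the fishes'
metabolism. With readings every 15 s that gives 20 readings per window; the
raw reading cadence is an instrument-specific choice and is configurable
(`ChamberSpec.sensor_interval`).

The per-window slope estimator is a weighted mean of `n ∈ {3, 5, 7}` central
differences about the window-centre reading, with triangular weights
(1; 2, 1; 3, 2, 1) normalised by their sum (1, 3, 6). Properties that the
tests pin down:

* exact for affine concentration traces at arbitrary spacing, and for
  quadratics at the centre of a symmetric stencil;
* for i.i.d. Gaussian reading noise of SD σ and spacing Δ, the propagated
  slope variance is `Σₖ wₖ² · 2σ²/(2kΔ)² / (Σₖ wₖ)²` — the Monte-Carlo test
  checks the estimator against this closed form.

The default stencil is `n = 7` (the most smoothing); at window edges it
falls back to 5 then 3, and windows with fewer than 3 usable readings are
flagged missing, never fabricated. The centre reading of an even-length
window is the earlier of the two middle readings.

Slopes become mass-specific rates through
`rate = sign · D · (RespirVol − FishVol) · 3600 / FishWeight`
with sign −1 for O₂ and +1 for CO₂ and ammonia-N. `FishWeight`/`FishVol`
are the totals over the fish in the chamber (default: five juveniles of
0.5 g / 0.5 mL; chamber 2.0 L). Ammonia-N is not cycled through the chamber:
it accumulates in the holding tank (6 L default, no flush) and is assayed
bi-hourly; AE is the two-point slope between consecutive samples pushed
through the same rate equation with the tank water volume, reported at
interval midpoints.

Quotients are molar ratios, `RQ = (VCO₂/44)/(VO₂/32)` and
`AQ = (VN/18)/(VO₂/32)`. The ammonia divisor 18 (ammonium rather than 17
for NH₃) is kept as the field convention for this assay. Quotients are
computed on the aggregated grids — RQ from hourly mean rates, AQ pairing
each bi-hourly AE value with the mean VO₂ of its containing 2-h window —
not per cycle; this is why a mean of per-timepoint quotients differs from
the quotient of mean rates. Entries with non-positive VO₂ are NaN.

## 2. The synthetic-data generator

The generator emulates a 7-day exposure of triplicate tanks under a
16 h light : 8 h dark photoperiod (lights on 04:00, off 20:00; the run
starts 08:00 on day 1). The true rate of each channel is

```
rate(t) = base · timecourse(t) · (1 + A · s(t))
```

* `s(t)` is a smoothed square wave (+1 mid-photophase, −1 mid-scotophase)
  with logistic dawn/dusk edges of ~1 h 10–90% width — metabolic day/night
  separation in such data is plateau-like rather than sinusoidal.
* `A` is the fractional diel amplitude per channel. Presets: control
  0.30/0.45/0.50 (O₂/CO₂/NH₃-N), phenanthrene 0.15/0.30/0.35, pyrene
  0.22/0.38/0.45. Treated amplitudes are reduced (phenanthrene most), and
  within every preset the ordering AE > CR > OR makes the quotients inherit
  a photophase-high rhythm — a ratio of two waves with equal amplitude
  would be rhythm-free.
* `timecourse(t)` encodes the exposure dynamics: the ammonia-excretion
  multiplier ramps linearly from 1 to a plateau (×3.0 phenanthrene, ×2.5
  pyrene) over the first 48 h; the CO₂-excretion multiplier decays
  exponentially (τ = 24 h) toward a terminal level (×0.5 / ×0.7) after a
  96-h onset. Control multipliers are identically 1.
* `base` is not set directly: each preset is calibrated by numerical
  quadrature (trapezoid, 1-min grid) so that the 7-day time-average of the
  true rate equals the group's target mean — control 1778.57 / 127.97 /
  56.44, phenanthrene 444.46 / 73.92 / 690.60, pyrene 534.26 / 107.85 /
  413.96 mg kg⁻¹ h⁻¹ (OR / CR / AE). An independent finer-grid quadrature
  in the tests confirms the calibration to ≪ 0.5%.

Noise has two components, both sampled from a single seeded generator so a
seed reproduces a dataset bit-for-bit:

* i.i.d. Gaussian reading noise per sensor sample — SD 0.004 mg/L (optical
  O₂), 0.0005 mg/L (optical CO₂), 0.005 mg/L (colorimetric ammonia kit).
  These sit at the precision end of such sensors and were chosen so the
  recovered group SDs are of the same order as the inter-tank spread
  reported for experiments of this design.
* a multiplicative inter-tank biological offset (SD 1.5%, shared across
  channels within a tank), the dominant contribution to between-tank spread.

What the generator does **not** emulate: sensor drift and calibration
error, temperature/solubility effects, background (blank-chamber)
respiration, fish behaviour and movement artefacts, level-dependent assay
noise, or any toxicokinetics of the exposure compounds. Tests passing on
this generator therefore demonstrate that the *analysis* is correct and
well-calibrated under the stated noise model — not that the pipeline is
robust to every artefact of real instruments.

One consequence of the level-independent assay-noise model is worth
flagging: treated-group ammonia runs at a several-fold elevated level with
the same absolute noise, so its autocorrelation is *cleaner* than
control's even though its fractional diel modulation is smaller. The
"control ACF amplitude exceeds treated" property is therefore asserted for
OR, CR and RQ (where treatment suppresses the level), while for AE/AQ the
amplitude ordering is asserted on the generator's fractional amplitudes.
With multiplicative (CV-type) assay noise the ACF ordering would extend to
AE/AQ as well; that variant is out of scope here.

## 3. Rhythm analysis

Hourly tank-mean series (bi-hourly AE/AQ linearly interpolated onto the
hourly grid — a piecewise-constant forward fill would add a spurious
half-sample phase lag) are detrended and autocorrelated at integer-hour
lags up to 72 h.

* **Detrending.** Default is a centred 24-h moving-average baseline (the
  classic seasonal-decomposition trend filter, half-weights at the window
  ends): it removes drifts of arbitrary smooth shape — the exposure
  time-courses are ramp- and saturation-shaped, which a straight line
  cannot absorb — while passing any exactly-24-h-periodic component
  untouched. An OLS-line detrend (`"linear"`) and plain mean-centring
  remain selectable.
* **Normalisation.** Each lag is normalised by the Cauchy–Schwarz bound of
  its two aligned segments, with missing values pairwise-deleted; this
  guarantees `acf(0) = 1` and `|acf| ≤ 1` even with gaps. On complete series
  it agrees with the standard estimator to O(lag/N).
* **Dominant period.** The best positive local maximum in an 18–30 h band
  (avoiding the 12-h harmonic and the 48-h alias); a series with no such
  maximum, or with zero variance, is flagged arrhythmic.

Statistical power note: the single-lag location of an ACF peak is a fragile
statistic. For the quotient series under the default noise, the expected
margin between the 24-h peak and its neighbours is ~0.02 ACF units, while
the per-lag estimation jitter of one 168-h experiment is of the same order
— so one simulated week can return 23 or 25 h for RQ even though the
estimator is consistent (a convergence study over replicate experiments
shows the mean ACF peaking at exactly 24 h for every parameter and preset).
The periodicity acceptance test therefore evaluates the mean
autocorrelation over 60 replicate simulated experiments, which is also how
mean autocorrelograms are usually presented; per-experiment exact-lag
detection is reliable for the directly measured channels but should not be
expected for noisy quotients.

## 4. SOM and clustering

The self-organizing map is a classic online Kohonen network: 8×6
rectangular grid (~`5√N` units for a week of hourly samples), codebook
initialised uniformly within the per-feature data range, 1000 passes over
the samples with learning rate decaying 0.5 → 0.01 and Gaussian
neighbourhood radius decaying from half the grid diagonal to 1, all
exponential in the step fraction; BMU ties break toward the lowest unit
index and training is deterministic given a seed. Features are the five
parameters z-scored per parameter across the series.

Ward's minimum-variance linkage is applied to the codebook vectors (the
usual practice for ecological SOMs — clustering prototypes, not samples)
and cut into k = 6 clusters; sample clusters follow their BMU. Cluster ids
are relabelled by descending scotophase fraction so that "cluster 1 is the
darkest" holds across runs. Per-cluster phase purity is the majority-phase
fraction; with an intact 16:8 rhythm the purity is near 1, against a 16/24
baseline for phase-blind clustering.

## 5. Group statistics

Tanks are the biological replicates: summary means and SDs are computed
across tank means (three per group). The comparison tests, however, default
to time-resolved observations (all tank-hours), because with three tanks a
tank-mean Mann-Whitney cannot go below its exact floor of p = 0.1 while the
reference experiments report p < 0.001; tank-mean granularity is available
via a flag. The Mann-Whitney p is exact — full enumeration of the
`C(n+m, n)` label assignments on midranks, hence correct under ties — when
the smaller sample has ≤ 8 observations and the enumeration stays under
10⁵ assignments; otherwise a tie-corrected normal approximation with
continuity correction is used. No multiple-testing correction is applied;
each test is read at its own α. Same-preset (null) comparisons at hourly
granularity are conservative rather than anticonservative because the two
groups share the deterministic diel signal; the type-I-error check (100
replicate null comparisons of 2-day simulations) bounds the empirical size
at ≤ 0.10.

## 6. Problem sizes and determinism

Default experiment: 7 days × 3 tanks, 1344 chamber cycles per gas channel
per tank (20 readings each) and 85 ammonia samples. Recovery tests run ten
replicate experiments per preset; the periodicity test runs sixty; the
type-I check runs 100 two-day null pairs. Every stochastic element —
simulation, SOM training, subsampling — takes an explicit integer seed, and
identical seeds give bit-identical outputs, including byte-identical CSV
exports (trace files are read back with round-trip float parsing).

## 7. Known limitations

* Tank-level resolution only; individual fish are not modelled ("the tank
  is the replicate").
* No solubility/temperature correction and no blank-chamber background
  subtraction; rates are as-measured.
* The ACF estimator reports integer-hour periods only; sub-hour period
  shifts are invisible by design (no cosinor or spectral methods).
* The exact-lag periodicity of noisy quotient series is only resolvable in
  ensemble (see §3).
* The exposure time-courses are phenomenological (ramp/exponential); they
  are calibrated to reproduce weekly means and qualitative dynamics, not
  mechanistic toxicokinetics.
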