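# Methods

This note documents the models, defaults and numerical choices behind
`cardiomet`, and what the synthetic-data generators do and do not
emulate.

## Study conditions emulated

The package targets the rat fructose-overload metabolic-syndrome design:
three groups — control (C), sedentary fructose (F), fructose + low
intensity exercise training (FT) — of 8 animals each, fructose given as
100 g/L drinking water, insulin tolerance tests with a 0.75 U/kg bolus
and glucose sampled at 0/4/8/12/16 min, conscious arterial-pressure
recordings at ~2 kHz, and post-mortem morphometry of right atrium, left
ventricle and ascending aorta. `cardiomet.tables` holds the group-level
endpoint means ± SEM that parameterize the default synthetic cohort;
per-animal values are drawn as Gaussians with SD = SEM·√8.

## Beat-to-beat analysis

The pressure simulator builds each beat as a half-sine systolic upstroke
(first 30% of the beat) to that beat's systolic target, followed by an
exponential diastolic decay (time constant 0.12 beat) back to the
diastolic level. Only beat-level features propagate downstream, so the
intra-beat morphology is a free choice; LF (default 0.4 Hz) and HF
(default 1.5 Hz) oscillations amplitude-modulate the per-beat systolic
values with sinusoid amplitude sd·√2, so each band's injected variance is
exactly sd².

Peak detection subtracts a rolling-median baseline (window = one beat at
the minimum heart rate) and takes local maxima with prominence ≥ 0.3 ×
signal IQR and a refractory distance of 60/max_hr; the physiologic band
defaults to 200–500 bpm. Per beat (peak-to-peak window): SAP is the
maximum over the beat's own systole — the window up to mid-beat — so
that the next beat's upstroke cannot masquerade as the current systole
(taking the max over the whole window biases SAP toward the larger of
two adjacent systoles and roughly halves systogram variance); DAP is the
minimum strictly between peaks; MAP is the time-average of the waveform,
measured directly rather than approximated by DAP + PP/3. First/last
partial beats are discarded. Which side of the peak the "true" DAP lies
on is not specified in standard descriptions; the between-peak minimum
is used.

## Spectral analysis of the systogram

The per-beat SAP series is treated as evenly sampled at the recording's
mean beat rate (beats/s), the beat-domain convention of rodent
blood-pressure-variability work; no interpolation onto a time grid is
performed. Segmentation: 300 beats, 50% overlap, trailing remainder
dropped; a series shorter than one segment falls back to a single
full-length segment with a warning.

Each segment is mean-detrended. The autocovariance uses the biased
(divide-by-N) estimator, which guarantees a positive-semidefinite
sequence for the Levinson–Durbin recursion. Order selection minimizes
AIC(p) = N·ln σ²_p + 2(p+1) over p = 4–24 (ties to the smaller order;
constant segments return p_min with a flag). The one-sided AR spectrum
is evaluated on a 1024-point grid over [0, fs/2] (endpoints carry the
unfolded two-sided value) and band powers are trapezoidal integrals with
interpolated band edges; the HF band (0.6–3.0 Hz) extends beyond the
Nyquist frequency of a ~5.4 beats/s systogram and is clipped with a
warning, as any fixed-band convention must at these beat rates.

Headline "SAP variance" is the time-domain sample variance (ddof = 1) of
the detrended full systogram; the integral of the averaged spectrum is
reported separately as `total_power`, since the two need not coincide
for finite samples.

Numerical validation uses `ar_acovf`, the exact Yule–Walker solve for
the theoretical autocovariance of a stationary AR model. The
Parseval-type test family samples AR models by conjugate pole pairs with
modulus ≤ 0.95: bounding the pole modulus bounds the spectral peak
bandwidth, which is what makes a fixed frequency grid adequate for
integration (models built from unconstrained random reflection
coefficients can place poles within 10⁻⁸ of the unit circle, whose
spectra no fixed grid resolves).

## Baroreflex gain

Gain = mean over retained boluses of ΔHR/ΔMAP (the "response per mmHg"
definition); an OLS regression-slope variant is available via
`method="slope"` for sensitivity analysis. The acceptance window
|ΔMAP| ∈ [5, 40] mmHg is closed at both ends. BR is reported signed
(negative for a functioning reflex), TR as a positive magnitude,
matching the conventional table signs. Peak-response extraction from raw
bolus recordings is out of scope; trials arrive as (ΔMAP, ΔHR) pairs.

## Kitt

Glucose decay after an insulin bolus is exponential, so the "linear
phase of decline" is fitted as ln(glucose) vs time over the closed 4–16
min window, excluding the pre-injection t = 0 reading. Then t½ = ln 2/k
and Kitt = 100 × 0.693/t½ %/min (the 0.693 constant is kept as printed;
the ≤0.02% difference from ln 2 is below reporting precision). A
raw-scale variant (`fit_scale="raw"`) uses the fractional decline rate
|slope|/mean(glucose). Non-decaying series return Kitt = 0 with a
`decaying=False` flag rather than a negative index; slopes at
floating-noise level (|k| ≤ 1e−12/min) count as non-decaying.

Caloric bookkeeping uses 2.89 kcal/g chow and 4.0 kcal/g fructose with
the drinking-water concentration converting mL to grams. Note the
published group totals (30.8/34.7/37.9 kcal/day) are not reproducible
from the published mean consumptions with these factors (e.g. F: 8.2 g
chow and 39.1 mL at 100 g/L give 39.3 kcal/day, not 34.7); the formula
is implemented as stated and the discrepancy left unresolved.

## Stereology and vessel morphometry

Point grids are near-square regular lattices of exactly n points with a
single uniform random offset (systematic uniform random sampling);
surplus lattice positions are dropped at random to avoid spatial bias.
On fields of exactly known fraction the estimator is unbiased with
SE ≈ √(f(1−f)/PT). Synthetic tissue fields realize area fractions by
random pixel assignment — exact to the pixel, and sufficient for
point-counting estimators, which are insensitive to spatial texture;
they do not emulate the spatial autocorrelation of real histology, so
passing tests demonstrate estimator correctness, not segmentation
robustness.

Granule metrics use connected components (≥ 2 px) with equivalent-circle
diameter 2√(area/π), appropriate for near-circular EM profiles.

Vessel geometry: d = 2√(a/π); IMT is the mean of the four angular
measures (accepted in µm, converted internally to mm — a thickness
exceeding the lumen diameter is rejected as a unit error);
IMA = 1.28·[π(d/2+IMT)² − π(d/2)²] with the 1.28 fixation-shrinkage
factor. Forward computation from published diameters and thicknesses
approximately reproduces the published "area" column (0.70 vs 0.71,
0.95 vs 0.96, 0.63 vs 0.65 mm²), supporting its reading as intima-media
area.

Elastic lamellae are counted on 36 radial profiles: the wall is located
as the longest contiguous wall-labelled run along each ray, the lamella
indicator is cleaned by binary closing then opening (length-2
structures: bridges 1-px gaps, removes 1-px speckle), bands are counted
per ray, and the median over rays is reported. This is robust to 5%
uniform label noise at the default calibration (1 px/µm, 3 µm bands).

CWT = MSAP × d/2 is reported primarily in mmHg·mm — the scale on which
published values are internally consistent — with the dyne/cm conversion
(×133.322) alongside, despite the conventional attribution of dyne/cm
units to this formula.

Percent changes are computed under both denominator conventions; the
headline value uses the reference (F) denominator for decreases and the
new-value (FT) denominator for increases, the only convention consistent
with the full set of published summary percentages.

## Statistics

Normality: Lilliefors-corrected KS test (statsmodels). One-way ANOVA is
the classical fixed-effects F, computed directly (scipy's `f_oneway`
serves as an independent oracle in the tests). SNK: means sorted, a pair
spanning r means compared against q(1−α, r, df_within)·√(MS_w/n)
(harmonic-mean n when unequal, flagged), with non-significant stretches
protecting all inner pairs; quantiles come from
`scipy.stats.studentized_range`, checked in the tests against a
numerical-integration CDF oracle. SNK runs unconditionally by default
(`require_significant=True` gates it on the omnibus test). Repeated
measures: balanced two-time split-plot decomposition — group tested
against subjects-within-groups, time and group×time against the
within-subject residual; with two time points sphericity holds
trivially. The one-group case satisfies F = t² of the paired t-test
exactly. α defaults to 0.05, two-sided.

The synthetic cohort draws white-adipose weight and LV collagen from a
shared latent factor (within-group ρ = 0.89) to emulate the reported
fat–fibrosis association; the pooled correlation additionally reflects
between-group mean alignment, and tests compare against the
model-implied pooled value.

## Pipeline and problem sizes

The demo pipeline uses 60 s waveforms at 500 Hz per animal (≈325 beats:
one full 300-beat spectral segment), 400×400 px tissue fields at
0.1 px/µm, and aortic rings at 1 px/µm — sizes chosen so a full
24-animal replication runs in well under a minute while exercising every
code path; all sizes are configurable upward for production use.
Determinism: every stochastic step takes an explicit integer seed;
per-animal seeds derive from the cohort seed via the root generator, and
grid placements hash the animal id with CRC-32.

## Known limitations

- The pressure simulator has no respiration-driven intra-beat coupling,
  no ectopy and no measurement drift; beat detection is validated on
  clean morphology plus Gaussian systolic noise only.
- The systogram convention ignores beat-interval jitter (no resampling);
  at the simulated jitter levels this is negligible, but severe
  arrhythmia would violate it.
- Synthetic tissue fields are spatially uncorrelated (see above).
- The repeated-measures decomposition assumes two time points; more
  require a general mixed model.
- No multiplicity control across endpoints is applied, mirroring the
  original analysis plan.
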