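# Methods

This note records the models, conventions and numerical choices behind
`flashkit`, in the order data flows through the package.

## The assay being modeled

A restrained male firefly emits fast defensive (alarm) flashes continuously
for tens of minutes. A spectrometer pointed at the light organ integrates the
565–569 nm band and stores one averaged count value per 100-ms bin; counts
are relative intensity units. Overhead, monochromatic LED light steps through
a schedule: for each of eight wavelengths (444, 463, 488, 515, 533, 597, 628,
663 nm), a 1-min dark segment precedes a 1-min exposure, at a dim (1×,
0.107 µmol m⁻² s⁻¹) and a bright (10×, 1.075 µmol m⁻² s⁻¹) photon-flux
level, 32 minutes in all. Wavelength order is uniformly randomized; dim/bright
order is randomized within wavelength. Ambient light changes the signals:
short and mid wavelengths (≤ 533 nm) brighten flashes and slow them; bright
short-wavelength light can stop signaling entirely; long wavelengths
(≥ 597 nm) do essentially nothing.

## Synthetic recordings

The generator's defaults are the study conditions; everything it does is
reproducible from one master seed via `numpy.random.SeedSequence` spawning
(separate child streams for cessation draws, flash timing/amplitude, and
detector noise, so toggling noise never moves a flash).

**Flash train.** A two-state burst/pause renewal process reconciles the fast
within-train kinetics (~200 ms pulses separated by 200–300 ms gaps, i.e. an
instantaneous rate of ~130 flashes/min) with the much lower long-run dark
rate of 43.167 peaks/min. Burst lengths are geometric; pauses are
exponential. The dark pause mean is not a free parameter: it is solved in
closed form so that expected flashes per cycle over expected cycle time
equals the target rate,

    pause = L / r − [(L − 1)·E(interonset) + pulse],   r = base_rate × m / 60,

where `m` is the current frequency multiplier. A frequency multiplier below
one both lengthens pauses and shortens the mean burst in proportion (floor of
one flash): reduced signaling appears as sparser, shorter bursts with longer
silences, which matches the observed rise in interpulse interval under light
and keeps single-segment rate estimates usable. With the default mean burst
of 2 flashes in darkness, dark pauses average ~2 s with occasional pauses of
10 s or more, and they lengthen markedly under light.

The default mean burst length is 2 flashes. Longer bursts (6–8) are equally
compatible with the printed summary statistics but make one-segment rate
estimates so clumped that group means at the study's segment length stop
being informative; 2 keeps the train "burst-like" while staying near the
renewal-process variance floor. The per-segment dispersion this produces is
substantially smaller than the between-individual SDs printed in the
published table, which is intentional: those SDs fold in natural variation
that the recovery analyses would otherwise have to average away.

**Time-varying rate.** Pauses are sampled from the integrated hazard
(1/pause-mean evaluated along the pause), not from the mean at draw time.
This matters twice: at segment changes, where the behavioral transient decays
exponentially with τ = 5 s (flash rate and amplitude both blend from the
previous segment's multiplier), and across segment boundaries spanned by a
long pause. Freezing the rate at draw time leaves a measurable excess rate
(~5–7%) in low-rate segments even after the 15-s trim, because each pause
lags the decaying target; hazard integration removes it. τ = 5 s puts
e⁻³ ≈ 5% of the transient at the analysis-window edge, a ≤ 0.5% rate bias
over the window.

**Pulses and noise.** Each flash is a raised-cosine pulse of width 200 ms,
analytically averaged into the 100-ms bins it overlaps and then scaled so its
maximum bin equals the nominal amplitude — the recorded peak of a flash is
its amplitude regardless of bin phase, which gives noise-free simulations
exactly recoverable peaks. Amplitude = 5420 counts × intensity multiplier ×
individual offset × lognormal jitter (unit mean, CV 0.25 by default; the
within-exposure jitter magnitude is a convention, not an inference). Detector
noise is Gaussian with mean 50 and SD 30 counts, clipped at zero: below the
200-count exclusion floor with probability > 0.999, as the extraction rule
assumes. Because pauses are exponential, two bursts can occasionally abut
with a near-zero pause; the resulting merged pulse pair is the one case where
detected count can fall below injected count (documented in the conservation
property, which conditions on gaps of at least two bins).

**Behavioral profiles.** A `ResponseProfile` maps (wavelength, level) to an
intensity multiplier, a frequency multiplier and a cessation probability;
dark is always (1, 1, 0). `ResponseProfile.from_reference()` reproduces the
published degree-of-change table: intensity multipliers equal the printed
intensity ratios; bright cells at ≤ 533 nm get cessation probability 0.5
(half the males stopped signaling) with conditional frequency multiplier
`printed_ratio / 0.5`, so the expected *observed* rate ratio — cessation
segments contribute zero flashes — still equals the printed column, while
intensity means (computed only over segments with flashes) track the
intensity multiplier directly. Cessation is drawn per bright exposure.
Individual random effects are lognormal multipliers on rate and amplitude
(unit mean, log-SD 0.2), reflecting high natural variation without a stated
magnitude.

**What the generator does not emulate.** No LED/filter optics, no spectral
bandwidth (single-band counts in, counts out), no courtship-flash spectrum,
no drift, flicker or saturation in the detector, and no within-trial
habituation beyond the per-segment transient — in particular, the generator
has no built-in exposure-order decay, which is why it doubles as the null
case for the order-effect test. Passing tests therefore show the pipeline is
correct and calibrated *for this data model*, not that real recordings meet
its assumptions.

## Extraction conventions

- **Trim:** the first 15 s of every segment is the adaptation period and is
  dropped; rates are normalized per minute over the remaining 45 s (a
  raw-count mode exists, `per_minute=False`; which normalization the original
  analysis used is not stated, and per-minute makes dark and light segments
  comparable).
- **Zeroing:** "zeroed within each recording" is implemented as subtracting
  the recording's 5th percentile and clipping at zero — robust while flashes
  occupy a minority of bins; subtract-the-minimum is available
  (`method="min"`).
- **Detection:** counts ≤ 200 after zeroing are noise (the floor itself is
  excluded). Each maximal run of above-floor bins yields one event per
  retained local maximum: plateaus take their earliest bin; two maxima are
  separate flashes only when the valley between them drops below 50% of the
  smaller maximum, and the run splits at the valley bin (which closes the
  earlier event). The 50%-dip convention is ours — at 100-ms bins and
  200–300-ms gaps true flashes almost always separate naturally. One known
  consequence: for bumps within 2× of the floor, raising the floor can split
  a previously merged run, so floor-monotonicity of the event count is only
  guaranteed for flashes exceeding twice the floor (real flashes are ~25×).
- **Morphology:** duration = number of above-floor bins × 100 ms; interpulse
  interval = offset-of-one to onset-of-next ("duration between flashes"), not
  onset-to-onset. Segments with no events report rate 0 and *missing*
  intensity/duration/IPI — cessation is never coded as zero intensity.

## Group analysis

- **Base values:** each specimen's first dark segment (validated to precede
  every light exposure) is averaged across specimens; degree of change is a
  plain quotient of group mean over base value. Interleaved darks are kept in
  the morphology output for diagnostics but, following the original design,
  are not the comparison baseline (they carry lingering effects of previous
  exposures).
- **Mixed models:** Gaussian linear mixed models (the printed mean ± SD
  reporting is symmetric; a Poisson GEE option exists for rate-as-count,
  `family="poisson"`), one model per response × level because a joint design
  is rank-deficient. Wavelength is a categorical fixed effect with initial
  dark as reference; specimen is a random intercept; rate models add an
  exposure-order (1–16) random intercept, dropped for intensity where it
  showed no effect. statsmodels' MixedLM fits the crossed intercepts as
  variance components within a single trivial group; each fit is run from two
  optimizers (Powell and L-BFGS/BFGS) and the higher likelihood kept, because
  quasi-Newton fits on these small crossed designs occasionally report
  convergence at a poor optimum. Each *baseline* recording gets its own order
  level: the initial darks are independent recordings, and giving them one
  shared order intercept would load the entire order variance onto the dark
  reference mean, making every dark-vs-wavelength test conservative
  (measured null rejection as low as 0.00–0.015 at α = 0.05 before the
  change, 0.02–0.09 with mean 0.052 after, over 100 replicate null studies).
  Wald p-values use a t reference with residual degrees of freedom
  (observations − fixed parameters), the safer small-sample choice. No
  multiple-testing correction is applied by default, matching the original
  per-wavelength reporting (`scipy`-based Holm adjustment is a one-liner away
  for users who want it).
- **Order effect:** a maximum-likelihood likelihood-ratio test (df = 1)
  comparing the light-only wavelength model with and without an order term.
  The default term is a numeric slope in order 1–16 — the natural estimator
  for a cumulative effect of previous exposures, and the variant whose null
  distribution is a clean χ²₁ (p-values uniform under the null; verified by
  simulation). An order-random-intercept variant (`mode="intercept"`) matches
  the wording of the original random-effects structure but tests on the
  boundary. Identical likelihoods return χ² = 0, p = 1 — the structural-zero
  case seen for flash intensity.
- **Correlation:** Pearson r across wavelengths between mean flash intensity
  and mean flash rate at one level; scale-invariant, so raw means and
  degree-of-change columns give the same value. At least three complete
  wavelengths are required.
- **Unreproducible by design:** the original per-wavelength p-values and
  order-effect χ² statistics derive from six specimens' raw recordings that
  were never deposited; the package reproduces their *structure* (sign
  patterns, calibration, power under built-in effects), not their values.

## Problem sizes and precision

The simulation-based checks use: 10,000 s of simulated darkness for rate
calibration (relative error ≲ 1%); 200 replicate six-male null studies for
type-I calibration of the dim-level rate tests (binomial SE ≈ 0.015 per
wavelength at α = 0.05); and one 30-male study with the published multipliers
(cessation disabled, so the frequency multipliers are exactly the printed
ratios) for degree-of-change recovery. At 30 specimens the worst cells —
bright short-wavelength exposures with ~6 expected flashes per 45-s segment —
have a relative standard error near 7% from renewal/Poisson noise alone plus
~4% shared baseline noise, so the ±15% recovery band sits at roughly 2
standard errors there: intensity ratios recover to ~3–4%, rate ratios
typically to ~8–13% with occasional excursions just past 15% on unlucky
seeds. The acceptance script reports the realized maxima rather than
clamping them.

## File formats

Traces: two-column delimited text (time_s, counts) at exact 0.1-s steps,
`#`-prefixed header lines tolerated, optional JSON metadata sidecar
(`<name>.meta.json`); values round-trip bit-identically. Schedules: YAML with
one entry per segment (order index, phase, wavelength_nm, level, start_s,
duration_s) plus the generating seed. Analysis tables: TSV with missing
values written as `NA`.
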