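# flashkit

Tools for studying how monochromatic ambient light at night reshapes the
bioluminescent flash signals of fireflies, built around the restrained-male
alarm-flash assay: a firefly (*Aquatica ficta*) is held in front of a
spectrometer that averages counts every 100 ms while an overhead LED steps
through a randomized schedule of 1-min dark and 1-min monochromatic exposures
(eight wavelengths, 444–663 nm, each at a dim 1× and a bright 10× quantum-flux
level). The package provides:

- **`flashkit.synthetic`** — a calibrated generator of spectrometer-like
  recordings with known ground truth: a burst/pause renewal flash train
  (raised-cosine pulses ~200 ms wide, 200–300 ms gaps, long-run dark rate
  43.167 peaks/min, dark peak amplitude 5420 counts), behavioral response
  profiles per (wavelength, intensity) including complete cessation, detector
  noise, and adaptation transients at every illumination change.
- **`flashkit.extraction`** — the photometric analysis pipeline: discard the
  first 15 s of each segment (adaptation period), zero each recording against
  its own baseline, isolate flash peaks as local maxima of runs above the
  200-count noise floor, and summarize per-segment morphology (mean peak
  intensity, peaks/min, flash duration, interpulse interval).
- **`flashkit.stats`** — the group analysis: dark base values from the initial
  dark recordings, degree-of-change ratios (group mean / dark base value),
  Gaussian mixed models of wavelength effects (specimen and exposure-order
  random intercepts), a likelihood-ratio test for the exposure-order effect,
  and the Pearson correlation between per-wavelength mean flash intensity and
  mean flash rate.
- **`flashkit.radiometry`** — irradiance (µW/cm²) ↔ photon flux
  (µmol m⁻² s⁻¹) conversion used to equalize stimuli across wavelengths:
  flux = P·λ/(h·c·N_A).
- **`flashkit.pipeline` / the `flashkit` CLI** — end-to-end orchestration and
  a self-contained reproduction of the published summary-level numbers.

## Worked example

Simulate a six-male study in which light has the published behavioral effect,
extract morphology, and fit the group analysis:

```bash
$ flashkit simulate --seed 7 --n-individuals 6 --out run7
base intensity 6008 counts, base rate 38.222 peaks/min
dim: intensity-rate correlation r = -0.8057
bright: intensity-rate correlation r = -0.5772
```

The base values are this cohort's initial-dark means (six specimens with
lognormal individual offsets around 5420 counts and 43.167 peaks/min). The
negative correlations recover the central trade-off: wavelengths that brighten
the alarm flashes also slow them. `run7/effects.tsv` is the per-(wavelength,
level) table — e.g. at 444 nm dim this run gives a mean flash intensity of
12342 counts (degree of change 2.05 relative to dark) and 23.6 peaks/min
(degree of change 0.62), while at 488 nm bright half the males cease signaling
and the rate collapses to 2.9 peaks/min. `run7/summary.json` holds the
correlations and the exposure-order likelihood-ratio test; missing intensity
entries (cells where a specimen never flashed) propagate as `NA`, never zero.

Radiometric helper — the same photon flux needs ~1.49× more power at 444 nm
than at 663 nm:

```bash
$ flashkit flux --power 52.3 --wavelength 444
1.94114 µmol m⁻² s⁻¹ at 444 nm
$ flashkit flux --target 0.107 --wavelength 444 --invert
2.88289 µW/cm² at 444 nm
```

`flashkit segment`, `flashkit extract` and `flashkit analyze` run the
individual pipeline stages on trace/schedule files (plain two-column text and
YAML; see `docs/methods.md`).

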