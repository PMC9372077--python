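# mhsfx — multi-hit serial femtosecond crystallography

Serial femtosecond crystallography (SFX) at MHz X-ray free-electron lasers
normally measures each protein microcrystal once. With pulse trains whose
pulses are separated by sub-microsecond intervals (e.g. 886 ns at 1.125 MHz),
a crystal riding a liquid jet can still be inside the X-ray focus when the
next pulse arrives, yielding two (occasionally more) diffraction patterns
from the *same* crystal — a route to tracking sub-microsecond structural
dynamics in a single crystal. `mhsfx` implements the analysis around this
*multi-hit* mode for scientists working with CrystFEL-style indexing streams:

- **stream_io** — read/write a subset of the CrystFEL stream format (chunks,
  crystal blocks, reciprocal bases a\*, b\*, c\* in nm⁻¹, reflection lists),
  with train/pulse identity recovered from event labels.
- **multihit** — the consecutive-hit classifier: two indexing solutions on
  adjacent pulses of the same train are one crystal when every angle between
  corresponding reciprocal basis vectors is < 5° and every basis-vector
  length agrees within 10%. Produces single/first/second-hit splits,
  orientation-change histograms and run summaries.
- **intensity** — data-quality diagnostics: I/σ(I) filtering, normalised
  mean-intensity vs 1/d ("powder") profiles, Wilson-B fits, and half-set
  correlations with CC\* = √(2·CC½ / (1 + CC½)).
- **beam_profile** — Lorentzian fits to beam-footprint images
  (3×3 median filter + 7.5% noise threshold), with FWHM = 2γ (50% of the
  beam) and FW = 7.04γ (82.4%), PSF correction and aggregate statistics.
- **transit** — the geometric model linking jet speed v, pulse spacing Δt
  and beam widths: interpulse travel d = v·Δt decides whether a second hit
  lands inside the FWHM, only in the tails, or not at all, and how many
  hits are possible (⌊(FW + 2e)/d⌋ + 1 with edge allowance e).
- **dose** — position-resolved per-pulse absorbed dose (MGy) for a crystal
  crossing a separable 2D Lorentzian fluence, Beer–Lambert photoabsorption,
  with a Gaussian-beam cross-check estimator.
- **synthetic_data** — a generator of stream files and beam images with
  planted ground truth (Poisson crystal arrivals, uniform random
  orientations, per-interpulse tumbling, Wilson falloff, noise) so the whole
  pipeline is testable end to end.

## Worked example

Simulate a slow-jet run (42 m/s, 886 ns spacing), detect double hits, and
inspect the transit regime:

```bash
$ mhsfx simulate --preset 42ms --n-trains 20 --seed 7 \
      --out sim.stream --truth truth.tsv
381 frames, 405 crystals, planted double fraction 0.9378

$ mhsfx detect --stream sim.stream --summary summary.json
double-hit crystals: 196 (93.8%), singles: 13

$ mhsfx regime --speed 42
double_in_fwhm  d=37.2 um  max_hits=2

$ mhsfx ccstar --cc-half 0.906
0.975

$ mhsfx dose-scan --out dose.tsv
7 partial + 26 full positions; max dose 0.034 MGy
```

Reading the output: with the default (purely geometric) hit window almost
every simulated crystal that can be hit twice is, and the classifier
recovers exactly the planted fraction (93.8%); experimental double-hit rates
are far lower because detection and indexing intervene — plant any target
fraction with `synthetic_data.hit_window_for_double_fraction`. At 42 m/s a
crystal travels d = 37.2 µm between pulses, less than FW/2 + FWHM/2 =
42.2 µm for the mean beam (FWHM 18.7 µm, FW 65.8 µm), so the second hit
occurs inside the FWHM. The dose scan steps an 8 µm crystal from the edge
of the modelled 100 µm region toward the beam centre: 7 of 33 positions are
partial hits, and the dose at the last scanned tail position is ~0.03 MGy
(the beam-centre dose with default material parameters is ~0.19 MGy, below
the ~0.2 MGy room-temperature damage benchmark).

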