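# Methods

This note documents the science implemented in `ft2dms`: the signal model,
the processing chain, the estimators, the synthetic-data generator, and the
numerical and design choices a maintainer or reviewer would want spelled
out.

## Signal model

A narrowband 2D FT-ICR experiment records a real stack s(t₁, t₂): n₁
transients of n₂ detection samples, one per encoding-delay increment.  Two
encoding pulses of duration T₁ separated by t₁ modulate the precursor
radius as

    r(t₁)/r₀ = (1 + cos 2π(f_ICR − f_min)(t₁ − T₁)) / 2,

where f_ICR is the precursor cyclotron frequency and f_min the lowest
frequency of the chirp pulses (the pulse generator's phase reference).  A
centre-of-cell fragmentation period τ_m converts de-excited precursors
into fragments, so fragment abundance is proportional to 1 − r/r₀ — the
*inverted* modulation, which is where the π phase shift between fragment
and precursor signals in the vertical dimension comes from.  A third pulse
re-excites everything for detection.

Phases carried by the detected signals:

* fragment, horizontal: φ_f,h(f₂) = c₂f₂² + c₁f₂ + c₀ +
  2πf_min(2T₁ + t₁ + τ_m).  The quadratic part is the chirp-excitation
  phase; the additive term is the generator's pulse-start phase.
* precursor, horizontal: φ_p,h(f₁) = c₂f₁² + c₁′f₁ + c₀ + 2πf₁t₁ with
  c1′ = c₁ + 2π(T₁ + τ_m + T₂ + T₃).  The 2πf₁t₁ term makes precursor
  phases t₁-dependent, which is why the fragment correction function
  cannot phase autocorrelation-line precursor peaks (they come out with
  rolling phase / negative intensity instead — a useful diagnostic).
  The first-order assembly adds delay terms (seconds) to a rad/Hz
  coefficient; we read this as c₁′ = c₁ + 2π·(delays), with a
  `delays_2pi=False` switch for the literal sum.
* vertical: φ(f₁) = 2π(f₁ − f_min)(t₁ − T₁), plus π for fragments.

## Processing chain

Absorption mode (order is fixed):

1. row apodization (shifted sine-bell, maximum at 15% of the record),
2. row zero-fill (2 doublings by default),
3. row complex FT of the real transient, positive half kept
   (forward kernel e^{−i2πft}),
4. digital demodulation: each row multiplied by e^{−i2πf_demod t₁},
   cancelling the generator roll (f_demod = f_min, or measured, see below),
5. quadratic phase correction applied to each complex row
   (multiplication by e^{−iφ(f₂)}; after demodulation one set of
   coefficients serves every row, with 2πf_min(2T₁+τ_m) folded into c₀),
6. drop of the row imaginaries (axis-2 imaginary planes),
7. column apodization and zero-fill,
8. column FT of each retained real plane ("real FT" of the
   amplitude-modulated columns), assembling the bicomplex quadrants
   RR/RI/IR/II,
9. linear vertical correction applied as an i-rotation: slope f_N·T₁
   turns across the band (overridable), π shift for fragments, optional
   extra zero order,
10. drop of the column imaginaries.

Magnitude mode skips steps 5 and 9, zero-fills once per axis by default,
and returns √(RR² + RI² + IR² + II²).

The bicomplex convention: i rotates axis 1 (vertical), j axis 2; RI is the
i-component and IR the j-component; i² = j² = −1, k = ij, k² = +1.  This
ring is commutative — it is not the quaternions — so the two axis
rotations commute and can be applied in either order.

### Demodulation frequency from split peaks

Demodulating at a frequency wrong by δ leaves a residual rotation
e^{i2πδt₁} that splits every vertical peak into a pair 2δ apart.  The
workflow (`estimate_demod_from_split`, or `f_demod="auto"` in the
pipeline) processes at the nominal frequency, measures the split, takes
δ = separation/2, and resolves the sign by reprocessing both candidates
and keeping the one that removes the split.  Accuracy is one vertical bin.

### Quadratic coefficient estimation (tangent method)

Small spectral regions are phased with local *linear* functions
(p₀, p₁); each such line is a tangent of the overall quadratic, so the
slope constraints p₁ = 2c₂f_c + c₁ form a wrap-free least-squares system
for (c₂, c₁) — no unwrapping across a band whose phase spans thousands of
turns — and c₀ follows as a circular mean.

How (p₀, p₁) is read from a region matters.  A lone resonance line carries
one constant phase times its lineshape, so a single line cannot fix p₁;
regions must contain at least two lines (in practice: isotopic clusters).
We first implemented the obvious approach — minimizing a dispersion
objective (negative-lobe area plus peak asymmetry) over a (p₀, p₁) grid —
and measured that its optimum is displaced from the true phase by tens of
percent in p₁ for damped, off-grid lines: the dispersion tails and the
flat baseline a one-sided DFT puts under each line bias the score.  The
shipped estimator therefore fits each region with a sum of complex
Lorentzians sharing one decay rate (the frequency-domain shape of
exponentially damped sinusoids), reads each line's phase from its fitted
complex amplitude, and takes p₁ as the amplitude-weighted least-squares
slope through the unwrapped line phases.  For a quadratic overall phase
the weighted slope equals the derivative at f_c = f̄ + m₃/(2m₂)
(weighted mean plus a third-moment correction), so the tangency triple is
exact up to fit error.  The dispersion objective is retained as the
quality score, for single-peak zero-order phasing
(`estimate_zero_order`, with a peak-positivity anchor), and for its
documented properties (≈0 for a phased peak, maximal at a π rotation of a
compact peak, 2π-periodic).  Estimation should run on unapodized,
exponentially damped spectra; the averaged demodulated row spectrum of a
2D stack works directly.

Measured performance on synthetic data (five two-line clusters across the
band, line spacing 150 Hz): c₂ recovered to ~0.1% noiseless and within 5%
at spectral S/N ≈ 100.  A chirp-theory seed c₂ ≈ π/(sweep rate) is
available as `chirp_c2_initializer` but never asserted against data.

### Vertical phase and fold-overs

The vertical correction slope is f_N·T₁ turns over the band
(f_N = 1/(2·t₁ dwell); 50 µs increments give the 10 kHz convention, and
10 kHz × 739 µs = 7.39 turns).  An operator override in turns is
supported, as refinement beyond the theoretical value is expected
practice.

For aliased signals the phase rule "180° per fold" holds exactly when T₁
is an integer multiple of the t₁ dwell; otherwise each fold pair leaves an
additional smooth residual 2πk·f_s·T₁ that is constant for peaks with a
common fold count and is absorbed by the zero-order term during operator
phasing.  The package therefore treats the sign rule the way it is used:
zero-order phase the fundamentals, then read signs — fundamentals with
even fold counts positive, odd-folded 2ω harmonics negative.  With the
study band plan (modulation ≈146.3 kHz, 10 kHz band, T₁ = 739 µs) the
harmonic sits ≈122° from the fundamental, comfortably negative after the
fundamental is phased.

## Synthetic-data generator

`simulator.synthesize` writes the model above directly into the time
domain: fragment terms with the inverted modulation envelope, the
generator phase roll, the chirp quadratic at each detection frequency;
optional detected-precursor terms with the precursor phase law (including
2πf₁t₁); optional fully de-excited unfragmented precursors carrying the
fragment phase law (flag-controlled); optional 2ω harmonic amplitude
components; exponential damping; white Gaussian noise from a seeded
generator (bit-identical stacks per seed).

Defaults follow the narrowband study conditions: T₁ = 739 µs (739 sweep
steps × 1 µs), T₂ = 14.78 ms (× 20 µs for detection excitation),
T₃ = 3 ms, τ_m = 60 ms, f_min = 74 728.13 Hz, f_max = 535 714.29 Hz,
1024 t₁ increments of 50 µs.  Damping defaults to one third of the
detection record, a typical narrowband decay; pass `np.inf` for the
undamped delta-line oracles.  Fragmentation efficiency is the linear map
1 − r/r₀ (only "maximal at centre" is physically constrained); harmonics
are injected as explicit amplitude components without modelling their
electrostatic origin.  Fold-overs are produced physically — the generator
writes true high modulation frequencies and aliasing arises from the t₁
sampling itself — so the analysis-side fold bookkeeping is exercised
independently.

What the generator does *not* emulate: ion-cloud physics and space
charge, frequency drift, scintillation/multiplicative noise, isotope fine
structure (isotope patterns are user-supplied abundance lists), and
non-uniform t₁ sampling.  Passing tests therefore validate the
transform/phase algebra and the estimators under the stated signal model,
not robustness to every instrumental artefact.

## Metrics

S/N is peak height over the RMS-about-zero of a signal-free window —
about zero, not about the Rayleigh mean, which makes the theoretical
absorption gains exact in expectation: complex-FT baseline noise is
Rayleigh with power 2σ² (→ √2 gain in 1D) and 4-quadrant hypercomplex
noise has power 4σ² (→ factor 2 in 2D).  FWHM is read by linear
interpolation of the half-height crossings (no model fit); positions are
refined by a 3-point parabola; ties break toward lower frequency.
Resolving power is (m/z)/FWHM; with ~1 Da isotope spacing a resolving
power R keeps isotopic envelopes resolved up to R × 1 Da (14 kDa at
R = 14 000).  m/z conversion is the one-term law f = K/(m/z) with K from
a single anchor; the anchor is a configuration choice because printed
anchor pairs from real calibrations are typically inconsistent at the
10⁻⁴ level (a two-term law absorbs the difference on-instrument).

## Numerical choices and problem sizes

* FT sign convention e^{−i2πft} everywhere; positive-half spectra; axis
  bin b ↦ b/(M·dwell) for filled length M.
* "Zero-filled twice" is read as two successive length doublings,
  configurable as an integer.
* Angles are radians inside the library; `turn`/`deg` suffixes are parsed
  at the CLI boundary only.
* All spectral planes are float64; HDF5 layout version 1 with groups
  /transient, /spectrum, /processing (config snapshot as JSON).
* The test-suite and acceptance experiments run at desk scale chosen to
  keep every oracle exact: transform oracles on grids ≤ 32×32 against an
  O(N²) DFT; S/N experiments at 16 384 points (1D, 100 noise seeds) and
  128 × 4 096 (2D, 20 seeds); phase round-trips on 256 × 8 192 stacks.
  The exact-phase S/N experiments use undamped on-grid lines with no
  apodization or zero-fill so that lines are single bins and the measured
  ratios carry no lineshape corrections.

## Known limitations

* Broadband 2D phasing (hyperbolic dissociation-line geometry, automated
  coefficient search) is out of scope; the tangent estimator needs
  operator-chosen or auto-picked multi-line regions.
* The Lorentzian region model assumes exponential damping; strongly
  truncated (undamped) or heavily apodized lines should be estimated from
  an unapodized processing pass.
* The shifted sine-bell is defined by its stated maximum position and
  endpoint zero; other implementations may differ at the first sample.
* Single-anchor m/z calibration only; no isotope deconvolution, charge
  deconvolution or identification.
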