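# Methods

This note documents the models, numerical choices, and limitations behind
`hfire-bench`. The package has two halves: a *measurement chain* (waveform
construction, trace filtering and reduction, shape-factor inversion,
statistics) that mirrors how bench recordings are analyzed, and a *synthetic
bench* (tissue model + virtual oscilloscope) that generates traces with the
statistical structure the chain assumes, so that recovery can be tested
end-to-end with known ground truth.

## Burst model and spectral characterization

A burst is `cycles` repetitions of `[+pulse (PW), gap d1, −pulse (PW),
gap d2]`, starting positive, sampled uniformly (default 2 ns, which places
500 points on a 1 µs pulse). When a protocol does not fix the cycle count,
it defaults to the smallest count reaching 100 µs of on-time
(`ceil(100 / 2·PW)`), the usual way short bipolar pulses are matched to a
conventional long-pulse dose.

The *characteristic frequency* is defined as the reciprocal of one full
cycle period, `1/(2·PW + d1 + d2)`. This is a definition, not an estimate:
for ideal square bursts the dominant nonzero peak of the magnitude spectrum
falls in the same FFT bin, and the package asserts that agreement rather
than assuming it. Spectra are plain one-sided FFT magnitudes of the ideal
waveform (optionally unit-energy normalized); only relative frequency
content is meaningful, and no attempt is made to estimate a measured
impedance spectrum.

Pulse boundaries are placed by rounding ideal start times to the sample
grid, with every pulse spanning exactly `round(PW/dt)` samples. For
protocols commensurate with the sampling period (all the standard ones are)
this makes positive and negative on-times — and hence the burst's mean —
exactly zero; non-commensurate protocols can carry a ±1 sample imbalance
per pulse, which is why the charge-balance property is guaranteed only on
grid-commensurate protocols.

## Trace reduction

Both recorded channels are filtered with a first-order low pass,
`y[n] = y[n−1] + α(x[n] − y[n−1])`, `α = dt/(τ+dt)`, with τ = PW/3. The
backward-Euler α differs from the exact `1 − exp(−dt/τ)` by < 0.01% at the
2 ns / (1 µs)/3 operating point. The filter is initialized at `y[0] = x[0]`
so the first pulse is not corrupted by a startup transient; the consequence,
verified in tests, is that the very first pulse is essentially unattenuated
while subsequent pulses peak near `(1 − e⁻³) ≈ 0.9502` of the plateau (a
from-rest square pulse reaches exactly that value at its end, t = 3τ). The
median over pulses makes the burst values insensitive both to this first
pulse and to isolated corrupted pulses.

Because voltage and current pass through the identical filter, the
attenuation cancels in `R = V/I`; no plateau correction is applied to the
per-channel magnitudes, which are reported as processed. The residual bias
on R from the capacitive overshoot on the current channel is below 1% at
the default transient settings.

Segmentation uses protocol timing (recordings are generator-synchronized);
a polarity-crossing detector with a 10%-of-max threshold is available for
imported traces without timing metadata. Traces shorter than the protocol
are rejected, not padded; clipped/saturated samples are not detected or
corrected.

## Geometry and conductivity inversion

Configurations use the bench's mixed units (mm, cm, µs, V/cm); all physics
is SI internally. Distance-normalized voltage (V/cm) maps to amplitude via
sample thickness (plates) or center-to-center spacing (needles).

Plate measurements invert to conductivity with the prism shape factor,
`σ = l/(A·R_B)`. The synthetic bench draws each replicate's sample thickness
from N(6 mm, 0.2 mm) truncated positive and the inversion uses the recorded
per-sample thickness, mirroring the caliper correction used with real
samples. Needle-pair resistances are *not* inverted by default: the
non-uniform field couples electroporation dynamics into the measured R, so
`conductivity_curve` refuses needle input unless explicitly overridden, in
which case the infinite-medium two-cylinder shape factor
`S = πL/acosh(D/2a)` is used and the caveat stands.

## Synthetic tissue model

The generator is deliberately lumped: one conductivity per trace (or per
instant, in mechanistic mode), one resistance through the geometry's shape
factor, additive Gaussian noise.

* **Phenomenological mode** (the contract surface): σ depends only on the
  applied distance-normalized field and the pulse width.
  `σ(E) = σ_bulk(PW) + (σ_max(PW) − σ_bulk(PW))·s((E−E_th)/w)`. The
  smoothing function `s` is a C² quintic smoothstep clamped to [−1, 1]:
  exactly 0 below `E_th − w`, exactly 1 above `E_th + w`, 0.5 at `E_th`.
  The clamped floor matters: with the tuber preset (transition 500 V/cm,
  half-width 150 V/cm) the 100 V/cm level must measure the bulk value
  exactly, which a logistic tail would visibly violate. Between tabulated
  pulse widths, σ values interpolate linearly and clamp at the ends.
* **Mechanistic mode** (qualitative): within each pulse,
  `σ(t,E) = σ_ss(E) + (σ_hf − σ_ss(E))·e^(−t/τ_mem)` with τ_mem ≈ 1 µs —
  while the membrane charges it shunts current, so short pulses see a
  higher apparent conductivity. σ_hf is the bulk value at the shortest
  tabulated pulse width and σ_ss the sigmoid at the longest. The mapping
  from membrane charging to the measured per-pulse-width bulk values is not
  identifiable from apparent quantities alone, so this mode is for
  qualitative pulse-width studies only, and the phenomenological mode is
  what the acceptance benchmarks use.

Tuber preset: σ_bulk = 0.13 S/m (1 µs) / 0.04 S/m (10 µs); σ_max = 0.55 /
0.67 S/m; E_th = 500 V/cm with w = 150 V/cm, placing the conductivity rise
between ~350 and ~650 V/cm. The cardiac preset is a labelled synthetic
placeholder (~0.2 S/m baseline) for exercising the cardiac geometry only.

Other generator features: a capacitive overshoot at each pulse onset
(default 10% of the plateau current, τ = 0.2 µs — short enough that the
τ = PW/3 filter's purpose is exercised by 1–2 µs pulses); optional
first-order generator rise time (off by default); relative Gaussian noise
per channel (default 1% of the pulse plateau; bench noise was not
characterized, this is a plausible oscilloscope figure).

Noise is drawn per segment (pulse or gap) from seeded substreams keyed by
`(trace seed, channel, segment kind, segment index)`. Two traces that
differ only in their delay durations therefore share identical per-pulse
noise under the same seed — delay invariance holds sample-for-sample, not
just in distribution. All seeds derive from user-supplied integers through
`numpy` `SeedSequence`; runs are bit-reproducible across platforms.

**Delays are not inputs to the tissue model, and no state crosses bursts or
ramp levels.** The delay-invariance and ramp-memorylessness findings are
thus true by construction in the generator; what the statistics test is
whether the *measurement chain* correctly reports them (type-I error
calibration) and whether it would detect violations (power against injected
effects: a conductivity increase proportional to d2, and a resistance
carry-over across ramp levels — both test hooks, off by default).

What the generator does **not** emulate: spatial field non-uniformity in
the lumped traces (handled separately by the field module), reversible
electroporation recovery between bursts, thermal effects, electrode–tissue
contact impedance, cell-scale pore dynamics, and drift or clipping in the
instrumentation. Passing recovery tests therefore demonstrate correctness
of the analysis chain under the stated model, not fidelity of the model to
any particular tissue.

## Statistics

Welch's t (unequal variances, Welch–Satterthwaite df, two-tailed) and
one-way ANOVA with Tukey–Kramer HSD (studentized-range p-values, all
k(k−1)/2 pairs) are computed from their closed forms; scipy supplies the
reference distributions, and independent scipy implementations serve as
oracles in the tests. α = 0.05 throughout; significance markers follow the
*, **, ***, **** convention. ANOVAs run per (pulse width, level) cell with
no correction across cells beyond Tukey within each ANOVA — matching
per-panel testing practice; a caveat, not a recommendation. Under the null
generator both tests' empirical type-I error at n = 8 is verified to lie in
[0.03, 0.07].

## Field and ablation forward model

The needle-pair field is computed on the electrode-midline 2D cross-section
(per unit length, scaled by the electrode exposure), two ways:

* **Analytic**: image line sources at `±√((D/2)² − a²)` give the exact
  potential of two conducting cylinders in a uniform medium; electrode
  surfaces are exact equipotentials at ±V/2.
* **Finite difference**: `∇·(σ(E)∇φ) = 0` on a uniform grid (5-point
  stencil, harmonic-mean face conductivities), Dirichlet electrodes,
  insulating outer boundary, Picard iteration on σ with under-relaxation
  0.7 that halves adaptively whenever the φ-residual fails to shrink
  (sharply sigmoidal σ(E) otherwise oscillates); tolerance 1e−6 on the
  relative φ change, max 500 iterations, failure raises with the residual.
  Default grid: 100 µm spacing on a 5 cm square domain — chosen so the
  uniform-σ solve matches the analytic shape factor to ~1%, with the
  electrode mask radius inflated by half a cell because a pinned node
  represents a half-cell of conductor (without this the staircase boundary
  inflates R by ~5% at this resolution). Plate geometry solves the
  rectangle between the plates and scales by the circular sample area
  (exact for uniform σ).

Ablation area is the cell-count area with `E ≥ EFT` outside the electrodes,
on the midline slice (directly comparable with stained cross-sections).
Lethal-threshold presets per pulse width (1 µs: 1000 V/cm … 10 µs:
600 V/cm) are literature-informed placeholders, not measurements; with
them, predicted areas increase with pulse width, qualitatively as observed.
Since neither field route takes delay parameters and σ(E) is
delay-invariant, predicted fields and areas are delay-invariant as an
identity.

## Problem sizes

Single-shot recoveries (conductivity benchmarks, closed-form checks) run at
the full recording conditions: 2 ns sampling, 100 µs on-time bursts, 9-level
plate ramps, 3 bursts per level, n = 8 replicates, 1% noise. Monte Carlo
rate estimates (delay-invariance false-positive/power rates, ramp-memory
rates; 100 seeded repetitions each) run scaled down — 10 ns sampling,
10-cycle bursts for 1 µs pulse widths, 2–3 field levels — sizes chosen so
hundreds of repetitions stay tractable while keeping the statistical
contract (n = 8 per group, α = 0.05, ±10%/−20% injected effects) unchanged.
The FD oracle comparisons use 100 µm grids on 2–5 cm domains as noted above.

## Known limitations

* The per-pulse-width bulk conductivities and the membrane-charging time
  constant are not jointly identifiable from apparent measurements; the
  mechanistic mode is qualitative by design.
* The two-cylinder shape factor is an infinite-medium approximation; at
  finite insertion depths and near boundaries it overestimates conductance.
* The FD solver is 2D; end effects at the electrode tips are not modelled.
* Imported-trace support assumes the fixed CSV dialect (comma, dot decimal,
  header, seconds) and rejects rather than repairs non-uniform sampling.
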