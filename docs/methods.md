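# Methods

This note documents the models, estimators and conventions implemented in
`ampakit`, the defaults they ship with, and what the synthetic-data
generators do and do not emulate.

## Integrate-and-fire model and rheobase search (`core_model`)

The model cell is a leaky integrate-and-fire (LIF) point neuron driven by a
single double-exponential synaptic conductance:

    C_M dV/dt = (E_leak − V)/R_in + g(t) (E_rev − V)
    g(t) = g_peak [exp(−(t−t0)/τ_decay) − exp(−(t−t0)/τ_rise)] / N

with N the analytic maximum of the bracketed difference, so that `g_peak` is
literally the peak conductance.  Default parameters (all configurable, YAML
round-trip provided): τ_M = 10 ms, E_leak = −70 mV, R_in = 160 MΩ,
C_M = τ_M/R_in = 62.5 pF, V_thresh = −37 mV, V_peak = 20 mV,
V_reset = −80 mV, E_rev = 0 mV, τ_rise = 1.4 ms, forward Euler with
Δt = 0.1 ms.  The printed leak reversal is taken as −70 mV (a resting
potential of +70 mV would be unphysiological for a cortical interneuron; the
measured resting potential of the modelled cell class is −70 ± 2 mV).

Integration conventions, frozen after a systematic comparison of forward-
Euler variants against the reference rheobase values (see below):

* the conductance drive for each Euler step is the average of g(t) at the
  two step endpoints;
* the threshold test `V ≥ V_thresh` is applied after each Euler update; the
  crossing sample is displayed at V_peak (no effect on dynamics), the next
  sample is forced to V_reset, and integration resumes from there.  The
  spike thus occupies two samples (0.2 ms); there is no further refractory
  mechanism;
* the synaptic conductance waveform is unaffected by spiking.

The first/second **rheobase conductance** (lowest peak conductance driving
≥ 1 or ≥ 2 spikes) is found by bisection over `g_peak`, default bracket
[0, 100] nS, 15 iterations (resolution ≈ 0.003 nS), returning the final
bracket midpoint.  Spike count is verified to be a non-decreasing step
function of `g_peak` at the bracket endpoints; an invalid bracket raises.
With the defaults the search yields 13.15 / 22.15 nS (τ_decay = 3 ms,
1 / 2 spikes) and 11.23 / 17.80 nS (τ_decay = 5 ms), within 0.12 nS of the
reference values for this parameterisation (13.03 / 22.09 / 11.15 /
17.76 nS).  No Euler variant we tested (conductance sampled at step start,
midpoint or end; spike consuming zero, one or two samples; threshold tested
before or after the update; grid-sampled vs analytic kernel normalisation;
single precision) reproduces all four reference values to the second
decimal; the frozen convention is the only one placing all four within
0.15 nS, and the residual mismatch is attributed to unpublished details of
the original integrator.  Because the midpoint of the final bracket can sit
marginally below the true threshold, code that needs a guaranteed spike
count at rheobase should simulate at `RheobaseResult.bracket[1]`.

The **dynamic-clamp emulation** reproduces the discrete hardware loop of a
conductance clamp in software: at each loop tick (default 30 kHz) the
membrane potential is read, the current i = g(t)(E_rev − V_m) is computed
from the voltage read one tick earlier (one-tick delay, zero-order hold),
and held until the next tick while the membrane integrates at Δt.  When the
loop rate exceeds 1/Δt the integration step is refined to the tick length.
In the fast-loop limit the emulation converges to the direct simulation
(verified subthreshold to < 0.5 mV).

**Response metrics**: AP latency = first spike − conductance onset;
response duration = first-to-second spike interval (undefined below two
spikes, reported as `None`); for subthreshold runs, the EPSP peak latency
and a rise time constant from a single-exponential fit to the 20–100 %
rising phase.  The single-exponential rise fit is a convention — the
reference analysis reports a dynamic-clamp EPSP rise time constant without
stating the fit — and is documented as such.

## Rectification statistics (`rectification`)

All voltages are corrected for the liquid junction potential before
analysis: membrane potential = command − junction potential (10 mV default
for evoked/paired-style data, 11 mV for mEPSC data; configurable per
dataset).

* **RI_slope**: ordinary least squares on I–V points with negative (inward)
  current gives slope s1 and the reversal potential E_rev = −intercept/s1;
  a second fit on all points with V > E_rev, constrained through
  (E_rev, 0), gives s2; RI_slope = s2/s1.  The s1 regime is current-sign
  defined (points with exactly zero current do not enter it); the s2 regime
  is voltage defined, so fully blocked zero-current points above the
  reversal count toward s2 — this is what makes a complete outward block
  yield RI_slope = 0.  Fewer than two points in either regime, or s1 ≤ 0,
  raises.
* **I–V normalisation**: each curve is divided by |I(−60 mV)| (interpolated
  if −60 mV is not sampled; curves not covering it are excluded with a
  warning), then averaged per voltage with SEM.  Keeping the sign means an
  inward current at the reference voltage normalises to −1.
* **RI_+60/−60**: summed fitted mEPSC charge over equal-length epochs at
  +60 and −60 mV commands, each sum divided by the absolute driving force
  at the junction-corrected potential (49 and −71 mV for an 11 mV junction
  potential and E_rev = 0).  The driving-force rescaling convention is
  chosen so that an ohmic, non-rectifying conductance maps to exactly 1 and
  a fully blocked one to 0; the reference analysis states only that the
  ratio was "adjusted" for the junction potential, so this is our
  convention, not a claim about the original computation.
* **NMDA/AMPA ratio**: AMPA = mean current in a 1 ms window centred on the
  first-EPSC peak at −60 mV (peak located on a 0.5 ms-smoothed copy within
  10 ms of stimulus onset); NMDA = mean current in the same-width window
  20 ms later at +50 mV; ratio = NMDA/|AMPA|.
* **Wash-in effect**: mean(treatment)/mean(baseline) × 100, guarded by a
  baseline-stability contract (t test of Pearson's r of amplitude against
  sweep index; P < 0.05 flags the baseline unstable, mirroring the
  discard-or-truncate rule used for recordings).

## Miniature-EPSC analysis (`mepsc`)

Traces are zero-phase (forward–backward) low-pass Butterworth filtered,
order 4, 2 kHz cutoff.  Only the cutoff is prescribed by the reference
procedure; order 4 and zero-phase application are our choices (note that
forward–backward filtering doubles the attenuation, so the gain at the
cutoff is −6 dB rather than −3 dB).

Detection is threshold crossing at 2.5 × the background-noise SD in the
event direction (inward at negative holding potentials, outward at
positive).  The noise SD is estimated as MAD/0.6745 on the filtered trace,
then re-estimated once with detected events masked out.  With the default
synthetic noise SD of 3.2 pA the threshold is 8.0 pA.  Each suprathreshold
excursion yields one candidate; candidates must be separated by the event
window (10 ms) unless the signal returns below half-threshold between
peaks, in which case overlapping events are kept as separate candidates.
Excursions that stay above threshold for less than `min_duration`
(0.5 ms default) are discarded: at a 2 kHz bandwidth such crossings are
briefer than the filter's own impulse response and cannot be synaptic.
This duration gate is our automated stand-in for the manual visual triage
of the original procedure; setting `min_duration=0` recovers the raw
level-crossing behaviour, whose false-positive rate on pure Gaussian noise
matches the Rice formula (verified in the tests).

Each candidate snippet (1 ms of pre-onset baseline to 10 ms after onset,
truncated at the next candidate's onset so overlap does not distort the
fit) is least-squares fitted with the product form

    I(t) = A (1 − exp(−(t−t0)/τ_r)) exp(−(t−t0)/τ_d),  t ≥ t0

with τ_r ≤ 10 ms and τ_d ≤ 50 ms (a quantal event cannot be slower than
the window it was detected in).  The reference analysis cites an empirical
fit equation without printing it; the product form is the standard choice
in the cited tradition and has the analytic integral A τ_d²/(τ_r + τ_d),
used for the per-event charge.  Amplitude, 20–80 % rise time and charge
are all taken from the fitted waveform; a non-convergent or
noise-dominated fit flags the event `unfit` and excludes it from charge
sums.  Triage accepts events with fitted 20–80 % rise times below 0.4 ms
(fitted rather than raw rise times, for noise robustness).  Epoch charge
statistics sum the fitted charges of accepted events whose onsets fall in
fixed-length epochs (100 ms default).

On the default synthetic conditions (12 Hz Poisson events, 20 pA mean
amplitude, 3.2 pA noise, 60 s) the pipeline recovers the programmed rate
and mean charge within a few percent (tested at the 10 % level).

## Morphometry (`morphometry`)

Morphologies are standard 7-column SWC trees, analysed in a 2D
(lateral, depth) projection with the pia at depth 0 and horizontal layer
boundaries.  Parent links are validated (dangling ids, cycles).

* **Density maps**: each compartment contributes a 2D Gaussian of mass
  equal to its length (σ = 25 μm).  Implementation: length-weighted
  histogram of compartment midpoints (5 μm bins) convolved with a
  unit-mass Gaussian kernel, which preserves total mass; per-cell maps are
  centred on the soma (lateral) and the L4/L5 boundary (depth), mirrored
  about the soma's vertical axis, normalised to unit maximum and averaged.
  The gamma exponent (default 0.5) is display-only.  The small
  pia-alignment rotation is the identity for the axis-aligned synthetic
  morphologies generated here.
* **Sholl profiles**: counts of compartments whose endpoint distances to
  the soma straddle circles at 6.5 μm radius increments (half-open
  d_min ≤ r < d_max so a compartment touching a circle is counted once).
* **Convex hulls**: gift-wrapping (Jarvis march), counter-clockwise,
  collinear points excluded from the vertex set; the ensemble hull is the
  hull of the union of per-cell hulls and their mirror images.  The hull
  fraction above a layer boundary is computed on area (exact polygon
  clipping via shapely), the most natural reading of a "percentage amount"
  of a hull; a vertical-extent-based reading was considered and rejected.
* **Per-layer lengths**: each compartment's length is apportioned to
  layers in proportion to its depth extent inside each band; arbors beyond
  the outermost defined boundaries count toward L1/L6 with a warning.
* **Clustering**: basket cells are clustered on a single feature (axon-hull
  area fraction above the L2/3–L4 boundary) by agglomerative single-linkage
  clustering with squared Euclidean distances, cut at 25 % of the maximum
  merge height (clusters = connected components below the cut; this is our
  reading of the best-cut criterion, which the reference procedure does not
  spell out).  A plain fuzzy c-means run (c = 2, fuzzifier m = 2,
  deterministic quantile initialisation) provides an independent check;
  the best-permutation label agreement is reported.

## Synthetic data (`synthetic_data`)

The generators emulate the statistical structure of the study conditions
and provide exact ground truth; they are not biophysical models.

* **I–V families**: I(V) = g_max (V − E_rev)(1 − b(V)) with
  b(V) = 1/(1 + exp(−(V − V_half)/k)) emulating the polyamine outward
  block.  The calcium-permeable (BC) preset uses V_half = −10 mV,
  k = 12 mV, chosen to give strong inward rectification (RI_slope ≈ 0.1)
  with a realistically smooth knee; calcium-impermeable presets (MC, PC)
  have b ≡ 0.  E_rev defaults to 0 mV.
* **EPSC trains**: five pulses at 30 Hz; pulse k is scaled by ppr^k, so the
  second/first ratio equals the preset paired-pulse ratio (0.36 depressing
  for BC inputs, 5.2 facilitating for MC inputs) — a deterministic
  geometric progression, not a resource model, because only the
  paired-pulse summary is constrained.  Kernels are difference-of-
  exponentials with Table-style kinetics (τ_rise 1.8/1.9 ms, τ_decay
  2.9/5.1 ms); the first-pulse amplitude comes from the preset I–V model at
  the holding potential; Gaussian noise is added on top.
* **mEPSC recordings**: Poisson onsets at 12 Hz; lognormal quantal
  conductances (CV 0.3 — the amplitude distribution is not specified by
  the reference data, lognormal is the conventional choice) scaled so the
  mean amplitude at −60 mV is 20 pA; per-event current = g_q (V − E_rev)
  (1 − b(V)), which programs the rectification the charge-ratio estimator
  must recover; fast somatic kernels (τ_r 0.12 ms, τ_d 3 ms) and 3.2 pA
  Gaussian noise (so the 2.5 SD detection threshold is 8.0 pA).
* **Morphologies**: stochastic random-walk trees inside class-specific
  laminar envelopes over representative layer boundaries (100 / 350 / 450 /
  700 μm): Martinotti-type cells have an ascending axon reaching L1 and
  descending dendrites; type-1 basket cells ramify the axon in L2/3 but
  never enter L1; type-2 basket cells keep the axon near L5.  Soma always
  in L5.

What the generators do **not** emulate: receptor gating kinetics, dendritic
cable filtering (beyond the slowed kernel time constants), correlated or
non-stationary noise, electrode artefacts, true anatomical branch
statistics, and 3D arbor structure (z is cosmetic jitter).  Passing tests
therefore demonstrate correctness of the estimators under idealised
conditions, not robustness to every pathology of real recordings.

## Problem sizes and numerical choices

Simulations use 100 ms at Δt = 0.1 ms; bisection uses 15 iterations over
[0, 100] nS.  Synthetic mEPSC test recordings are 60 s (about 720 events),
and the charge-ratio convergence check uses ~1000 events per polarity.
Geometric operations are verified against brute-force oracles on 50 random
instances each.  Clustering cohorts are 10 + 10 cells.  All random numbers
come from seeded `numpy.random.default_rng` generators, so every synthetic
dataset is reproducible from (preset, seed).

## Known limitations

* The rheobase values match the reference parameterisation to ≈ 0.1 nS,
  not to the printed second decimal; see the integration-convention
  discussion above.
* The mEPSC detector is tuned for well-separated somatic events; bursts
  denser than the event window are split only when the trace dips below
  half-threshold, and severely overlapping events bias fitted charges.
* `charge_ratio_ri` assumes an ohmic driving-force correction with
  E_rev = 0; a shifted synaptic reversal would bias the ratio.
* The density map positions compartment mass at segment midpoints; very
  long compartments (≫ bin size) should be resampled before mapping.
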