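# Methods

This note documents the models, parameter choices, and numerical decisions
behind `dryclean`, and what the synthetic test bed does and does not show
about real recordings.

## Pipeline model

The pipeline treats a multichannel dry-EEG recording as a superposition of
(i) spatially smooth, temporally colored cortical background, (ii)
structured physiological artifacts with characteristic topographies and
time courses, (iii) spatially uncorrelated sensor noise, and (iv) sparse
single-channel high-amplitude jumps.  Each stage targets one of these:

* **Phase A** — zero-phase FIR band-pass 0.5–70 Hz plus a 48–52 Hz
  band-stop.  The kernels are windowed-sinc (Hamming) designs, transition
  width 0.5 Hz at the low edge (band-pass) and 1 Hz (band-stop), applied
  forward and backward via FFT convolution with reflection padding; the
  double pass squares the magnitude response (≥100 dB at 50 Hz) and
  guarantees exactly zero phase.  Channel hygiene is threshold-based:
  channels isoelectric (<0.5 μV) or high-amplitude (>100 μV) for more than
  70 % of samples are flagged; trials with any-sample excursions above
  150 μV on more than 40 % of channels are rejected.  The 100/150 μV
  defaults align the channel/trial scales with the jump-detection scale
  below; all are configurable because such limits are montage- and
  gain-dependent.
* **ICA stage** — channel means are removed, the data are whitened by SVD
  to a fixed 50 dimensions (comparability across recordings with different
  retained-channel counts; reduced with a warning if the data rank is
  lower), and an extended-Infomax unmixing is estimated.  The unmixing is
  fitted on an evenly decimated subsample of at most 4096 whitened samples:
  the mixing is time-invariant, estimation cost is linear in the sample
  count, and decimation preserves artifact waveforms in the feature
  statistics the algorithm uses.  Components are flipped so the largest
  mixing weight is positive, making the classifier's sign-sensitive
  features reproducible.
* **Component classifier** — a documented heuristic, *not* a trained
  classifier.  Features per component: fraction of topography power on
  frontal channels (y > 0.35 on the unit-sphere montage), left–right
  frontal asymmetry, band-power fractions (<5 Hz, >20 Hz), amplitude
  skewness, lag-1 autocorrelation, and the regularity of the high-z peak
  train (median inter-peak interval in 0.6–1.67 s with CV < 0.2 →
  cardiac/pulse).  Rules are applied in the order blink → eye movement →
  cardiac → myogenic; everything else is neural.  Spatially uncorrelated
  noise components typically fall into the myogenic class (broadband,
  weakly autocorrelated); for the cleaning objective this is acceptable —
  they are removed either way — but the labels must not be read as a
  physiological diagnosis.  All thresholds live on `ClassifierConfig`.
* **AP0** — per channel, an excursion beyond ±150 μV opens a period
  starting 200 ms before the first crossing (extended further back while
  the signal is already outside ±80 μV, a deterministic reading of the
  "at least 200 ms" labeling rule); the period ends at the first sample
  from which the signal stays within ±80 μV for 200 ms.  Periods closer
  than the 0.5 s taper are merged so taper zones never overlap.  Zeroing
  sets the period core to exactly 0 μV with multiplicative half-Hann fades
  of 0.25 s on each side.  Re-applying the same periods is a no-op (a
  period whose core is already identically zero is skipped), which makes
  the operation idempotent in practice — a smooth multiplicative taper
  cannot literally be a projection, so the guard supplies the idempotence
  that re-runs of a pipeline expect.  After spatial filtering the affected
  spans are replaced by spherical-spline estimates from all other channels
  (mesh-neighbor-only interpolation is available as an option).
* **SPHARA** — the montage is triangulated by 2D Delaunay on an
  azimuthal-equidistant projection about the cap's mean direction (open
  caps have disk topology; convex-hull triangulation would add spurious
  bottom faces).  Near-planar layouts fall back to their principal plane.
  Linear FEM yields the cotangent stiffness and consistent mass matrices
  with natural (Neumann) boundary conditions, so constants stay in the
  stiffness null space; obtuse cotangents are kept signed.  The
  generalized eigenproblem is solved densely (montages are ≤256 channels);
  eigenvectors come out mass-orthonormal, are stably sorted, and
  sign-fixed.  The Butterworth cutoff is the natural frequency √λ of the
  K-th basis function, K being the smallest leading subset holding 95 % of
  the recording's power (per recording; the composition of the power
  criterion with the Butterworth filter is the simplest one available, and
  a hard-truncation mode is provided for sensitivity checks).  If the
  power criterion lands on the constant function, the first positive
  natural frequency is used.
* **Phase C** — common-average re-reference, spherical-spline restoration
  of removed channels, segmentation into 7 s task epochs (L/R/T/F).
  Spherical splines follow Perrin (1989) with stiffness m = 4, 50 Legendre
  terms, and ridge regularization 1e-5 (the de-facto standard value; the
  system matrix is ill-conditioned enough that the regularizer visibly
  shapes the smoothing, so the conventional value is used rather than a
  smaller one).

Evaluation compares each chain to the Phase-A output over the continuous
recording, before Phase C; aggregation is channel → recording → grand
mean with equal weights.  `SNR` and `RMSD` are undefined for the reference
itself.  The mixed-model significance machinery often reported alongside
these metrics is deliberately out of scope; the per-cell means ± SD in the
exported tables are sufficient input for any off-the-shelf GLME tool.

## Synthetic test bed

`synthetic_eeg` emulates the statistics the pipeline assumes, on a
64-channel unit-sphere Fibonacci cap at 1024 Hz by default:

* background: the 8 lowest non-constant Laplace–Beltrami harmonics of the
  montage driven by AR(2) noise (double pole at 2 Hz; 1/f-like), plus a
  posterior-weighted 10 Hz alpha band (8–12 Hz filtered noise) projected
  onto the same harmonics; per-channel broadband SD 5 μV, alpha variance
  9 μV²;
* blinks: 15/min, 0.25–0.4 s hann² transients, ~150 μV at the frontal
  pole, Gaussian topography (σ = 0.35);
* eye movements: 6/min, step-like 0.5–1.5 s excursions, ±60 μV,
  left-minus-right frontal dipole;
* EMG: 8 bursts/min, 0.5–2 s of 20–70 Hz noise (15–40 μV RMS) on
  peripheral channel groups;
* cardiac/pulse: 70 bpm biphasic ~40 ms spikes with ±5 % period jitter,
  temporal/mastoid-weighted topography, 15 μV peak;
* sensor noise: white, 3 μV per channel, spatially uncorrelated;
* jumps: per-channel Poisson events, duration 0.4–2 s, amplitude
  200–800 μV with random sign, waveform = step with exponential return
  (τ = 0.3 s) and a small fast overshoot term, normalized so the onset
  peak equals the drawn amplitude; the event rate is set so the expected
  duty cycle equals `jump_fraction` (default 1.3 % of channel-time,
  matching the labeled share in dry-EEG recordings of this kind); a
  configurable fraction (default 0.2) co-occurs at half amplitude on one
  mesh neighbor.

The emitted matrix is bit-exactly the sum of the stored clean background
and per-class components (components are stored in float32 and summed in
float64, so conservation is exact), and all randomness descends from one
seed through named substreams.

What the generator does **not** model: volume conduction from cortical
sources, task-related (motor) activity, electrode drift, line-noise
harmonics, or realistic head geometry.  Passing tests therefore
demonstrate that each stage does what it claims *under its own model
assumptions* — smooth background, localized artifacts, uncorrelated noise
— not that the heuristic classifier matches trained artifact classifiers
on real data.

## Benchmark scale and the anti-smearing check

The shipped benchmark runs 11 recordings × 120 s at 256 Hz through all
five chains; this is the package's desk-scale rendering of a multi-subject
study and completes in about two minutes on one core.  On it, grand-average
SD decreases strictly along Ref → FPA → FPA+SPHARA → FPA+AP0+SPHARA and
SNR/RMSD increase strictly along FPA → FPA+SPHARA → FPA+AP0+SPHARA.  The
position of SPHARA-alone between Ref and FPA depends on the artifact mix
(the synthetic mix carries more ocular/jump power than uncorrelated noise),
so only its improvement over Ref is asserted.

The anti-smearing property — a single-channel jump contaminates its mesh
neighbors less when zeroed before the spatial filter — is checked two
ways.  Controlled: one injected jump per recording, ten seeded instances,
every instance must improve.  In-benchmark: at a 1.3 % duty cycle the
windows of different jumps (and of other >150 μV events the detector
legitimately picks up) frequently overlap on neighboring channels, so
per-jump error attribution is confounded; the benchmark check therefore
aggregates the neighbor error over *all* jump windows of a recording and
requires every recording to improve.  Zeroing also removes the genuine
background inside a period, which injects a small "hole" error into
neighbors after filtering — for jumps barely above threshold this hole can
rival the smearing it prevents, which is why the per-jump guarantee is
stated for the controlled setting.

## Numerical choices and degenerate inputs

* Eigen-solve: `scipy.linalg.eigh(S, M)` (dense, generalized); tiny
  negative eigenvalues are clipped to 0; degenerate eigenvalues keep the
  solver's stable order and only the sign is fixed, so comparisons across
  implementations must be done subspace-wise.
* ICA determinism: fixed seed to the Infomax initializer plus the sign
  convention gives bitwise-reproducible decompositions.
* Whitening rank: singular values below 1e-6 of the largest are treated
  as numerically zero (float32-quantized inputs carry a ~1e-7 relative
  noise floor).
* AP0 bounds: periods and tapers are clipped to the recording; a period
  that never stabilizes runs to the end of the recording.
* EDF export quantizes to 16 bits against per-channel symmetric physical
  ranges rounded up to the 2-decimal precision of the EDF header (the
  writer scales with the rounded values so a reader reconstructs exactly
  up to quantization); BrainVision export stores IEEE float32.
* Detection thresholds are evaluated on the Phase-A preprocessed signal —
  the representation the pipeline operates on.

## Known limitations

* The component classifier is a heuristic surrogate; its thresholds were
  chosen on the synthetic test bed and will need adjustment for real
  recordings (they are all exposed on `ClassifierConfig`).
* The automated AP0 detector implements the published labeling rules
  mechanically; manually labeled period files (TSV) can be supplied
  instead where curated labels exist.
* Natural-frequency Butterworth filtering assumes the mass matrix is well
  conditioned; extremely irregular montages may require the obtuse-cotangent
  clamping option when triangle quality is poor.
* Metrics are computed on continuous recordings; an epochs-based variant
  is available through segmentation but is not the default.
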