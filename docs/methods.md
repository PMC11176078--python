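# Methods

`swimstates` reimplements, as a tested pipeline over synthetic data, the
computational chain that turns wide-field video of a single larval zebrafish
into latent behavioral states and drug-effect scores, and the companion
calcium-imaging analysis that turns dorsal-raphe fluorescence into
2-component population trajectories.  This note records the models, the
defaults and why they were chosen, the numerical details, and what the
synthetic benchmarks do and do not demonstrate.

## Synthetic sessions

The generator (`swimstates.synthetic`) stands in for the raw recordings,
which are not publicly deposited.  A session is a sequence of swim bouts
drawn from three latent states — spontaneous scooting, rapid OMR scooting,
and a merged turning/escape state — sampled per bout from an epoch-specific
mixture (10 s stationary-grating "spontaneous" epochs alternate with 10 s
moving-grating "OMR" epochs).  Routine turns and C-turns are collapsed into
one `turn_escape` state with a bimodal peak-angle distribution because the
downstream embedding treats both as one turning/escape axis.

Per-state defaults (all configurable, none measured constants): spontaneous
scoots ~22 Hz beat, 15° peaks, 4 half-cycles, 1.5 s rests; OMR scoots
~32 Hz, 18°, 10 half-cycles, 0.6 s rests; turns/escapes ~28 Hz with a
35°/60° angle mixture and left/right asymmetry 0.8.  These were chosen once
to reproduce the qualitative geometry of the known swim-type repertoire.

Each bout is a damped tail oscillation: per-half-cycle peak angles carry an
exponential decay and a dominant-side scaling `(1 ± asymmetry)` so the
emitted peaks hit the target L/R balance; the lateral head displacement is
generated in antiphase at 0.003 mm/deg (≈1 px at 45°), since the pipeline
uses lateral head motion as the tail-cycle reference.  Forward displacement
follows the multiplicative law `distance = 0.004 · f · n · θ^0.4 · vigor`
(mm, Hz, half-cycles, degrees), with the drawn bout speed acting as a
relative vigor factor; this couples displacement to tail kinematics so the
distance-model validation is coherent end to end.  Heading rotates across
the bout by `±1.2 · asymmetry · mean peak angle`, giving turns large heading
changes and scoots small ones.  Tail points are placed on a parabola whose
tangent at 1 mm arc length equals the per-frame tail angle (tabulated
curvature-vs-angle inversion), so the quadratic-fit readout recovers the
generating angle almost exactly.

Conditions reweight the state mixtures and apply multiplicative shifts:
stress raises the turn/escape share during spontaneous epochs and lengthens
rests (×1.8), the psilocybin-like condition shifts spontaneous swimming
toward rapid scooting with shorter rests, and the drug+stress condition
partially restores the control mixture (rest shift ×1.25).

What the generator does **not** emulate: hydrodynamics, wall interactions
and thigmotaxis, pose-estimation noise and outliers, eye/nostril tracking
errors, inter-fish variability beyond the seed, and social behavior.
Passing tests therefore demonstrate correctness of the computations under
the stated statistical structure, not performance on real video.

## Tracking

Frames are 8-bit, nominally 83 μm/px at 290 Hz.  The background model is
the pixelwise mean of 100 equidistant frames (`floor(k·N/100)` — a
deterministic, endpoint-safe convention).  Coarse detection blurs the
difference image with σ = 250 μm (≈3 px; kernel truncated at 4σ) and takes
the darkest pixel, ties broken row-major.  A 144×144 px patch (12×12 mm) is
cropped, out-of-frame pixels filled with the mean background level, and
min–max rescaled to 0–255 (an all-constant patch maps to zeros).

The subpixel step follows the star-centroiding recipe with explicit
parameters: Gaussian blur σ = 1 px → invert → subtract the patch median →
zero everything below 20 % of the peak → intensity-weighted center of mass.
On the synthetic benchmark (Gaussian template σ = 4 px, peak-SNR 10,
uniform subpixel offsets, 500 frames) the mean absolute error is ≈10 μm
(0.12 px), within the ~25 μm design figure.  A windowed "recurrent" search
around the previous position is available as a speed optimization and is
tested to produce identical results for plausible frame-to-frame motion.

Tail angle: a quadratic `y = ax² + bx + c` is least-squares fitted to the
trunk point and six tail points in the body frame (origin at the trunk,
x along the nostril→trunk axis, y toward the fish's right).  The angle is
the arctangent of the tangent at **arc length** 1 mm from the tail base —
arc length rather than x-projection, because the two diverge at large bend
angles; the x-projection variant is one flag away (`arc_length=False`).
Sign convention: positive = tail toward the fish's right; the value is odd
under mirror reflection and invariant under rigid rotation.

## Kinematics

Bout segmentation thresholds are not prescribed anywhere and are set to
standard larval scales: speed smoothed with a 15 ms moving average, onset
4 mm/s, offset 2 mm/s (hysteresis), merge gap 50 ms, minimum duration
30 ms — all configurable.  The inter-bout interval is the time since the
previous bout's offset; the first bout's interval is missing and those rows
are dropped from feature vectors rather than imputed.  Epoch labels follow
the bout's onset time.

Tail half-cycles are delimited by alternating signed peaks of the lateral
head displacement (minimum prominence 5 μm); within each half-cycle window
the maximum |tail angle| and its sign give one cycle.  Per bout:
`n_motions` counts half-cycles; the reported tail frequency is the
half-cycle rate divided by two (full tail-beat convention); the L/R balance
is `|ΣR − ΣL| / (ΣR + ΣL)` over per-cycle peak angles (0 symmetric,
1 fully one-sided).

Central-region filtering keeps bouts whose onset lies within 30 mm of the
center for large (>50 mm) arenas and 10 mm for small ones; forward swims
additionally require |heading change| < 30°.  Session QC fails recordings
with fewer than 50 OMR-epoch bouts (6.7 swims/min over the 7.5 OMR minutes
of a default 15-min session).

The distance model `distance = k·f^a·n^b·θ^c` is fitted by L-BFGS-B on the
raw squared error (a log-domain option exists but is off by default, since
the validation target is the raw-distance fit), exponents bounded [0, 3],
`k` parameterized as `exp(log k)` to stay positive, initialized from the
log-linear least-squares solution.  Degenerate designs (any parameter
constant across bouts) are rejected as unidentifiable.  Angles are in
degrees throughout — the 0.4 power is unit-sensitive, so degrees are
declared canonical and recorded in all outputs.

## State embedding and statistics

Features per bout: tail frequency (Hz), mean peak angle^0.4 (deg^0.4),
number of tail motions, L/R balance, inter-bout interval (s).  Features are
z-scored with reference-dataset statistics and embedded with 2-component
FastICA.  Because ICA order and sign are indeterminate, the fitted axes are
canonicalized by loading correlations: IC1 is the component correlating
most strongly (and positively) with tail frequency, IC2 the other,
oriented positively with L/R balance — so rightward = rapid scooting,
upward = turning/escape.  The normalization and unmixing are frozen and
applied to new datasets without refitting (persisted as JSON).

The kernel-density two-sample test is 1-D (the per-axis distributions are
what is tested).  Statistic: the integrated squared difference of the two
Gaussian KDEs with per-sample Silverman plug-in bandwidths, evaluated in
closed form via the Gaussian convolution identity (no quadrature grid).
The p-value is an add-one-corrected permutation fraction; asymptotic nulls
are out of scope.  The p-value is invariant under common affine transforms
and symmetric in its arguments; its type-I rate matches the nominal level
(permutation p-values are multiples of 1/(n_perm+1), so calibration tests
use n_perm = 199 with rejection at p ≤ 0.05, where the achievable level is
exactly 0.05).

Drug-effect scores keep the printed sign conventions: the stimulatory
scores normalize a drug fish's spontaneous distance (or IC1) shift by the
control mean (or the control spont→OMR IC1 contrast); the anxiolytic scores
normalize the drug+stress shift by the stress-vs-control contrast, so full
reversal yields −1 and no effect 0.  A derived "anxiolytic magnitude"
(= −score) is exposed for plotting only.

## Neural analysis

ΔF/F is the raw 1 Hz trace **divided** by a rolling-percentile baseline
(bottom 30th percentile, centered 2-min window, truncated at the edges) —
the plain ratio without subtracting 1; `subtract_one=True` restores the
conventional form, in which case values are clipped at 0 before NMF.
Period-selective neurons are found by a two-sided independent t-test
(equal-variance by default; Welch by flag) on per-trial spontaneous-vs-OMR
mean ΔF/F, at p < 0.05; zero-variance traces are guarded as
non-significant.  Calibration caveat: the test's false-positive rate
matches the nominal level under independent noise, but shared slow baseline
drift correlates the per-trial period means and makes the test
*conservative* (observed ≈0.01 at drift amplitude 0.05); the test suite
checks both regimes.

Pooled trial-averaged activity (neurons × trial-period) is factorized with
rank-2 NMF (coordinate descent, deterministic NNDSVD initialization, fixed
seed).  Components are ordered so component 1 is the OMR-preferring
temporal profile (the swim axis), decided by the spont-vs-OMR contrast of
the temporal factors.  Trajectories are `V[i,t] = Σ_n W[n,i]·S[n,t]` per
fish or group, each component divided by its Euclidean norm over time —
making trajectories invariant to common rescaling of S and to neuron
ordering.  Anatomical masking and registration are out of scope; neuron
sets are taken as given.

## Problem sizes

Test-suite and analysis runs use deliberately desk-scale inputs chosen as
sufficient for the assertions they support: 240-s behavioral sessions
(~200 bouts) for end-to-end kinematics and embedding, 500-frame rendering
benchmarks, 1000 neurons × 20 trials for classifier calibration, and
150–200 replicate permutation tests for calibration of the kde test.
Sampling-error bounds in tests are 3 standard errors at those sizes.

## Known limitations

- The generator's bout waveform is a scaled sinusoid; real tail kinematics
  have richer envelopes, and real pose estimates carry outliers the
  pipeline's robustness is not tested against.
- The coarse detector assumes a single fish and a static background.
- The kde test is O(n²) per permutation; for samples ≫10³ subsample or
  reduce permutations.
- The distance-model exponents are only identifiable when parameters vary;
  sessions dominated by a single stereotyped bout type fit poorly.
- Drug-effect scores are ratios of group means; they inherit instability
  when the stress-vs-control contrast in the denominator is small.
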