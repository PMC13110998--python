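# Methods

This note documents the models, numerical choices, and limitations behind
`eitvent`: what the synthetic generator emulates, how breaths are
segmented and measured, and how the phase-level statistics are computed.

## Data model

A recording is a reconstructed EIT frame sequence: impedance in arbitrary
units (AU) on a pixel grid (default 32×32, the conventional raster for a
32-electrode belt), at a device frame rate carried explicitly in every
container (the generator defaults to 20 Hz; nothing downstream assumes a
rate). The canonical orientation is row 0 = ventral, column 0 = the
animal's right; files may declare any of the four row/column conventions
and are flipped to canonical on load. Lung regions are two pixel masks
separated by the vertical anatomical midline; all global signals and
centroids are computed on lung pixels only.

## Synthetic study generator

The generator emulates a six-animal, two-session crossover with seven
protocol phases — awake standing, sedated sternal recumbency, mechanical
ventilation head-high and head-low, spontaneous breathing with and
without an endotracheal tube, standing after recovery — recorded for
5 minutes standing and 2 minutes recumbent.

**Phase-level physiology.** Each of the eight summary variables (CoV_RL,
CoV_VD, ROI-R, TIV, MIV, EELI, tidal rate, TI) has a per-phase mean and
SD (package defaults tabulate a healthy-alpaca peri-anaesthetic profile,
e.g. tidal rate 34.2 ± 12 breaths/min standing pre-sedation falling to
12–16.5/min in the sedated and ventilated phases). A draw for animal *i*,
session *s*, phase *p* is
`mean_p + sd_p·(√f·z_i + √(1−f)·z_isp)` with `f = between_animal_var_frac`
(default 0.5): the animal term is shared across phases and sessions, so
the drawn tables have exactly the random-intercept covariance structure
the mixed model assumes. The tabulated SDs mix between-animal and
within-animal variance without stating the split, so the fraction is an
explicit parameter rather than a guess. Draws are truncated to
physiologically admissible ranges; in particular tidal rate is truncated
to [6, 60]/min because the ventilation protocol itself bounds ventilator
rates (10–18/min) and a slower rate cannot yield an analysable 2-minute
window. MIV is drawn at phase level only for the statistical simulations;
in frame synthesis MIV emerges as tidal rate × TIV.

**Spatial model.** The ventilation distribution of a recording is a
non-negative weight map summing to 1 over lung pixels: uniform per lung,
scaled to the target right/left split, with linear tilts along each axis
solved (bounded least squares) so the weighted centroid hits the target
CoV values. The ROI split is exact by construction; the centroids are
exact to solver precision. Because the right-lung mass fraction pins most
of the lateral centroid, an extreme ROI draw combined with a conflicting
CoV_RL draw can be jointly infeasible on a fixed lung geometry; the study
generator then takes the nearest feasible map. Ground truth is always the
*achieved* map centroid, never the requested target, so recovery checks
remain exact.

**Temporal model.** Breaths are raised-cosine pulses: a half-cosine rise
from onset over TI seconds to the breath amplitude (= TIV), then a
half-cosine decay over TE; successive breaths are contiguous (TE runs to
the next onset), giving a clean trough/peak alternation. Per-breath
amplitude and duration jitter use a 5% coefficient of variation. The
per-pixel signal is `baseline(p)·b(t) + weight(p)·g(t)`: the baseline
distributes EELI uniformly over lung pixels and interpolates per-breath
EELI levels piecewise-linearly.

**Artefacts** are additive and individually switchable: linear baseline
drift (AU/s), a cardiac-frequency sinusoid (default 1.3 Hz ≈ 80
beats/min), and per-breath motion spikes (Gaussian bumps, σ = 0.15 s,
centred on the affected breath's peak). The "mild" default
(drift 0.002 AU/s, cardiac 0.05 AU, spike probability 0.03, magnitude
2 AU) produces occasional genuinely unanalysable phases — the synthetic
analogue of recordings dropped from a live study.

**What the generator does not emulate:** reconstruction physics and
electrode artefacts, posture-dependent lung geometry (masks are fixed
ellipses shared by all animals), within-breath shape variability beyond
the raised cosine, correlated artefacts (coughing trains, belt slippage),
or non-Gaussian physiology. Passing recovery tests therefore demonstrates
the pipeline's correctness on signals with known structure, not its
robustness to every failure mode of real recordings.

## Breath analysis

The global signal is the per-frame sum over lung pixels. Extrema are
detected on a centred moving average and then *refined to exact raw-signal
extrema*, so reported boundaries are raw discrete extrema (on noise-free
signals they equal a brute-force extrema scan exactly; the test suite
asserts this equality on randomized clean signals).

Numerical choices, in order of application:

- **Smoothing window 0.75 s** (config-exposed). The window approximates
  one cardiac period, attenuating oscillation at ≥ 1.2 Hz by ≈ 90% while
  breath peaks survive; a much shorter window (e.g. 0.2 s) leaves cardiac
  ripple nearly untouched and fragments segmentation. Near the signal
  edges the window shrinks symmetrically (half-width `min(h, i, n−1−i)`)
  so the smoothed series follows the first and last breath instead of
  flattening there.
- **Prominence floor.** First pass: 10% of a robust signal range
  (2.5–97.5 percentile) — immune to ripple-dominated candidate medians.
  The floor is then re-estimated as 10% of the median detected breath
  amplitude and extrema are re-detected. Peaks and troughs are forced to
  alternate (the more extreme of two same-type neighbours survives).
- **Refinement radius** `min(window/2, 0.3 × median trough spacing)`:
  wide enough to cover the smoothing shift, never wide enough to reach a
  neighbouring breath's extremum.
- **Tie-breaks on flat runs.** A flat peak reports the first index of the
  maximal run. A flat trough is split: end-expiration takes the first
  index, the next onset the last — an end-expiratory pause belongs to
  neither breath. This keeps TI and tidal-rate definitions coherent when
  breathing pauses occur.
- **Edge breaths.** A trough plateau touching the recording boundary is
  not an interior extremum, so up to one partial breath is discarded at
  each edge.

**Artefact flags** (all thresholds config-exposed; the field's practice
of hand-selecting "artefact-free" breaths is replaced by an explicit
rule): a breath is flagged with reason
(a) `amplitude` when |TIV − rolling-median TIV| > max(k·MAD, 0.25·median
TIV) with k = 4, where the MAD is the recording-wide median of those
deviations (a windowed MAD breaks down — masking — when two spikes share
a window) and the rolling median (7 breaths) falls back to the global
median in its truncated edge windows;
(b) `baseline` when the end-expiratory level shifts by more than
0.5·median TIV across the breath;
(c) `duration` outside [0.5 s, 30 s].
The amplitude floor of 0.25·median TIV exists because with realistic ~5%
breath-to-breath variability a bare 4·MAD ≈ 2.7σ rule would flag ~0.7% of
clean breaths by chance. Lowering k, the floor, or (b)'s multiplier never
unflags a breath (tested as a property).

**Run selection** takes the earliest run of ≥ 6 consecutive unflagged
breaths, truncated to 10 — deterministic and auditable; which 6–10
breaths a human analyst would pick is otherwise unspecified. A phase
without such a run raises a typed error and is reported as unanalysable;
it is never imputed.

## Ventilation metrics

The functional image of a breath is the per-pixel impedance change from
onset to end-inspiration; negative pixels (out-of-phase local impedance
change) are clamped to zero for centroid/ROI purposes and counted. CoV is
the impedance-weighted centroid over lung pixels with the percentage
coordinate interpolated linearly between the extreme lung-pixel centres
(0% = right / ventral lung extreme); grids whose lung region spans a
single row or column are rejected. TIV is reported as the non-negative
magnitude of the onset→end-inspiration change (the definition phrased as
end-minus-start would be negative under the sign convention in which
inspiration raises impedance); a non-positive TIV marks a mis-segmented
breath and is an error, not a value. TI is a duration. Tidal rate is
60 / mean onset-to-onset duration over the selected run (robust to run
truncation and consistent with per-breath granularity), and
MIV = tidal rate × mean TIV of the run by definition — the identity is
asserted in tests to guard aggregation-order bugs, since a
product-of-phase-means is *not* the mean of per-run MIV. TIV/EELI/MIV
stay in AU throughout; no volume calibration is attempted (none is
available without simultaneous spirometry).

## Phase statistics

For each variable: `y = phase + (1 | animal)`, REML, both sessions pooled
as repeated rows per animal (an optional fixed session term is
config-exposed and off by default). The design matrix uses cell-means
coding, so coefficients are the estimated marginal means per phase.

- **REML fit.** The criterion is profiled over the variance ratio
  θ = σ²_subject/σ²_resid, optimised by bounded scalar minimisation
  (tolerance 1e-10) started from a method-of-moments estimate, with
  per-group Woodbury identities so no n×n solve occurs during
  optimisation. θ below 1e-6 is flagged a singular (boundary) fit —
  reported, not fatal; its F-test falls back to the residual-df
  denominator.
- **Satterthwaite df** by the delta method: for a contrast ℓ,
  df = 2f²/(g′Ag) with f = ℓ′Cℓ, g = ∂f/∂(σ²_subject, σ²_resid), and A
  twice the inverse observed Hessian of the REML deviance. Both g and the
  Hessian use exact closed forms (the two-component model admits them),
  not finite differences. The overall phase F decomposes the contrast
  covariance along its eigenvectors, assigns each 1-df component its
  Satterthwaite df, and pools them. On balanced complete data this
  reproduces the classical repeated-measures ANOVA F and integer df to
  ~1e-8 relative error; on unbalanced data it matches lmerTest/emmeans
  (checked in the suite against R).
- **Contrasts.** All 21 phase pairs on the EMMs, each with its own
  Satterthwaite df; multiplicity adjustment is Tukey's studentised range
  (the conventional family for all-pairwise EMM comparisons; the
  adjustment method is logged in the output).
- **Diagnostics** are plot-first, matching how such models are checked in
  practice: QQ and residual-vs-fitted data (conditional residuals, BLUPs
  removed) exported as CSV, with a Shapiro–Wilk p-value as a coarse
  numeric screen at 0.05.
- **ICC.** Repeatability across the two sessions is ICC(2,1) — two-way
  random effects, absolute agreement, single rater — computed from the
  two-way ANOVA mean squares on the animal × phase pairs of one variable,
  with the standard F-based 95% CI. Pairs missing a session are dropped
  and counted. Computing the ICC per variable on animal×phase pairs
  (rather than per phase, which would leave 6 pairs) is a documented
  choice; repeatability "across both measurements" does not itself fix
  the pairing unit.
- Significance threshold α = 0.05 throughout.

## Missing data

Dropped recordings are absent rows everywhere: the likelihood handles the
imbalance in the LMM, ICC drops incomplete pairs, and nothing is imputed.
The generator can emulate the canonical dropout pattern (one animal
missing its last four phases in one session — assigned to animal 4,
session 2; one missing the final standing phase — animal 6, session 1)
to exercise these paths; which session the four-phase dropout occurred in
is not identifiable from the design, so the assignment is a convention.

## Problem sizes and determinism

Validation runs use the study at its native size (84 recordings; 5-minute
standing and 2-minute recumbent windows at 20 Hz), 100 randomized signals
for the segmentation oracle, 1000 null simulations for type-I calibration
of the phase F-test, and 100 replicates for the qualitative-findings
recovery rate — sizes at which every Monte-Carlo band in the test suite
is comfortably resolved. All randomness flows from explicit seeds through
`numpy` generators; per-sequence seeds derive from the study seed plus
the sequence identity, so any subset of a study regenerates bit-identical
frames and reruns of the CLI produce byte-identical metric tables.

## Known limitations

- The elliptical lung masks and midline are shared across animals and
  phases; real studies segment per-animal geometry from CT.
- The artefact taxonomy (drift, cardiac sinusoid, isolated spikes) is
  deliberately minimal; the flag rules are defaults to be tuned on real
  recordings, not claims about any particular study's practice.
- The LMM supports a single random intercept (the design's only random
  effect); random slopes or session-nested intercepts are out of scope.
- Kenward–Roger df are not implemented; Satterthwaite is the only
  small-sample approximation offered.
- CoV is computed on lung-masked pixels; devices that compute it on the
  full image will differ slightly when signal leaks outside the masks.
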