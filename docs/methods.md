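# Methods

`deptrack` reconstructs single-cell trajectories from frequency-modulated
dielectrophoresis (DEP) time-lapse sequences and estimates each cell's
crossover frequency f_co — the applied-field frequency at which the real
part of the Clausius–Mossotti (CM) factor, and with it the direction of
DEP-driven motion, changes sign.  Everything is validated end to end on a
bundled synthetic-experiment generator with known ground truth.  This note
records the models, the defaults and why they were chosen, and what the
synthetic validation does and does not show.

## Dielectric model

A cell is a single-shell sphere: conductive cytoplasm (radius `r_cell`,
relative permittivity `eps_cyto`, conductivity `sigma_cyto`) wrapped in a
thin insulating membrane (`membrane_thickness`, `eps_mem`, `sigma_mem`),
suspended in a medium (`eps_medium`, `sigma_medium`).  The shell is
collapsed to an equivalent homogeneous complex permittivity

    e*_p = e*_mem * (a^3 + 2K) / (a^3 - K),
    K = (e*_cyto - e*_mem) / (e*_cyto + 2 e*_mem),
    a = r_cell / (r_cell - d_mem),   e* = e - j*sigma/omega,

and Re[CM] = Re[(e*_p - e*_m)/(e*_p + 2 e*_m)] is bounded in [-0.5, 1] for
any passive parameter set.  Defaults approximate a 19-µm MCF-7 cell in a
~60 µS/cm sucrose DEP buffer (`eps_mem = 7`, 7-nm membrane → specific
membrane capacitance ≈ 8.9 mF/m², `eps_cyto = 60`, `sigma_cyto = 0.5` S/m,
`eps_medium = 78`, `sigma_medium = 6e-3` S/m, `eta = 1` mPa·s); the model's
crossover is ≈ 15.8 kHz, inside the 1–41 kHz sweep window of the default
protocol.

## Stimulation protocol

The default schedule spans 1,320 s at 10 frames/s (13,200 frames), in three
steps:

1. 1-kHz nDEP trap hold (25 s) → sweep 1→41 kHz at +800 Hz/s (50 s) →
   41-kHz pDEP trap hold (25 s) → sweep 41→1 kHz at −800 Hz/s (50 s);
2. twelve trap/test pairs (25-s trap + 60-s static test): 1-kHz traps
   followed by 20, 30, 40, 50, 60, 70 kHz tests interleaved with 41-kHz
   traps followed by 1.0, 1.5, 2.0, 2.5, 3.0, 3.5 kHz tests;
3. a repeat of step 1.

Segment boundaries are half-open (a boundary instant belongs to the later
segment).  The hold durations are the one free choice (they are not fixed by
the sweep rate or the ladder); 25/60 s make the three steps total exactly
1,320 s and give every trap ample settling time.

## Synthetic experiment generator

**Chip and field.** The electrode is a regular grid of circular holes
(radius 20 px, pitch 96 px) centred in a circular field of view inscribed
in the image.  The field-gradient magnitude |∇E_rms²| is modelled as a sum
of Gaussian bumps on the hole rims; the direction field points toward the
nearest rim.  The bundled experiments use `sigma_bump = hole_radius`
(rather than the `hole_radius/4` function default) for two reasons: the
gradient then stays finite at the hole centre, giving the nDEP trap a
point-like attractor instead of a flat plateau, and a wide annulus of
near-constant gradient (coefficient of variation ≤ 10%) exists away from
the rim for velocity measurements.  The 96-px pitch keeps neighbouring rim
bumps decoupled, so the gradient seen by a transiting cell does not depend
on its transit angle.

**Kinematics.** In the overdamped Stokes regime the DEP drift velocity is
proportional to Re[CM]·r²·∇E_rms².  The generator replaces Re[CM](f) by a
smooth odd polarity factor in log-frequency,

    S(f) = tanh( ln(f / f_co) / (2 * 0.4) ),

and integrates  v = mobility_gain · S(f(t)) · r_cell² · grad(p) ·
direction(p) + jitter  per frame.  The 0.4 ln-unit width matches the slope
of the single-shell Re[CM] zero crossing, which reaches roughly two thirds
of its low-frequency plateau about one octave below f_co; a transition
narrow in *linear* frequency would turn the step-2 mobility samples into
pure sign bits and make the sigmoidal mobility fit degenerate, which is
neither what the dielectric model predicts nor what the velocity method
assumes.  S changes sign exactly at f_co, so the observable the pipeline
estimates — the motion reversal — is preserved regardless of the width.

Radial steps never overshoot the current attractor.  The pDEP trap point
sits `rim_offset = 3` px inside the rim line: a finite-size cell resting
against the hole wall keeps its centroid inside the hole, so nDEP
departures always start inward (without the offset, frame-to-frame jitter
around the exact rim lets ~half the cells slip outside at every polarity
reversal and drift off to the inter-hole region).  Cells resting on an
attractor are in mechanical contact with the substrate; their Brownian
jitter is damped to 10% (`trapped_jitter_factor`) and restored the moment
the polarity flips.  Free-cell jitter defaults to the Stokes–Einstein value
for a 9.5-µm sphere at the chip's ≈1.07 µm/px scale and 10 fps:
σ ≈ 0.09 px per axis per frame.  `mobility_gain = 0.17` px·s⁻¹ per
(px²·gradient unit) gives peak drift speeds of ≈5–8 µm/s for 5–7-px cells,
in the range of reported DEP velocities.  One random generator per cell,
seeded by `(seed, cell_id)`, makes every trajectory independent of how many
cells are simulated.

**Rendering and corruption.** Frames are 8-bit grayscale: flat electrode
background, darker hole interiors and rim annuli, radially shaded bright
cell discs with a 1-px anti-aliased edge, optional circular vignette, and
additive Gaussian noise (σ = 3 grey levels) seeded per frame.  Detection
streams are corrupted by Bernoulli dropout, Gaussian centroid jitter and
Poisson false positives placed uniformly in the FoV disk.

## Pipeline components

**FoV mask.** Otsu binarization (the threshold method is configurable; the
original procedure does not state one) → hole filling → morphological
opening with an exact-disk structuring element (radius 50 px, computed via
the Euclidean distance transform) → keep the largest connected component →
blank the top and bottom 10 rows.

**Detection.** Any callable producing centroid–radius states can be
plugged in, including a CSV stream from an external neural detector; the
bundled reference backend is multiscale Laplacian-of-Gaussian blob
detection (threshold 0.2 on the scale-normalised response, calibrated once
on rendered frames in both trap states).  Radii derive from boxes as
r = (w+h)/4.  Detection scoring uses optimal one-to-one assignment within
a centroid-distance tolerance — the faithful reading of TP as the
cardinality of the prediction/ground-truth correspondence — with
precision, recall and F-measure reported to five decimals.

**Rapid-motion events.** Before identities exist, frame-wise mean
displacement is computed over mutual-nearest-neighbour pairs (distance cap
4× median detection radius).  Rapid frames are strict local maxima within
±5 frames that reach λ = 0.5 of the global maximum; tracking treats ±10
frames around them (the halo) as the rapid regime.  λ, window and halo are
exposed; none is prescribed by the original description.  Note that on the
synthetic chip only departures from the rim (where the gradient peaks)
produce a displacement maximum at the switch frame itself; departures from
the hole centre accelerate through the rising gradient and peak tens of
frames later — an inherent property of gradient-proportional kinematics.

**Tracking.** One track per first-frame detection (later entrants are
never assigned identities).  Association is nearest-neighbour within a
regime-dependent ROI (3 track radii stable / 6 rapid), gated by a maximum
displacement (same radii) and a circle-IoU threshold (0.2 stable / 0.05
rapid); the gates scale with cell size and satisfy the
relaxed-during-rapid ordering.  Only the distance minimiser is tested
against the gates (argmin-first; `best_feasible` switches to the
alternative semantics).  On failure, up to 10 subsequent frames are
scanned for any detection inside the ROI; a recovered gap is filled by
linear interpolation in x, y and r.  Tracks failing both association and
recovery terminate at their last known state.  Post hoc, a track is
out-of-range if shorter than the sequence or if any centroid leaves the
mask, and track pairs overlapping (circle IoU > 0.5) for ≥3 consecutive
frames are re-examined: tails are swapped when that reduces the
displacement across the event boundary, otherwise the pair is flagged
merged.

**Evaluation.** MOTA = 1 − (FN+FP+IDsw)/ΣG_t with greedy per-frame
centroid matching (tolerance = the ground-truth cell's radius),
ground-truth states outside the mask excluded from G_t, and CLEAR-style
identity switches (one per ground-truth cell whenever its matched track id
changes between matched frames).  The retention curve is the fraction of
initial tracks whose last *detected* (not interpolated) frame is ≥ t.

## Crossover-frequency estimation

**Velocity method (static tests).** A measurement annulus with gradient
coefficient of variation ≤ 10% is selected inside the hole, ending 4 px
short of the rim to exclude the pDEP arrival zone.  For each test
frequency, the first contiguous in-ring run spanning ≥ half the ring width
yields a signed radial velocity — by default the least-squares slope of
radial distance vs time over the run (with the first/last two frames of
long runs trimmed), which equals travel-distance-over-transit-time for
uniform motion but is insensitive to the ±1-frame timing noise of the
boundary crossings; the literal endpoint estimator is available as
`estimator="endpoints"`.  The radius-normalised mobilities v/r² across
frequencies are fitted with a four-parameter logistic **against
log-frequency** (the ladder spans almost two decades and Re[CM] is
sigmoidal on a log axis), with plateaus loosely bounded by the observed
extremes: the outermost test frequencies lie far from any plausible
crossover, so the extreme samples are near-saturated, and without the
anchor the 4PL depth/slope trade-off is ill-posed whenever one branch is
sampled over a narrow band.  f_co is the fitted root
x0 − ln((L2−L1)/(−L1) − 1)/k; fits with single-sign data, no root, or a
root outside the sampled hull are invalid.  Eq. (11)-style absolute
calibration (Re[CM] = 3ηv/(r²·ε_medium·∇E_rms²)) is available when SI
units are known; on the synthetic chip the proportionality constant is
absorbed by the fit.

**Intensity method (sweeps).** Per sweep, the trapped site is the robust
mean of the cell's positions over the last 50 frames of the preceding trap
hold (iterative Mahalanobis trimming at the chi-square(2) 0.975 quantile).
The mean intensity over a probe disc of the cell's own radius is monitored;
f_co is the applied frequency at the first sweep frame whose deviation from
the baseline mean exceeds 3 baseline standard deviations for ≥3 consecutive
frames.  The probe matches the cell footprint because a larger disc
conserves the cell's integrated brightness under small displacements and
only responds once the cell clears the probe edge, delaying the trigger by
several kHz.  The persistence requirement exists because a single-frame
3-sigma excursion recurs by chance about every 370 frames of Gaussian
noise, whereas a genuine escape deviates for hundreds of consecutive
frames.  Per-cell estimates are the median over the four sweeps (two up,
two down), which cancels the small, opposite-signed escape-lag biases of
the two sweep directions and is robust to one spurious trigger.  Cells with
no valid trigger on any sweep are reported invalid.

## Numerical choices and edge cases

- Coordinates: origin top-left, x = column, y = row, 0-based, pixel
  centres at integers, everywhere.
- Circle IoU uses the exact lens-area formula with clipped arccos
  arguments; disjoint and contained configurations short-circuit.
- Ties (equidistant candidates, equidistant rims) break to the lower
  index.
- The nDEP no-overshoot clamp stops 0.01 px short of the hole centre,
  where the radial direction is undefined.
- Degenerate inputs raise or flag rather than guess: all-flat frames
  (mask), zero-variance baselines (intensity), singular covariance
  (trapped site), empty first frames (tracking), zero denominators
  (metrics, force balance).
- Reported metric ratios are rounded to five decimals; everything else is
  kept at full precision.

## Problem sizes used in validation

The bundled validation runs at desk scale: tracking benchmarks use 100
cells over 500 frames (two polarity switches), crossover-frequency
recovery uses 50 cells through the full 13,200-frame protocol with
rendering confined to the sweep windows, and the Monte-Carlo IoU oracle
uses 100 circle pairs at 10⁷ samples each.  Kinematics at full protocol
length are cheap (seconds); rendering dominates the intensity method.

## What the synthetic validation shows — and does not

Passing tests show that the pipeline's logic is correct against a
generator whose physics is known exactly: identities are preserved through
polarity reversals, dropouts are bridged, the conservation identity holds,
and both f_co estimators recover the ground truth to a few percent and
agree with each other.  The generator does not emulate several features of
real chips: cell–cell interactions and occlusion, dielectrophoretic
heterogeneity beyond f_co (all cells share one mobility law), uneven
illumination and electrode texture beyond the simple rendered pattern,
electro-hydrodynamic effects (Joule heating, electroosmosis, wall drag),
or detector failure modes of a learned model.  Accuracy numbers obtained
here therefore bound the algorithmic error, not the end-to-end error on
real microscopy data.

## Known limitations

- The first-frame identity rule means cells entering later are never
  tracked; dense late arrivals would appear only as association clutter.
- The overlap-based identity correction resolves pairwise events with a
  two-permutation test; three-way merges are flagged but not untangled.
- The intensity method assumes the trapped cell is stationary during the
  baseline window; slowly drifting traps would inflate the baseline sigma
  and delay triggers.
- The velocity method needs at least one transit on each side of f_co;
  cells whose f_co lies outside (or at the very edge of) the tested ladder
  are reported invalid rather than extrapolated.
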