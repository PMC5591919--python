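# Methods

This note documents the models, estimators, parameter choices and known
limitations of `cardiokin`. Every number quoted here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## Synthetic beating model

A syncytium's contraction is modelled as a train of raised-cosine
displacement pulses. With contraction phase τ_c and relaxation phase τ_r,

    s(u) = (1 − cos(π u / τ_c)) / 2,            0 ≤ u ≤ τ_c,
    s(u) = (1 + cos(π (u − τ_c) / τ_r)) / 2,    τ_c < u ≤ τ_c + τ_r,

else 0. The pulse was chosen for one property: its derivatives are
closed-form, so a marker of amplitude A has exact peak metrics
D = A, V = A·π/(2τ_c), Acc = A·π²/(2τ_c²) — the ground truth every
estimator is scored against. The price is a second derivative that jumps at
the pulse onset; the acceleration estimator below is designed around that.

Markers move radially toward the frame center — the simplest displacement
field of a sheet contracting about a fixed point — with amplitude growing
linearly with distance from the center; the farthest grid marker carries the
full per-syncytium amplitude that the ground-truth record describes.

Defaults (all configurable; units and rationale):

| parameter | default | why |
|---|---|---|
| beat rate f_beat | 1.0 Hz | spontaneous beating of neonatal murine syncytia is ~1–3 Hz; 1 Hz keeps even the slowest arm's pulse (τ stretched 15%) inside one period |
| τ_c / τ_r | 0.30 / 0.45 s | upstroke shorter than relaxation, ~0.75 s active phase |
| amplitude A0 | 10 px | typical marker excursion at the field-of-view edge |
| interval jitter CV | 0.10 | physiological rate variability; intervals are clamped below at τ_c+τ_r, truncating the jitter distribution rather than letting pulses overlap |
| positional noise σ | 0.1 px | emulates sub-pixel tracker jitter |
| sampling rate | 25 Hz | ordinary video frame rate; acquisition duration 20 s |
| between-syncytium CV | 0.20 | lognormal multiplicative variability of amplitude across syncytia |

Per-arm effects are multiplicative on amplitude and on both phase durations
(ISO: ×1.10 amplitude, ×0.80 τ; EMF: ×0.93, ×1.10; ISO+EMF: ×0.82, ×1.15).
τ-shortening under β-adrenergic stimulation is the mechanism that makes the
acceleration contrast significant while the amplitude contrast stays
sub-threshold at n = 20 — the qualitative signature the reproduction run
checks. The between-syncytium amplitude factor is drawn once per syncytium
and shared across its five acquisitions, so averaging the 27–39 min window
does not erode the n = 20 unit-level variance.

What the generator deliberately does not emulate: calcium dynamics, action
potentials, non-radial strain fields, illumination drift, or rate effects of
the treatments (rate multipliers exist but default to 1). Passing tests on
this generator therefore demonstrate correctness of the measurement chain,
not biological fidelity of any particular effect size.

## Tracking

A 5 × 6 orthogonal grid seeds the markers on frame 0. Each marker is tracked
by normalized cross-correlation of a static frame-0 template (radius 8 px)
over a search window (radius 10 px/frame) centered on the previous position;
the integer peak is refined by 3-point parabolic interpolation per axis,
clamped to ±0.5 px. The template is never updated: 20 s recordings under
constant illumination gain nothing from updating, and a static template
cannot accumulate drift. Correlation peaks below 0.2 mark a frame "lost";
the last position is held so series stay uniformly sampled, and a trajectory
with >20% lost frames is invalid (a video with >50% invalid markers fails).

Because the template lives on the integer pixel grid, correlation measures
motion relative to frame 0; reported positions are anchored at the caller's
sub-pixel initial position plus that motion. Measured accuracy on rendered
stacks: 0.002 px RMS noise-free, ~0.14 px at peak SNR ≈ 10.

## Kinematics

Displacement is the Euclidean distance from the frame-0 position (policy
`"baseline"` uses a 10th-percentile rest position for drifting records). A
Savitzky–Golay filter (window 0.2 s forced to an odd sample count, cubic)
provides the smoothed signal and its first two analytic derivatives; edge
samples use the one-sided fits of the terminal windows.

Beats are peaks of the smoothed displacement with topographic prominence
above max(6·σ̂, 5% of signal range), where σ̂ is a MAD-based noise scale from
first differences of the *raw* displacement, and separation ≥ 0.25 s. The
6× multiplier is calibrated on noise-only records (0.5% false-positive rate
over 200 seeds); 5%-of-range suppresses the filter's own ringing on
noise-free signals. Onset and end are the flanking local minima, advanced
across rest plateaus (samples within 2% of the rise) so segments hug the
actual contraction; partial beats touching a record edge are discarded.

Per beat, over onset→peak only: D = smoothed peak minus onset; V = max
Savitzky–Golay velocity. Acceleration is different. Its true maximum sits at
the onset, where the second derivative is discontinuous; any centered
smoother whose window straddles the onset averages in the rest phase and
attenuates the peak by 20–50% (measured). Acc therefore comes from a
separate polynomial refit restricted to the detected contraction phase:

- fit degree min(5, n−2) to the raw samples in [onset, peak] — the odd top
  degree matters because the upstroke is antisymmetric about its midpoint,
  and an even cap leaves +20–40% curvature bias;
- fit the *signed* projection of the displacement onto the marker's dominant
  motion direction, not the magnitude — 2D noise rectified by the magnitude
  forms a convex floor near onset that biased fitted curvature by ≈ +15%;
- maximize the analytic second derivative from half a sample inside the fit
  window (the extreme edge extrapolates against the rest phase).

Measured recovery: noise-free 100 Hz beats — D −0.9%, V −1.3%, Acc −3.8%;
at study defaults (25 Hz, noise, jitter, 50 syncytia) median relative errors
≈ 2%, 1%, 7%. The reported D stays the non-negative magnitude; the
projection is internal to the curvature fit.

Aggregation is unweighted at every level (beats → marker → video →
syncytium); markers with no detected beats are excluded from a video's mean,
and the syncytium (n = 20 per arm) is the experimental unit for statistics.

## Statistics

Textbook fixed-effects one-way ANOVA (p from the F distribution;
cross-checked against `scipy.stats.f_oneway` and a permutation null in
tests), followed by Fisher LSD: all pairwise contrasts with standard error
from pooled MS_within and *no* multiplicity adjustment — that is the
procedure's definition, and reports flag it rather than silently
"improving" it. Significance is CI-exclusion of zero; the unadjusted p is
also reported. Measured calibration: null rejection rate 0.050 ± binomial
error over 2000 replicates; two-group LSD decisions identical to the
pooled-variance t test; 95% CI coverage within [0.94, 0.96].

The reproduction harness votes per contrast over independently seeded
studies (default 20) and passes a metric when every expected contrast
matches in the majority of seeds — single-seed verdicts on borderline
contrasts (the ISO amplitude effect is deliberately sub-threshold at n = 20)
are unstable by design, which is why the vote exists.

## Field model

The elemental field is the exact complete-elliptic-integral solution for a
circular loop; a straight-segment Biot–Savart quadrature of the same loop is
kept as an independent validation route (they agree to <0.1%, and doubling
quadrature segments moves the result <1e-6 relative). A solenoid
superposes its turns at midpoints of equal winding segments, which converges
quadratically to the continuous closed form (on-axis agreement 0.1%).

The rig is two identical coaxial solenoids in series. Their true geometry is
not part of this package's sources, so the shipped default is a **calibrated
surrogate**: R = 5 cm, L = 10 cm, 4 cm face gap, and a turn count (1279)
solved once so the printed 319 mA peak current yields ≈2.83 mT at the
center — the field consistent with an energy density u = B²/2μ0 ≈ 3.18 J/m³.
Derived dosimetry at defaults: center B_z 2.829 mT, central-region
homogeneity ~2% (transverse components <0.1% of B_z), u = 3.183 J/m³, and
for the 1.36 ms current ramp an induced azimuthal field E = (r/2)·dB/dt =
18.2 mV/m at the 17.5 mm dish edge (uniform-field Faraday approximation for
an axisymmetric dish). The trapezoidal pulse assumes a fall equal to the
printed rise and a plateau filling half the 75 Hz period; both are
configurable and neither affects the peak-field dosimetry.

## Fluorescence

Synthetic images place non-overlapping elliptical cells with a mild dome
profile on a noisy background; segmentation is Otsu's global threshold plus
connected components and an area filter (a percentile threshold is available
for images that break Otsu's bimodality assumption). Quantification is the
per-cell *mean* intensity on the 0–255 display scale (not integrated
intensity), normalized to the control mean as fold change with a t-based 95%
CI; the four-arm fold values feed the same ANOVA/LSD machinery. Measured:
segmentation recovers the exact cell count on default-contrast images and
per-cell means within 2% of ground truth.

## Numerical and edge-case policy

Degenerate beat segments (onset = peak) yield zero-valued records with a
warning; empty videos ("no beats detected") and empty acquisition windows
raise; zero within-group variance in ANOVA defines p as 0 or 1 with a
warning; field evaluation within 1 µm of a wire raises as singular; the
trajectory CSV reader rejects missing columns, frame-numbering gaps,
non-uniform time stamps and ragged marker lengths with named errors. All
generators and the study driver derive per-video streams from a root seed
(`numpy.random.SeedSequence` spawning), so identical seeds give bit-identical
trajectory tables and CSV outputs.

## Problem sizes

Defaults were sized so the full test suite and the acceptance script each
run in minutes on a single core: acceptance uses 20 seeded studies of
4 arms × 20 syncytia × 5 videos (trajectory mode, no rendering), 500-frame
rendered stacks for tracking, 2000 ANOVA null replicates, 100 noise-only
seeds and 50 recovery syncytia. All counts are parameters and scale up
without code changes.

## Known limitations

- The waveform family, radial displacement field, and effect multipliers are
  stand-ins with the study's statistical *structure*, not fitted to any real
  recording; absolute metric values are in arbitrary pixel units (no
  pixel-to-micron calibration exists in the sources).
- Contractility (V) inherits a significant ISO contrast from the shipped
  τ-shortening, whereas the reproduced narrative treats the single-treatment
  kinematic contrasts as non-significant; the pattern checks therefore score
  D, Acc and fluorescence, not V.
- The LSD procedure is intentionally unadjusted; with 6 pairwise contrasts
  per metric its family-wise error exceeds α.
- The coil geometry is calibrated, not measured; only the center-field and
  derived dosimetry quantities are meaningful, not, e.g., the off-axis
  profile shape far from the center.
- Tracking assumes translation-only spot motion and constant illumination;
  there is no rotation/scale handling and no template update.
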