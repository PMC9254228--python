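# Methods

This note documents the models, algorithmic choices and limitations
behind `circafly`, in the order data flows through the package.

## DAM2 monitor I/O

The parser accepts the tab-separated DAM2 dialect: a reading index, a
date (`d mmm yy`), a time, a status code, six device fields (field 10 is
the light sensor) and 32 channel counts — at least 42 fields, with extra
trailing fields tolerated, since field counts vary across firmware.
Rows with a non-OK status are treated as missing readings and imputed as
zero counts with a logged warning rather than dropped: the periodogram
and the consolidation statistic both assume an unbroken uniform bin
grid, and dropping rows would silently shift every later phase
assignment. Ages are days post-eclosion; recording starts at
`start_age_days` (default 3, flies being loaded at three days old) and
the age of bin *i* is `start_age + i·bin_minutes/1440`.

Death detection is deliberately simple: a fly is scored dead at the age
of its last active bin when the terminal run of zero counts spans at
least `quiescence_hours` (default 24 h). A fly with no activity at all
is assigned the start age. Death days are quantised to the bin grid.
Age-window slices take bins whose start age lies in
`[start_day, end_day + 1)`; the default AW1/AW2/AW3 windows therefore
tile a 3–23-day recording exactly, with no gap or overlap.

## Chi-square periodogram

The statistic is the Sokolove–Bushell Qp. For each integer
bins-per-period *P* in the scan grid (default: every 20-min step from
16 h to 32 h), only the first `K·P` bins (*K* = ⌊N/P⌋ complete cycles)
are folded, keeping all columns the same depth so the χ²(P−1) null
retains its exact form; with column means M_h and grand mean M̄ over the
folded bins,

    Qp = n·K·Σ_h (M_h − M̄)² / Σ_i (x_i − M̄)²,  n = K·P.

A fly is rhythmic when Qp exceeds the χ² critical value at α (default
0.01) at any trial period; the period estimate is the supra-threshold
Qp argmax (ties break to the smallest period, deterministically).
"Rhythm robustness" is defined here as peak Qp minus the significance
line at the peak — the plotted amplitude of the closed-source tool the
field commonly uses is not publicly specified, so no bit-compatibility
with it is claimed, and all robustness comparisons in this package use
this one definition consistently. A zero-variance window (e.g. a fly
dead throughout) yields Qp = 0 everywhere with a warning rather than an
error, and `RhythmCall.manual_override` lets an analyst record a visual
veto without the package ever setting it.

Calibration, measured by simulation on white-Poisson series (mean 5
counts/bin): the per-period test is slightly conservative — the true
level at α = 0.01 is ≈ 0.006 for 7-day windows (K = 5–10 folded cycles)
and ≈ 0.008 for 21-day records. The *scan-level* false-positive rate is
a different quantity: the 49 trial periods of the default grid are
nearly independent after folding, so calling a fly rhythmic when any
period crosses its line inflates the family rate to roughly
1 − (1 − 0.006)⁴⁹ ≈ 0.22 (7-day) to ≈ 0.33 (21-day). This inflation is
inherent to per-period thresholding at a fixed α and is reported by the
acceptance script rather than corrected, because the emulated protocol
thresholds per period at *P* = 0.01 (and screens survivors by eye). For
genuinely rhythmic flies the scan is very sensitive: simulated κ = 2
flies are recovered with the correct period to within one bin in > 95%
of 7-day windows.

## Consolidation statistic r

Each age-window segment is divided into cycles of length *T* anchored at
the window start; a bin belongs to the cycle containing its midpoint and
its phase angle is `2π·((midpoint − cycle_start) mod T)/T`. The
midpoint (rather than bin-start) convention makes the phase assignment
symmetric within the bin; consecutive bins are separated by the constant
angle `bin_minutes·2π/T`. Within one cycle, *r* is the mean resultant
length of the activity-weighted unit vectors. Conventions where the
underlying procedure is unspecified: trailing partial cycles are
excluded (a partial cycle covers only part of the phase circle and
biases the resultant toward the covered phases); zero-activity cycles
yield a missing *r*, not *r* = 0 (excluded from cohort means, with *n*
reported per point); cycle indices map to nominal days as
`start_age + index`, a labelling convention exact only when *T* ≈ 24 h.

Cycle length selection per fly per window: a rhythmic fly uses its own
periodogram period; an arrhythmic fly the mean period of its genotype's
rhythmic flies in that window; a fly dying mid-window its prior-window
period, falling back to the genotype mean; a genotype-window with no
rhythmic flies at all falls back to 24 h with a logged warning (a case
the emulated protocol leaves uncovered). Every choice is returned with
a provenance tag (`own_period`, `genotype_mean`, `prior_window`,
`fallback_24h`) so output tables are auditable.

## Cohort statistics

Percentage rhythmicity is computed over flies alive through the window
(death day absent or past the window's last day). Groups with fewer
than 10 alive — or fewer than 10 rhythmic — flies are flagged excluded
for between-genotype period/robustness comparisons but keep their
summary numbers; exclusion is applied at the statistics layer, never at
data capture. Multi-run aggregation reports raw mean/s.e.m. percentages
plus `arcsin(√(p/100))` transforms for downstream repeated-measures
testing.

The m×n Fisher exact test uses the probability-ordering two-sided
criterion (total probability of tables, under fixed margins, no more
probable than the observed one) — the most common convention. 2×2
tables are exact (hypergeometric, delegated to scipy); larger tables
are estimated by Monte-Carlo permutation of column labels against fixed
row labels, which samples tables with exactly the observed margins; the
binomial standard error of the estimate is returned alongside p.
Benjamini–Hochberg adjustment is the standard step-up
`adj_(i) = min_{j≥i}(m·p_(j)/j)` (verified against R's `p.adjust`).
Cochran Q uses complete cases and returns a flagged missing result when
all rows are constant (the statistic is undefined); with two conditions
it reduces algebraically to McNemar's χ² without continuity correction,
which is therefore the McNemar default (the correction is exposed as a
flag). KS comparisons of 0–5 LNv-count distributions use the asymptotic
two-sample p, conservative on so discrete a support; results carry a
note saying so. Kruskal–Wallis/Friedman omnibus tests are delegated to
scipy; the mean-rank pairwise post-hoc is a Dunn-type z test with tie
correction, and every report records the exact method names used.

## Synthetic behaviour generator

A fly's expected count in a bin follows a von Mises density on its
circadian phase, scaled so the phase-average equals
`mean_counts_per_bin` (default 5 counts per 20-min bin, a moderate
activity level); observed counts are Poisson. The concentration κ is
the single consolidation knob: the profile's mean resultant length is
I₁(κ)/I₀(κ), 0 in the uniform limit and → 1 as κ → ∞, mapping directly
onto the *r* statistic. Defaults emulate the study design: 32 flies per
cohort, 21 days of DD from age 3 days, 20-min bins, period 24 h, κ = 4.
After an optional arrhythmia-onset age the rate becomes uniform at the
same mean — losing rhythm without losing activity, so rhythmicity
effects are not confounded by activity effects; after an optional death
age all bins are zero, matching the death detector's assumption. Each
fly draws from an RNG substream seeded by (cohort seed, fly index), so
cohorts are reproducible under parallel generation. The generator makes
no attempt to reproduce real ultradian structure, startle responses,
morning/evening peak anatomy or LD entrainment; passing tests therefore
demonstrate correctness of the analysis chain on idealised free-running
data, not robustness to every behavioural idiosyncrasy of real flies.

## Imaging pipeline

Preprocessing applies, in order: min–max rescale to the 0–255 integer
range (the source tool's display-range-dependent 8-bit conversion is
session-dependent and unrecoverable, so min–max is used); rolling-ball
background subtraction with radius 10 px (morphological background
estimation; exact agreement with sliding-paraboloid variants is not
claimed — the contract is the flat-field-to-zeros and blob-recovery
properties); subtractive unsharp mask `(I − w·G_σ(I))/(1−w)` with
σ = 1 px, w = 0.7; a 3×3 sharpen convolution
`[[−1,−1,−1],[−1,12,−1],[−1,−1,−1]]/4`; and Sobel gradient magnitude as
"find edges", rescaled to 0–255. The intermodes threshold smooths the
256-bin histogram with a 3-point running mean until exactly two local
maxima remain (capped at 10 000 passes; a histogram that never becomes
bimodal — e.g. a flat field — raises an error that the top-level
quantifier converts to an empty particle set with a warning) and sets
the threshold midway between the modes.

Particle analysis labels 8-connected foreground, fills interior holes
before labelling (outer-contour tracing: an object's edge ring and its
interior count as one particle, as a wand-trace counter behaves), and
drops components below 1 µm² — the stated lower size limit, interpreted
as area since the tool's size specification is in calibrated units.
Counts deliberately include spots: the pipeline does not distinguish a
large oval spot from puncta-like inclusions, so spot-bearing
hemispheres inflate inclusion counts exactly as the emulated procedure
does. Note that edge-based outlines run systematically larger than the
planted core areas; counts are the validated quantity, areas are
reported as measured.

## Synthetic micrographs

Planted inclusions are disks of the target area convolved with a
0.8 px Gaussian PSF — sharp-edged bright puncta. An earlier pure
Gaussian-profile rendering was rejected: its edge strength scales as
1/σ, so equal-brightness objects of different sizes produce edge rings
of very different intensity and no single intermodes threshold
recovers them all; PSF-blurred disks give uniformly strong edges, which
is also the more physical model of a compact aggregate under a
microscope. Spots are compact ellipses (aspect ratio 1.2–1.8) under the
same PSF. The default calibration is 0.1 µm/px over a 320×320 frame
(a 32 µm field, the scale of an LNv cluster): the edge ring that
segmentation traces is 1–2 px wide regardless of calibration, and at
coarser sampling that ring inflates a sub-cut-off 0.5 µm² speck's
outline past the 1 µm² filter; at 0.1 µm/px planted specks stay below
the cut-off and in-range objects above it. Noise options are none,
Poisson (on the intensity scale) or additive Gaussian. Ground truth
records each object's class, centroid and analytic area. The closed
loop — plant, segment, compare — recovers the planted count exactly on
≥ 95% of noise-free fixtures and within ±1 under Poisson noise;
what this shows is internal consistency of generator and pipeline, not
performance on real tissue, where focus, labelling variability and
touching objects add failure modes the generator does not model
(placement enforces object separation, so merged objects are never
generated).

## Hemisphere categorisation

Cell-level expHTT form labels are expert inputs; only the
hemisphere-dominance rule is computed. Each label contributes its base
forms (Diff+Inc → Diff and Inc, etc.) to a tally over Diff/Spot/Inc;
unstained (NoHTT) cells are excluded. A strict plurality names the
category; two-way ties give the combined categories Diff+Inc, Diff+Spot
or Spot+Inc; a three-way tie gives Diff+Spot+Inc. A hemisphere whose
cells are all unstained returns a NoHTT flag that is recorded but never
treated as a category. The rule is total (every valid label multiset
maps to exactly one outcome) and order-invariant, both property-tested.

## Problem sizes and numerical conventions

Simulation-based checks use 2000 series for type-I calibration (21-day
length, where the χ² null is closest to asymptotic), 200 flies for
period recovery, 50 flies per κ level for the consolidation ladder, and
100 noise-free plus 50 noisy fixtures for imaging recovery — sizes at
which the binomial uncertainty of each rate is well below the margins
being asserted. Exact identities (r oracle, Qp hand example, BH,
Cochran-Q/McNemar equivalence) are asserted at 1e-9–1e-12. Monte-Carlo
Fisher p-values use the add-one estimator (never exactly zero) and are
compared within three binomial standard errors.
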