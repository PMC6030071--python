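# Methods

This note documents the models, parameter defaults, and design choices
behind `qppdyn`, and what the synthetic validation does and does not show.

## Data model and conventions

A scan is a single slice of `m × n` voxels over `T` frames at repetition
time `TR` (default 0.5 s). In-mask voxels are enumerated in row-major
order over `(row, col)`, 0-based; every `L`-indexed array — series,
templates, atlas voxel sets — shares this ordering, which is what keeps
templates and series aligned across modules. Frames are 0-based; a window
specified in seconds is converted to frames by `round(sec / TR)` (3 s → 6
frames). Only single-slice data are accepted; a 3-D volume is rejected
unless one spatial dimension is 1. Group series are concatenations of
per-subject scans with recorded half-open frame intervals; no correlation
window, filter, or regression ever crosses a subject boundary.

## Detection

The sliding template correlation at start `t` is the Pearson correlation
between the vectorised `L × W` template and frames `[t, t+W)` — the value
at `t` describes the window *starting* at `t`. Starts whose window would
cross a scan boundary, run past the end, or have (numerically) zero
variance are flagged invalid and carry value 0. The implementation uses
exact per-window sums (a BLAS product for the cross-terms plus sliding
window sums), which agrees with brute-force Pearson to ~1e-15 and costs
`O(T·L·W)`.

Peaks are strict local maxima above the 0.2 threshold within each valid
run; a plateau counts once, at its first frame. Among peaks closer than
`min_separation` the larger wins (ties to the earlier frame). The
function-level default is `⌈W/2⌉`; the pipeline uses one full window `W`,
because occurrences of one pattern are by construction at least a window
apart and the STC of a monophasic burst template has secondary maxima
within half a window that would otherwise be double-counted.

Refinement iterates template → STC → peaks → average of the image chunks
at the peaks. Convergence is declared when the correlation between
consecutive iterations' STC vectors (over jointly valid positions)
reaches 0.9999 on two successive checks — a cheap, scale-free criterion;
`max_iter` is 20. An iteration with no suprathreshold peaks ends the
restart as an unconverged record with empty peaks; such records are kept
for audit but excluded from selection. 500 random restarts constitute a
full run; the fast profile uses 50. Selection takes the converged record
with the highest sum of STC peak correlations, with ties broken toward
more peaks, then the earlier seed frame.

On noise-free planted data any fixed frame offset from the occurrences is
an exact fixed point of the refinement (every occurrence repeats
identically), so recovered templates are compared to ground truth at the
best lag within one window, requiring at least half a window of overlap
so that one-frame overlaps cannot fake a match.

## Projection, rates, matching, window extension

A projection STC slides a *fixed* template over another group's series —
the computation is identical to detection-time STC, with peaks from the
same rule — so a pattern's occurrence rate (peaks per minute inside each
subject's interval) is measurable in the group it came from and, via
pSTC, in the other group. Rates are compared across groups with a pooled
two-sample two-tailed t-test (Welch available).

Corresponding QPPs across groups are found by maximising the absolute
cross-correlation between the reference pattern's pSTC and each candidate
record's STC over lags up to one window; the sign of the extremum marks
phase-inverted matches and the lag temporal offset.

Spatial contrast is the mean over frames of `|σ/μ|` of voxel intensities
(sample SD); frames whose mean is at rounding level relative to their SD
are capped at 1e6 (the ratio is unstable by construction), and constant
frames contribute 0. High values mean frames mix activated and
de-activated regions; global-signal-like patterns score low.

To estimate a pattern's true temporal extent, chunks extended by `E`
frames on both sides are averaged over non-overlapping occurrences
(edge-crossing windows dropped; of two overlapping extended windows the
later is dropped; at least 3 must remain). Voxels significant in a
per-cell one-sample t-test (Benjamini–Hochberg at q=0.001) define a
frame-wise RMS profile; the estimated length is the span from the first
to the last frame whose RMS clears half its maximum. The first-to-last
rule (rather than the longest run above threshold) is deliberate: a
biphasic pattern dips through zero mid-pattern and would otherwise be
truncated to one phase. Significance maps for display use the same
one-sample t machinery over all `L·W` cells with BH-FDR at q=0.001.

## Preprocessing

Default per-subject chain, in order: trim 20 frames per end → motion
(nuisance) regression → in-plane Gaussian smoothing → 0.01–0.2 Hz
band-pass → trim 20 frames per end again → quadratic detrend → unit
variance. The band-pass is a Hamming-window linear-phase FIR of order
`round(4/(low·TR))` capped at `T/3`, applied forward–backward
(`filtfilt`) so the net phase is zero; the data are demeaned first
because the FIR's DC gain is only approximately zero. Smoothing uses
masked normalisation (smoothed image divided by the smoothed mask) so
edge voxels are unbiased and a constant frame is preserved exactly.
Voxels with numerically zero variance are zeroed and flagged; the flag
propagates so downstream correlations skip them. Global signal
regression is available as a tagged variant stream and is off by default.
The pipeline smooths at σ=0.75 pixels, the σ=2 convention of a 128-wide
acquisition matrix rescaled to the 48-wide synthetic slice. Transient
counts and filter order are configuration defaults, not claims about any
particular acquisition.

## QPP regression and FC

A pattern's image series is the linear convolution of its (continuous)
STC segment with each voxel's W-frame template course, truncated to the
segment; invalid STC positions contribute 0. The full continuous STC is
used rather than a thresholded peak train, so sub-threshold expression is
removed too; a peaks-only variant exists. Removal is per-voxel OLS on
`[intercept, regressor]`, computed per subject on that subject's STC or
pSTC segment (FC is a subject-level quantity); residuals are exactly
orthogonal to both columns, and voxels whose regressor has no variance
pass through unchanged, flagged. Multiple patterns are removed
one-by-one.

FC matrices are pairwise Pearson correlations of ROI-mean courses,
Fisher z-transformed with `|r|` clipped at `1 − 1e-7`. Network measures
average zFC over within-DMN pairs, within-TPN pairs, and all DMN×TPN
cross pairs; homotopic (left–right) pairs are included. ΔFC is the
after-minus-before difference per subject and measure. Group statistics
are standard two-sample, paired, and one-sample t-tests with degenerate
zero-variance cases resolved explicitly (p=1 for a zero effect, an
infinite-t flag otherwise); multiple testing uses Benjamini–Hochberg.

## Classification

The default measure table has 17 columns per subject: DMN, TPN and
DMN–TPN zFC; occurrence rates of the three canonical patterns; DMN and
DMN–TPN zFC after regressing each pattern (DMN–TPN omitted for the
global pattern's delta); and the corresponding ΔFC values. Each measure
alone, and all jointly, feed an elastic-net logistic regression
(l1_ratio 0.5; regularisation strength chosen per training fold by inner
5-fold log-loss over a 5-point C grid, falling back to a fixed mid-grid
strength when a training fold is too small for inner CV). Predictors are
standardised inside each training fold. Cross-validation is stratified
10-fold repeated 10 times; with 18 subjects folds hold 1–2 subjects and
stratification is best-effort. Per repeat the AUC is computed from the
pooled out-of-fold probabilities (Mann–Whitney with ties counting ½);
the mean and its standard error are taken over repeats, and the
10×10 fits yield 100 coefficient vectors for the combined model. Models
are compared by a 2000-replicate stratified paired bootstrap of the AUC
difference (normal test of the observed difference against the bootstrap
SD), Bonferroni-corrected; the pipeline compares the combined model
against each single measure by default (all pairs optional) to keep the
run affordable.

## The synthetic cohort

The generator emulates a two-group mouse rsfMRI study: 8 WT + 10 TG
subjects, 20-minute scans at TR 0.5 s (2400 frames; the fast profile uses
1200), one 48×32 slice whose mask is an ellipse with a ventricle hole,
and 12 rectangular ROIs standing in for bilateral cingulate (Cg) and
dorsal caudate-putamen (DMN-like) and S1, S2, insula, ventro-lateral
caudate-putamen (TPN-like).

Three patterns are planted: `WT_like` (3 s; DMN ROIs co-active, TPN ROIs
anti-phase), `TG_like` (3 s; Cg anti-phase to dorsal CPu, TPN silent),
and `GS_like` (6 s; every ROI on one sign, with DMN riding the wave at
0.4× amplitude so the global wave is not simply a superset of the DMN
burst). Templates are unit Frobenius norm, zero off-ROI. The default
burst envelope is the band-limited bump: a half-sine passed through the
same 0.01–0.2 Hz zero-phase FIR the analysis uses and cropped to the
window. This plants the kind of infra-slow, band-limited event
resting-state analysis operates on, and makes the planted template
(approximately) invariant under the preprocessing chain — a crisp
half-sine would re-emerge from the band-pass with a pedestal and
undershoot tails that are preprocessing artefacts, not pattern.

Occurrence starts follow gamma-distributed inter-start intervals (shape
5 — "quasi-periodic": regular but jittered; the shape → ∞ limit is
strictly periodic), with a floor of one window between occurrences of
the same pattern. By default occurrences of *different* patterns never
share frames either (conflicting draws are dropped), which keeps the
ground truth identifiable: with temporal overlap allowed, chunk
averaging across coincident events converges on mixture templates that
fire at several event types at once. Overlap can be re-enabled
explicitly. Default rates (occurrences/minute): WT group 2.5 / 0.6 / 2.5
and TG group 0.6 / 2.0 / 1.5 for WT_like / TG_like / GS_like — the
wild-type pattern and the global wave are frequent in WT, the
disrupted-DMN pattern in TG.

Occurrence amplitudes are lognormal (σ=0.2) around 15 (3 s patterns) and
21 (6 s pattern) in arbitrary BOLD units; with noise SD 1.0 smoothed at
σ=0.4 pixels these place STC peaks around 0.4–0.6, comfortably above the
0.2 threshold yet far from ceiling, with the weakest occurrences near
it. Confounds: per-voxel quadratic drift (coefficient SD 2), six smooth
motion-like regressors with random spatial loadings (gain 0.5), and
spatially smoothed Gaussian noise. Ground truth records templates,
occurrence frames, amplitudes, groups and seeds (JSON); motion and drift
are kept in memory for the preprocessing stage but not serialised.

**What passing means.** The generator produces additive, non-overlapping,
band-limited events on crisp rectangular ROIs with stationary smooth
noise. Real BOLD data have hemodynamic convolution, physiological and
vascular noise, spatially varying SNR, imperfect registration, and
patterns that wax, wane and overlap. Recovery and calibration results on
this cohort validate the *implementation* — that detection finds what
was planted at the stated SNR, that regression removes exactly what the
model says, that the statistics are calibrated — not that the method has
any particular sensitivity on real scans.

## Known behaviour and limitations

* **The 6 s global pattern is recovered less cleanly than the 3 s
  patterns** (spatial correlation ~0.85–0.9 vs ~0.95, and its occurrence
  rate over-counted up to ~2×). Two intrinsic effects drive this: a
  half-empty 12-frame window shifted by half a window from the wave is
  still a near-fixed point, and peak-sum selection *favours* such
  promiscuous templates because their STC also fires on the
  band-pass undershoots of the frequent 3 s events. This is a property
  of select-by-peak-sum on mixed traffic, faithfully reproduced, and is
  reported honestly by the acceptance script.
* Rate estimates carry a small positive bias (~0.1–0.3 false peaks per
  minute) from just-above-threshold noise peaks; at the default planted
  rates this stays within a few percent of the per-subject rate.
* The coefficient-of-variation contrast is undefined for zero-mean
  frames; the 1e6 cap is arbitrary but documented, and only ranking is
  ever used.
* Sequential (one-by-one) regression of correlated patterns does not
  partition variance uniquely; the simultaneous design-matrix option
  exists but is not the default.
* Problem sizes in the test suite and acceptance script (fast profile:
  1200 frames, 50 restarts; determinism check: 2+2 subjects, 600 frames,
  12 restarts) are the package's validation scale; the full-profile
  defaults (2400 frames, 500 restarts) are what an actual study run
  would use.
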