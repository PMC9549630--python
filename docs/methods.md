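# Methods

## Scope and data model

The package operates on spatially aligned, masked 4D BOLD series. In memory a
group is an `ImageSeries`: a voxels × frames matrix over in-mask voxels (C
order over the mask, shared with `Atlas` so ROI lookups index rows directly),
the repetition time, and half-open per-subject frame bounds. Every
preprocessing and detection step respects those bounds: no regression, filter
or correlation window ever crosses a subject boundary, and sliding-window
offsets whose window would straddle one are flagged invalid (NaN) rather than
computed.

## Preprocessing

Fixed order, applied per subject segment:

1. **Global signal regression** — least-squares residual of every voxel
   against `[1, mask-mean time course]`. Residuals are exactly orthogonal to
   the regressors within each segment. Refused on z-scored input (the global
   estimate would be distorted) and on zero-variance global signals.
2. **Quadratic detrending** — residual against `[1, t, t²]` with `t` scaled
   to [−1, 1] for conditioning; demeaning is the intercept term, so output
   segment means are exactly zero. Segments shorter than 4 frames are
   rejected.
3. **Voxel-wise z-scoring** — per segment, population SD. Rows with
   SD < 1e-12 are set to zero and logged rather than dropped, keeping voxel
   indexing stable.
4. **Band-pass** — Butterworth 0.01–0.17 Hz, order 5, applied
   forward–backward (`filtfilt`) for zero phase. Order and band are
   configurable via `FilterSpec`; the high edge must stay below Nyquist
   (0.833 Hz at TR = 0.6 s).

Z-scoring precedes filtering deliberately (that is the pipeline order the
analysis defines), so filtered rows no longer have exactly unit SD. Two group
series are kept: the z-scored one drives detection; a parallel non-z-scored
series (all other steps applied) feeds peak-timing, which reads amplitudes.

Ventricle/CSF exclusion is represented entirely by the brain-mask input; no
segmentation is performed here.

## Detection

`detect_qpp` implements the iterative sliding-template algorithm. The STC at
offset k is the Pearson correlation (population normalisation; only relative
comparisons matter) between the flattened voxels × W template and the segment
starting at k. It is computed exactly but efficiently: the numerator comes
from W short diagonals of `template.T @ data`, segment means/variances from
rolling sums, so one STC costs O(V·W·T). A brute-force per-offset loop is the
test oracle at 1e-10.

Peaks are *strict* local maxima ≥ 0.2 whose both neighbours are valid,
greedily thinned from the highest peak so retained peaks are ≥ W apart —
this prevents double-counting overlapping windows; offsets adjacent to
invalid ones can never be peaks. Each iteration averages the occurrence
windows into a new template and stops when successive templates correlate
≥ 0.99 (`convergence_corr`), when an iteration finds fewer than 2 peaks, or
after `max_iter` = 20 updates; the converged flag is reported honestly either
way, and the final STC/occurrences are recomputed from the final template. A
converged template is a fixed point: re-refining it converges in one
iteration. Mean peak STC is tracked per iteration and non-increase is logged.

Ensembles draw `n_seeds` (default 200, as the method prescribes) seed frames
without replacement from the valid offsets of a dedicated RNG, so results are
exactly reproducible from `rng_seed`.

## Similarity, clustering, matching

`pattern_similarity` is the one similarity primitive: the space-time Pearson
correlation over overlapping frames, evaluated at integer shifts in
[−max_shift, max_shift] (default ⌊W/2⌋), choosing the shift with maximum
|correlation| (ties: smaller |shift|, then smaller shift) and returning the
*signed* value. Anti-correlated patterns therefore score near −1 and never
merge — the activation pattern and its mirror are distinct brain states.

Clustering is average-linkage on distance `max(0, 1 − similarity)`, tree cut
at 0.3 (= similarity 0.7, mirroring the 0.70 matching scale; configurable).
Unconverged QPPs are excluded by default. A cluster is robust when

- size ≥ 20 members (the reference gate for 200-seed ensembles — scale the
  10 % fraction when running smaller ensembles),
- its representative's pattern occurs > 10 times across the image series,
- more than half its members occur at least once in at least 80 % of
  subjects.

The representative QPP is the member with the most occurrences; ties break to
the lowest seed frame. Cross-group matching scores all rQPP pairs and fixes
them greedily by descending similarity, one-to-one; a pair is matched only if
correlation strictly exceeds 0.70.

## Group statistics

Voxel-wise maps use one-sample (activation) or pooled-variance Student
two-sample (group difference) t-tests per voxel-frame, two-sided. FDR is
Benjamini–Hochberg at q = 0.05 over *all* voxel-frame tests of one map (the
family could alternatively be per frame; joint is the default here), followed
by a per-frame 3D connected-component filter at 10 voxels with 6-connectivity.
Zero-variance voxel-frames get t = 0, p = 1, and are logged. Cohen's d on
occurrence-wise ROI-mean time courses uses the pooled SD with n₁+n₂−2.

Occurrence rates are per-subject counts of the group-level rQPP's STC peaks
restricted to that subject's frames, expressed as occurrences/minute
(count/(frames·TR/60) — the constant does not affect group tests); matched
clusters are compared with unpaired two-tailed t-tests, FDR across clusters.
Static FC computes ROI-mean Pearson correlations per subject, Fisher
z = atanh(r) with |r| clipped at 1 − 1e-12, and per-pair two-sample tests
with FDR across pairs.

## Peak timing

Representative QPPs of a second group are phase-aligned to the reference
group's by the circular shift (±max_shift) maximising space-time correlation.
Peak timing takes, per voxel and occurrence window of the *non-z-scored*
series, the argmax frame (maximum, not extremum magnitude; ties to the
earliest frame — the result is invariant to positive rescaling), averages
over occurrences, and groups voxel means by ROI. Voxels constant in every
window are excluded and counted. ROI pairs are compared by unpaired t-tests
on voxel-wise mean timings with FDR across pairs; the pairwise difference
matrix (peak_y − peak_x) is antisymmetric by construction. The genotype × age
ANOVA uses Type II sums of squares (robust to unbalanced voxel counts,
identical to the textbook decomposition under balance; verified against a
hand-coded oracle), with post-hoc Student t-tests (genotype within age, age
within genotype) under BH-FDR. Caveat, carried over from the analysis design:
voxels are treated as independent observations despite spatial dependence, so
these p-values are anti-conservative in that respect; no correction is added.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
MRI physics:

- **Atlas** — 24 × 24 × 8 grid, 22 × 22 × 6 brain box (2904 voxels). The two
  anti-correlated networks cover ~91 % of the brain (1320 voxels each) with a
  36-voxel BFB-like region in the band between them. Coverage matters: the
  whole-brain template correlation at an event scales with the fraction of
  in-mask voxels carrying the pattern, and with sparse networks the fixed 0.2
  STC threshold is never reached at realistic per-voxel CNR, which is also
  why whole-cortex patterns dominate real recordings.
- **Events** — one-cycle raised cosine over W frames, unit peak (smooth and
  unimodal, so planted peak timing is unambiguous; W = 2 degenerates to a
  flat pulse). Signed ROI amplitudes (+1 DMLN, −1 LCN, +1 BFB by default)
  give per-voxel CNR ≈ 1 against unit noise — invisible in single voxels,
  detectable after averaging, as in real data. ROI lags shift the waveform
  whole frames; the default wild-type template gives the BFB a 1-frame lead,
  and the transgenic-like template removes the BFB's participation (or, for
  timing studies, just its lead).
- **Onsets** — uniform with greedy rejection at a minimum separation of W+2
  frames: quasi-periodic events do not run back-to-back, and the two frames
  of slack keep adjacent detection windows disjoint even at ±1-frame phase
  offsets. Realised per-scan counts are Poisson around the group mean
  (defaults 30 wild-type / 15 transgenic per 500-frame scan, i.e. 6 vs 3 per
  minute), clipped to a feasibility cap of 60 % of span/separation because
  random sequential placement saturates well below dense packing.
- **Nuisance** — iid Gaussian voxel noise (SD 1), a shared low-frequency
  random walk (SD 0.5) so global signal regression has something to remove,
  and optional quadratic drift.
- **Ground truth** — every onset, amplitude, template and lag is recorded and
  serialised as JSON; noiseless generation is exactly reconstructible from
  it. Cohorts are byte-identical across runs with the same seed.

What it does *not* emulate: hemodynamic convolution, physiological noise,
motion, spatial autocorrelation of noise, or subject-level anatomical
variability. Passing tests show the pipeline recovers what it assumes —
recurring additive spatiotemporal events in band-limited noise — not that it
is robust to artefacts absent from the simulation.

## Scoring recovery against ground truth

Two subtleties are handled explicitly and deliberately:

1. **Reference pattern.** The detector only ever sees the band-passed series,
   and a 3.6-s event is reshaped by the 0.01–0.17 Hz filter (attenuation at
   the band edge plus zero-phase ringing); the detected template matches the
   filtered truth at ~0.98 while its correlation to the raw planted window is
   bounded near ~0.9 by the filter alone. `planted_pattern_filtered` renders
   one noiseless event and applies the pipeline's own band-pass, giving the
   correct reference for what detection can possibly recover (GSR and
   detrending barely touch an isolated event in noisy data and are omitted;
   correlation scores are insensitive to z-score rescaling).
2. **Phase.** Detection may lock onto a time-shifted copy of the planted
   pattern, with all occurrences offset by the same amount. `score_recovery`
   maximises the template correlation over ±W/2 shifts, and scores occurrence
   recall/precision at the single global shift with best F1 (±1-frame
   tolerance) — at half-frame phase the correlation-argmax shift can differ
   by one frame from the occurrence offset, which would spuriously zero the
   recall.

The band-passed series also genuinely contains a second, anti-correlated
pattern family (the post-event undershoot), which detection finds as a
separate robust cluster — the same two-anti-correlated-states structure seen
in real recordings. Recovery is therefore scored on the robust cluster that
best matches the planted reference.

## Problem sizes and runtimes

Validation studies run at desk scale, chosen so the full suite and the
acceptance script each finish in a few minutes on one CPU: recovery uses one
6-subject × 500-frame group with a 50-seed ensemble (robust gate scaled to
10 % = 5); occurrence-rate power uses 50 replicates of 6 + 6 subjects;
the null false-positive control uses 200 replicates of 15 + 15 noise
segments on a 200-voxel grid; lead/lag uses W = 15, 12 events/scan,
30 seeds. The method's reference configuration (200 seeds, 1000-frame scans)
is the library default and runs unchanged, just longer.

## Known limitations

- The 0.2 peak threshold is fixed at every iteration (no warm-up schedule);
  with weak or sparse patterns detection may simply not bootstrap, which is
  reported as unconverged seeds rather than compensated.
- Sub-frame (interpolated) peak localisation is not implemented; timing
  resolution is one TR.
- The FDR + extent thresholding is a heuristic, not a cluster-level inference
  procedure; no permutation calibration is provided.
- `max_shift = ⌊W/2⌋` bounds the phase families that clustering can merge;
  patterns detected at larger offsets form separate clusters by design.
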