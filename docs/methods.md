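# Methods

## Data model

A contact map is an N×N symmetric matrix of log(observed/expected) contact
frequencies with an explicit boolean mask for missing cells. Masked cells
never enter any mean, correlation, ratio filter or window — every statistic
in the package is computed over unmasked cells only, and pairing two maps
applies the union of their masks to both. Coordinates are 0-based; bin i
covers the half-open interval [start + i·b, start + (i+1)·b) for bin size b
(default 2,048 bp; a 448-bin map spans 917,504 bp). Asymmetric inputs are
symmetrized by averaging (i, j) and (j, i) rather than rejected, since
experimental dumps are near-symmetric. Preprocessing clips unmasked values
to (−2, 2), can fill missing cells by linear interpolation along rows and
columns (the two passes averaged; the axis order is fixed for determinism —
no convention is canonical here), and can smooth with a 2D Gaussian kernel.
Maps in which more than 60% of cells are exactly zero are flagged as
unreliable by a quality filter. The input is assumed already balanced and
log(O/E)-transformed; the log base is the producer's choice and none of the
scores depends on it beyond monotonicity. Supported formats are dense
tab-separated text (`nan` = missing) and a single 2D float64 `.npy` array.

## Scores

All scores are reported direction-aligned: similarity statistics x become
1 − x, so higher always means more disrupted, and every score is 0 on
identical unmasked content. Correlation- and MSE-type statistics are
evaluated over the upper triangle including the diagonal, so symmetric cells
are not double-counted (this leaves correlations unchanged and halves the
MSE sample without changing its value on symmetric maps).

- **MSE** — mean of (a − b)² over unmasked upper-triangle cells.
- **Correlation** — Spearman by default; Pearson behaves nearly identically
  on these data and is offered as an option. Undefined on constant inputs.
- **SSIM** — mean local structural similarity with Gaussian-weighted windows
  (window 7, σ = 1.5, K1 = 0.01, K2 = 0.03, Wang-style weighted moments
  without the sample-covariance correction), computed by scikit-image. The
  dynamic range is the joint max − min of the pair rather than a fixed
  (−2, 2) interval, so unclipped synthetic maps are handled. Masked cells
  are filled with the map's unmasked mean before windowing and the local
  SSIM image is averaged over unmasked cells only; undefined when the joint
  range is zero.
- **SCC** — per-diagonal (stratum) Pearson correlations ρ_k combined with
  HiCRep-style weights w_k = N_k·sd(a_k)·sd(b_k). Strata with fewer than 3
  unmasked cells or zero variance in either map are skipped; undefined when
  no stratum is admissible.
- **Track scores** — insulation (diamond window, 10 bins; undefined within
  one window of the edges), contact directionality (window =
  round(10,000 bp / b) native bins; for upstream sum A, downstream sum B and
  E = (A+B)/2 the value is sign(B−A)·((A−E)²/E + (B−E)²/E), zero when A = B
  or E = 0; the first and last 50 track positions are zeroed because partial
  windows make the statistic unstable — the buffer is interpreted in track
  bins, as 50 bp would be sub-bin at 2,048-bp resolution), eigenvector
  (leading eigenvector of the row-correlation matrix, masked cells excluded
  pairwise; the sign is fixed by positive correlation with the row-mean
  track and the pair is re-sign-aligned before comparison, since an
  eigenvector's sign is arbitrary and the score would otherwise be
  ill-defined), and distance enrichment (per-diagonal mean; one value per
  distance, which deliberately over-weights distal strata that contain few
  cells). Tracks are compared over jointly defined positions with
  1 − Spearman or MSE.
- **Triangle** — means over diagonal-anchored s×s submatrices (upper
  triangle including the diagonal) at dyadic scales {2, 4, 8, …} with
  stride 1, compared entrywise between the two maps. The dyadic
  diagonal-anchored scheme is this package's design; it is the minimal
  scheme that probes substructure from fine to coarse, and all of min_scale,
  stride and an optional block-average downsampling factor (5 is a sensible
  speed setting for 448-bin maps) are exposed.
- **Loops / TADs overlap** — features are called in each map and the score
  is 1 − matched/max(|A|, |B|). Matching is greedy by increasing distance
  (Chebyshev for loops, absolute for boundaries, radius 5), deterministic
  via a global sort with ties broken by lower index. The max denominator is
  monotone in unmatched features and agrees with the 3-vs-2, 2-matched →
  two-thirds reference behavior. When neither map yields a feature the score
  is undefined rather than zero — there is no evidence either way. Loop
  calling evaluates its ratio filters on exp(values): log(O/E) matrices
  contain non-positive entries that break mean-ratio thresholds, and
  exponentiation restores the positive O/E scale while leaving the calls
  invariant to additive shifts in log space. Defaults: p = 2, width = 5,
  all ratio thresholds 1.1, merge radius 5; candidate pixels must lie more
  than `width` off the diagonal and the donut excludes the pixel's own row
  and column. Boundary calling takes insulation minima (window 5, non-strict
  comparison so plateau minima are kept) with prominence — min(left-flank
  max, right-flank max) − minimum — at least 0.2, merging calls within 5
  bins keeping the strongest.

## Normalization

Similarity scores are aligned as 1 − x (an involution on [0, 1]). Min-max
normalization is applied per method across a collection of pairs; it
preserves ranking exactly, so ROC-AUC is invariant under it. A column with
no spread maps to all-0 ("no change observed" is the natural end of the
scale). Reference scaling divides scores by the mean score of a reference
set (e.g. many small neutral edits), so a value of 2 reads as "twice the
average reference disruption"; it is applied before min-max when both are
requested.

## Simulator

The generator replaces model-predicted canvases with an explicit parametric
model, because the alternative would require trained network weights and
would not be controllable feature by feature:

- **Canvas** — symmetric iid Gaussian field, Gaussian-smoothed (σ = 1 bin)
  and rescaled so the realized cell s.d. equals `background_sd`
  (default 0.02, a realistic noise floor for deeply sequenced log(O/E)
  maps; without the rescale, smoothing would shrink the documented s.d.
  about fourfold).
- **Domain structure** — between consecutive boundary bins, a uniform TAD
  block of +0.8; at each boundary, −0.6 depletion blocks of side 5 bins
  crossing the diagonal (five bins matches the TAD caller's diamond window,
  the width of the insulation dip a real boundary produces); at each TAD's
  far corner, a +0.5 Gaussian loop bump (σ = 2 bins). Values re-clip to
  (−2, 2). The amplitudes are fixed defaults chosen so that the structures
  are unambiguous to the feature callers while remaining within the clipped
  log(O/E) range; all are exposed as parameters.
- **Perturbations** — noise (mirrored-upper-triangle Gaussian field, so the
  per-cell s.d. equals the nominal σ exactly; range 0–0.2), resolution
  (block-average by k = round(new/old), remainder bins averaged into the
  last block, then each coarse value repeated k× so pairs keep a common
  shape — the global mean is conserved exactly on divisible sides; range
  2,048–50,972 bp), contrast (×c, c ∈ [1, 2]), intensity (+a, a ∈ [0, 0.2]),
  size (bilinear zoom about the origin cropped back to N×N, f ∈ [1, 1.1]),
  substructure ((1−m)·map + m·variant with an extra central boundary,
  m ∈ [0, 1]). Every operator is an exact identity at its null parameter,
  and sweeps space the parameter linearly over the range in 100 degrees by
  default.
- **Benchmark** — each draw places three boundary elements uniformly in the
  central 60% of a fresh canvas (sorted, minimum separation 5 bins to avoid
  degenerate merges) with TAD blocks between consecutive boundaries. The
  positive partner is the same construction with the middle element removed
  (losing a boundary, or weakening one when two elements are adjacent); the
  negative partner degrades the neutral map technically, with noise
  σ ~ U(0.01, 0.1) or resolution coarsened to a bin size ~ U(2,500, 25,000)
  bp and re-expanded. The default set is 100 positive plus 100 negative
  pairs, fully determined by one seed. At the lower end of the resolution
  range the rounded factor is 1 and the negative pair is identical — that
  is faithful to the stated range, and such pairs are simply easy negatives.
- **Screen planner** — a manifest of 7,500 planned pairs per perturbation
  category (insertion, deletion, random-deletion; 22,500 records total) with
  per-record seeds. Sequence-level editing and map prediction are outside
  this package's scope; the manifest enumerates and seeds the workload.

## Evaluation

ROC-AUC uses the Mann–Whitney rank formulation (exact and tie-safe; ties
count one half) rather than trapezoidal curve integration. PR-AUC is
step-wise average precision with tied scores processed as one block.
Undefined scores are excluded pairwise, never imputed. Method agreement is
summarized by pairwise Pearson correlation over jointly defined rows and by
the overlap of top-k score sets (k = ⌈frac·n⌉, stable tie-break by index).
Both AUC implementations are checked in the test suite against exhaustive
small-sample enumeration and against scikit-learn.

## What the simulator does and does not show

Synthetic maps have uniform TAD blocks, stationary Gaussian backgrounds and
exactly planted features, so a method's behavior on them bounds its
sensitivity under ideal conditions: passing the benchmark shows a score can
separate clean structural change from clean technical change. Real maps add
distance decay not fully removed by O/E, compartment-scale checkerboards,
sparsity at long range, mappability artifacts and correlated (non-iid)
noise; relative method rankings on real data can therefore differ,
especially for scores sensitive to long-range strata. The benchmark's
positives are all boundary-removal events and favor methods attuned to
TAD-scale change.

## Numerical choices and degenerate inputs

Scores return an explicit undefined status (not 0, not NaN arithmetic)
whenever the statistic does not exist: constant inputs under correlation,
zero dynamic range under SSIM, no admissible stratum under SCC, fully masked
pairs, or no features in either map. Spearman correlations of exactly
monotone transforms are exactly 1, so contrast/intensity perturbations give
correlation disruptions of exactly 0. Benchmark and sweep seeds derive from
a single `numpy` SeedSequence, keeping every run bit-reproducible; all
derived seeds stay below 2³¹.

## Problem sizes

The default map side is 448 bins at 2,048 bp. The test suite exercises the
full pipeline at 32–160 bins (where every score is fast and brute-force
oracles are feasible) and the benchmark and sweeps at the full 448-bin
geometry; the acceptance script runs the complete 100+100-pair benchmark at
448 bins in a few seconds.
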