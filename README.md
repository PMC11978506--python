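# contactdiff

Disruption scores, a perturbation simulator, and a benchmark harness for
pairs of chromatin contact maps.

## The problem

Hi-C and Micro-C experiments summarize the 3D folding of a genomic region as
a square contact matrix: entry (i, j) is the (distance-normalized,
log-transformed) contact frequency between bins i and j. Comparing two such
maps — mutant vs wild type, one cell type vs another, prediction vs
experiment — requires collapsing two matrices into a single "how different"
number, and different statistics prioritize very different kinds of change: a
correlation ignores a global intensity shift that dominates a mean squared
error, while a boundary-aware score ignores noise that saturates both.

`contactdiff` implements a panel of such disruption scores behind one
interface, plus a parametric simulator that manufactures TAD-structured maps
with controlled, labeled perturbations so that the sensitivity and
discrimination performance of every score can be quantified.

## What is implemented

**Global scores** (operate on the matrices directly; higher aligned score =
more different):

- `mse` — mean squared error, MSE(A, B) = mean((a_ij − b_ij)²)
- `correlation` — 1 − ρ, Spearman by default (Pearson optional)
- `ssim` — 1 − SSIM with Gaussian-weighted 7-bin local windows
- `scc` — 1 − SCC, the stratum-adjusted correlation: per-diagonal Pearson
  correlations ρ_k combined with weights w_k = N_k·sd(a_k)·sd(b_k)

**Track scores** reduce each map to a 1D track and compare the tracks with
1 − Spearman (`*_corr`) or MSE (`*_mse`):

- insulation (diamond-window mean, window 10 bins)
- contact directionality (signed upstream/downstream contrast, 10-kb window)
- eigenvector (leading eigenvector of the row-correlation matrix)
- distance enrichment (contact-decay profile, one value per diagonal)

**Triangle** compares mean contact over diagonal-anchored submatrices at a
dyadic ladder of scales.

**Feature scores** call loops (donut-style ratio filters: p=2, width=5,
thresholds 1.1) or TAD boundaries (insulation minima, window 5, prominence
0.2) in each map and report one minus the overlap ratio
matched / max(|A|, |B|).

**Normalization**: direction alignment (similarity scores become 1 − x),
per-method min-max normalization across a collection, and reference-set
scaling (score / mean of a reference disruption set).

**Simulator**: structureless log(O/E) canvases, TAD blocks with boundary
depletion stripes and corner loops, and six graded perturbations — noise
(σ ∈ [0, 0.2]), resolution (2,048 → 50,972 bp), contrast (×[1, 2]),
intensity (+[0, 0.2]), size (zoom [1, 1.1]), substructure (blend [0, 1]) —
plus labeled positive/negative benchmark pairs and an in silico screen
planner.

**Evaluation**: Mann–Whitney ROC-AUC, average-precision PR-AUC, pairwise
method-correlation matrices, and top-fraction overlap between rankings.

## Worked example

```python
import numpy as np
from contactdiff import (add_tad, make_canvas, make_pair, mse_score,
                         correlation_score, call_boundaries, perturb_intensity)

base = add_tad(make_canvas(n_bins=448, seed=1))     # one TAD, bins 112..336
brighter = perturb_intensity(base, 0.15)            # +0.15 on every cell

pair = make_pair(base, brighter)
print(round(mse_score(pair).aligned, 4))            # 0.0225
print(round(correlation_score(pair).aligned, 4))    # 0.0
print(call_boundaries(base).boundaries)             # [111, 335]
```

The intensity shift produces an MSE of exactly 0.15² = 0.0225 but a
correlation disruption of 0 — the two global scores disagree by design, which
is precisely the trade-off the package lets you measure. The boundary caller
recovers the two TAD boundaries planted at one- and three-quarters of the
448-bin map (bins 112 and 336, localized to within one bin).

A full benchmark from the shell:

```sh
contactdiff benchmark --methods all --negative-kind resolution --n 100 --seed 1 --out results.csv
```

writes per-method ROC-AUC and PR-AUC for 100 positive (middle TAD boundary
removed) versus 100 negative (resolution-degraded) map pairs.

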