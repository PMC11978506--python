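"""Loop and TAD-boundary calling, feature matching and the overlap-ratio score.

Loops are called with a donut-style local-enrichment filter: a candidate
pixel passes when the mean of its center block exceeds, by a ratio threshold,
the means of a surrounding donut, a lower-left block, and horizontal and
vertical flanking strips. Ratio filters run on exp(values) — log(O/E) maps
contain non-positive entries that would break mean-ratio thresholds, and
exponentiation restores the positive O/E scale. Boundaries are insulation
minima exceeding a prominence threshold. A pair of feature sets is scored by
the overlap ratio matched / max(|A|, |B|); the disruption score is one minus
that ratio.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np

from .core import ContactMap
from .global_scores import ScoreRecord
from .tracks import insulation_track

__all__ = ["FeatureSet", "call_loops", "call_boundaries", "match_features", "overlap_score"]


@dataclasses.dataclass
class FeatureSet:
    """Called loops (bin pairs, j > i) or boundaries (bins) plus calling params."""

    kind: str  # "loop" | "boundary"
    loops: List[Tuple[int, int]] = dataclasses.field(default_factory=list)
    boundaries: List[int] = dataclasses.field(default_factory=list)
    params: dict = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loops) if self.kind == "loop" else len(self.boundaries)

    @property
    def items(self) -> list:
        return self.loops if self.kind == "loop" else self.boundaries


def _integral(arr: np.ndarray) -> np.ndarray:
    out = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    out[1:, 1:] = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    return out


def _rect_sum(tab, r0, r1, c0, c1):
    """Inclusive-bounds rectangle sums from an integral image (vectorized)."""
    return tab[r1 + 1, c1 + 1] - tab[r0, c1 + 1] - tab[r1 + 1, c0] + tab[r0, c0]


def call_loops(cmap: ContactMap, p: int = 2, width: int = 5, ther: float = 1.1,
               ther_h: float = 1.1, ther_v: float = 1.1, radius: int = 5) -> FeatureSet:
    """Donut-filter loop calling.

    ``p`` sets the half-width of the center peak block, ``width`` the outer
    half-width of the donut and flank filters, the ``ther*`` parameters the
    center-to-filter mean-ratio thresholds, and ``radius`` the maximum
    Chebyshev distance for two passing pixels to merge into one loop (the
    merged loop sits at the cluster's maximum-center pixel).
    """
    n = cmap.n_bins
    if n <= 2 * width:
        return FeatureSet(kind="loop", params=dict(p=p, width=width, ther=ther,
                                                   ther_H=ther_h, ther_V=ther_v, radius=radius))
    evals = np.where(cmap.mask, 0.0, np.exp(cmap.values))
    valid = (~cmap.mask).astype(float)
    sv = _integral(evals)
    sc = _integral(valid)

    # candidates: far enough from edges and more than `width` off the diagonal
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cand = (jj - ii > width) & (ii >= width) & (ii + width < n) & (jj >= width) & (jj + width < n)
    ci, cj = np.where(cand)
    if ci.size == 0:
        return FeatureSet(kind="loop", params=dict(p=p, width=width, ther=ther,
                                                   ther_H=ther_h, ther_V=ther_v, radius=radius))

    def region(r0, r1, c0, c1):
        return _rect_sum(sv, r0, r1, c0, c1), _rect_sum(sc, r0, r1, c0, c1)

    # center block (2p+1)^2
    cen_s, cen_c = region(ci - p, ci + p, cj - p, cj + p)
    # full (2*width+1)^2 box and inner box -> donut ring, then drop the
    # pixel's row and column segments that fall inside the ring
    full_s, full_c = region(ci - width, ci + width, cj - width, cj + width)
    row_s, row_c = region(ci, ci, cj - width, cj + width)
    row_in_s, row_in_c = region(ci, ci, cj - p, cj + p)
    col_s, col_c = region(ci - width, ci + width, cj, cj)
    col_in_s, col_in_c = region(ci - p, ci + p, cj, cj)
    don_s = full_s - cen_s - (row_s - row_in_s) - (col_s - col_in_s)
    don_c = full_c - cen_c - (row_c - row_in_c) - (col_c - col_in_c)
    # lower-left block: rows (i, i+width] x cols [j-width, j)
    ll_s, ll_c = region(ci + 1, ci + width, cj - width, cj - 1)
    # horizontal: rows [i-p, i+p] x cols at distance (p, width] each side
    hl_s, hl_c = region(ci - p, ci + p, cj - width, cj - p - 1)
    hr_s, hr_c = region(ci - p, ci + p, cj + p + 1, cj + width)
    # vertical: cols [j-p, j+p] x rows at distance (p, width] each side
    vt_s, vt_c = region(ci - width, ci - p - 1, cj - p, cj + p)
    vb_s, vb_c = region(ci + p + 1, ci + width, cj - p, cj + p)

    def mean(s, c):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(c > 0, s / np.maximum(c, 1e-300), np.nan)

    center = mean(cen_s, cen_c)
    donut = mean(don_s, don_c)
    lower_left = mean(ll_s, ll_c)
    horiz = mean(hl_s + hr_s, hl_c + hr_c)
    vert = mean(vt_s + vb_s, vt_c + vb_c)

    with np.errstate(invalid="ignore", divide="ignore"):
        passing = (
            np.isfinite(center) & np.isfinite(donut) & np.isfinite(lower_left)
            & np.isfinite(horiz) & np.isfinite(vert)
            & (center / donut > ther) & (center / lower_left > ther)
            & (center / horiz > ther_h) & (center / vert > ther_v)
        )
    peak = evals[ci[passing], cj[passing]]
    pix = list(zip(ci[passing], cj[passing], peak, center[passing]))
    loops = _cluster_pixels(pix, radius)
    return FeatureSet(kind="loop", loops=loops,
                      params=dict(p=p, width=width, ther=ther, ther_H=ther_h,
                                  ther_V=ther_v, radius=radius))


def _cluster_pixels(pix, radius: int) -> List[Tuple[int, int]]:
    """Single-linkage clustering at Chebyshev distance <= radius; one loop per
    cluster, placed at its brightest pixel (ties: highest center mean, then
    lowest (i, j))."""
    if not pix:
        return []
    m = len(pix)
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(m):
        ia, ja = pix[a][0], pix[a][1]
        for b in range(a + 1, m):
            ib, jb = pix[b][0], pix[b][1]
            if max(abs(ia - ib), abs(ja - jb)) <= radius:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    clusters: dict = {}
    for a in range(m):
        clusters.setdefault(find(a), []).append(pix[a])
    loops = []
    for members in clusters.values():
        best = max(members, key=lambda t: (t[2], t[3], -t[0], -t[1]))
        loops.append((int(best[0]), int(best[1])))
    return sorted(loops)


def call_boundaries(cmap: ContactMap, window: int = 5, ther: float = 0.2,
                    radius: int = 5) -> FeatureSet:
    """Insulation-minimum TAD-boundary calling.

    Local minima of the insulation track (diamond window of ``window`` bins)
    are kept when their prominence — min(max of the left flank, max of the
    right flank) − minimum value, flanks of ``window`` bins — reaches ``ther``;
    called boundaries within ``radius`` bins merge, keeping the strongest.
    """
    track = insulation_track(cmap, window=window)
    v, d = track.values, track.defined
    n = len(v)
    candidates = []
    for i in range(1, n - 1):
        if not (d[i] and d[i - 1] and d[i + 1]):
            continue
        # non-strict comparison keeps plateau minima (ties resolved by the
        # radius merge below, strongest/lowest index first)
        if v[i] <= v[i - 1] and v[i] <= v[i + 1]:
            lo = max(0, i - window)
            hi = min(n, i + window + 1)
            left = v[lo:i][d[lo:i]]
            right = v[i + 1:hi][d[i + 1:hi]]
            if left.size == 0 or right.size == 0:
                continue
            strength = min(left.max(), right.max()) - v[i]
            if strength >= ther:
                candidates.append((i, strength))
    # greedy non-maximum suppression within `radius`
    candidates.sort(key=lambda t: (-t[1], t[0]))
    kept: List[int] = []
    for i, _ in candidates:
        if all(abs(i - k) > radius for k in kept):
            kept.append(i)
    return FeatureSet(kind="boundary", boundaries=sorted(kept),
                      params=dict(window=window, ther=ther, radius=radius))


def _distance(kind: str, x, y) -> float:
    if kind == "loop":
        return max(abs(x[0] - y[0]), abs(x[1] - y[1]))
    return abs(x - y)


def match_features(fa: FeatureSet, fb: FeatureSet, radius: int = 5) -> int:
    """Greedy one-to-one matching by increasing distance; pairs within
    ``radius`` (Chebyshev for loops, absolute for boundaries) count."""
    if fa.kind != fb.kind:
        raise TypeError(f"cannot match {fa.kind} features with {fb.kind} features")
    pairs = []
    for ia, a in enumerate(fa.items):
        for ib, b in enumerate(fb.items):
            dist = _distance(fa.kind, a, b)
            if dist <= radius:
                pairs.append((dist, ia, ib))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    matched = 0
    for _, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        matched += 1
    return matched


def overlap_score(fa: FeatureSet, fb: FeatureSet, radius: int = 5) -> ScoreRecord:
    """Disruption = 1 − matched / max(|fa|, |fb|).

    Undefined when neither map yields any feature (no evidence either way).
    """
    if fa.kind != fb.kind:
        raise TypeError(f"cannot score {fa.kind} features against {fb.kind} features")
    method_id = "loops" if fa.kind == "loop" else "tads"
    if len(fa) == 0 and len(fb) == 0:
        return ScoreRecord.undefined(method_id)
    matched = match_features(fa, fb, radius=radius)
    ratio = matched / max(len(fa), len(fb))
    return ScoreRecord(method_id=method_id, raw=ratio, aligned=1.0 - ratio)
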