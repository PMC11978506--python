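"""Triangle: multi-scale submatrix-average comparison.

The map is summarized by the mean contact of diagonal-anchored square
submatrices at a dyadic ladder of scales (s, 2s, 4s, ... up to N), each slid
along the diagonal. Comparing the two profiles captures differences in
substructure from fine (small s) to coarse (large s). An optional block-average
downsampling speeds up large inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .core import ContactMap, MapPair, make_pair
from .global_scores import ScoreRecord

__all__ = ["TriangleProfile", "triangle_profile", "triangle_score"]


@dataclasses.dataclass
class TriangleProfile:
    """Submatrix means ordered by (scale, start)."""

    scales: np.ndarray     # scale (bins) per entry
    starts: np.ndarray     # start bin per entry
    means: np.ndarray      # mean over unmasked on/above-diagonal cells; NaN if none
    scale_set: tuple
    stride: int

    def __len__(self) -> int:
        return len(self.means)


def _block_average(cmap: ContactMap, factor: int) -> ContactMap:
    """Mask-aware block average; a coarse cell is masked iff its block is fully masked."""
    n = cmap.n_bins
    edges = np.arange(0, n, factor)
    vals = np.where(cmap.mask, 0.0, cmap.values)
    cnts = (~cmap.mask).astype(float)
    s = np.add.reduceat(np.add.reduceat(vals, edges, axis=0), edges, axis=1)
    c = np.add.reduceat(np.add.reduceat(cnts, edges, axis=0), edges, axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(c > 0, s / np.maximum(c, 1), 0.0)
    return ContactMap(values=out, bin_size=cmap.bin_size * factor,
                      chrom=cmap.chrom, start=cmap.start, mask=c == 0)


def triangle_profile(cmap: ContactMap, min_scale: int = 2, stride: int = 1,
                     downsample_factor: int = 1) -> TriangleProfile:
    """Profile of upper-triangle submatrix means at dyadic scales.

    Scales are {min_scale, 2*min_scale, 4*min_scale, ...} up to the map side;
    at each scale s the window [i, i+s) x [i, i+s) slides with the given
    stride and its mean over unmasked cells on or above the diagonal is
    recorded.
    """
    if downsample_factor > 1:
        cmap = _block_average(cmap, downsample_factor)
    n = cmap.n_bins
    scale_set = []
    s = min_scale
    while s <= n:
        scale_set.append(s)
        s *= 2
    if not scale_set:
        raise ValueError(f"min_scale {min_scale} exceeds map side {n}")
    vals = np.where(cmap.mask, 0.0, cmap.values)
    upper = ~cmap.mask & np.triu(np.ones((n, n), dtype=bool))
    # cumulative sums let each window mean be O(1)
    vsum = np.zeros((n + 1, n + 1))
    csum = np.zeros((n + 1, n + 1))
    vsum[1:, 1:] = np.cumsum(np.cumsum(np.where(upper, vals, 0.0), axis=0), axis=1)
    csum[1:, 1:] = np.cumsum(np.cumsum(upper.astype(float), axis=0), axis=1)

    def rect(tab, i0, i1, j0, j1):
        return tab[i1, j1] - tab[i0, j1] - tab[i1, j0] + tab[i0, j0]

    scales, starts, means = [], [], []
    for s in scale_set:
        for i in range(0, n - s + 1, stride):
            tot = rect(vsum, i, i + s, i, i + s)
            cnt = rect(csum, i, i + s, i, i + s)
            scales.append(s)
            starts.append(i)
            means.append(tot / cnt if cnt > 0 else np.nan)
    return TriangleProfile(scales=np.array(scales), starts=np.array(starts),
                           means=np.array(means, dtype=float),
                           scale_set=tuple(scale_set), stride=stride)


def triangle_score(pair: MapPair, stat: str = "corr", min_scale: int = 2,
                   stride: int = 1, downsample_factor: int = 1) -> ScoreRecord:
    """Compare the Triangle profiles of the two maps with corr (1 − Spearman) or mse."""
    if stat not in {"corr", "mse"}:
        raise ValueError(f"unknown stat {stat!r}")
    method_id = f"triangle_{stat}"
    pa = triangle_profile(pair.map_a, min_scale, stride, downsample_factor)
    pb = triangle_profile(pair.map_b, min_scale, stride, downsample_factor)
    sel = np.isfinite(pa.means) & np.isfinite(pb.means)
    a, b = pa.means[sel], pb.means[sel]
    if a.size == 0:
        return ScoreRecord.undefined(method_id, stat)
    if stat == "mse":
        raw = float(np.mean((a - b) ** 2))
        return ScoreRecord(method_id=method_id, variant="mse", raw=raw, aligned=raw)
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return ScoreRecord.undefined(method_id, "corr")
    raw = float(stats.spearmanr(a, b).statistic)
    if not np.isfinite(raw):
        return ScoreRecord.undefined(method_id, "corr")
    return ScoreRecord(method_id=method_id, variant="corr", raw=raw, aligned=1.0 - raw)
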