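"""1D track summaries of a contact map and their pairwise comparison.

Four track kinds reduce an N x N map to a length-N vector capturing a
specific folding feature:

* ``insulation`` — mean contact in a diamond window sliding along the
  diagonal; minima mark domain boundaries.
* ``directionality`` — signed chi-square-like contrast of a bin's upstream vs
  downstream contact sums (adapted from the directionality index).
* ``eigenvector`` — leading eigenvector of the row-correlation matrix
  (compartment-style block structure).
* ``decay`` — mean contact per genomic distance (contact-decay profile; one
  value per diagonal, so distal distances carry equal weight).

Tracks from two maps are collapsed to a disruption score with Correlation
(1 − Spearman) or MSE.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .core import ContactMap, DegenerateInputError
from .global_scores import ScoreRecord

__all__ = [
    "Track",
    "insulation_track",
    "directionality_track",
    "eigenvector_track",
    "distance_enrichment_track",
    "compare_tracks",
]


@dataclasses.dataclass
class Track:
    """Per-bin 1D summary of a map; ``defined`` is false at edges/undefined bins."""

    values: np.ndarray
    defined: np.ndarray
    kind: str
    bin_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape:
            raise ValueError("values and defined must have equal length")


def insulation_track(cmap: ContactMap, window: int = 10) -> Track:
    """Mean unmasked contact in the ``window`` x ``window`` diamond at each bin.

    The block for bin i spans rows [i-window, i) and columns (i, i+window];
    bins closer than ``window`` to an edge are undefined.
    """
    n = cmap.n_bins
    if n <= 2 * window:
        raise DegenerateInputError(f"need more than {2 * window} bins, got {n}")
    values = np.zeros(n)
    defined = np.zeros(n, dtype=bool)
    for i in range(window, n - window):
        block = cmap.values[i - window:i, i + 1:i + window + 1]
        ok = ~cmap.mask[i - window:i, i + 1:i + window + 1]
        if ok.any():
            values[i] = block[ok].mean()
            defined[i] = True
    return Track(values=values, defined=defined, kind="insulation", bin_size=cmap.bin_size)


def directionality_track(cmap: ContactMap, window_resolution: int = 10_000,
                         replace_ends: bool = True, buffer: int = 50) -> Track:
    """Signed up/downstream contact contrast per bin.

    For bin i with window w = round(window_resolution / bin_size) native bins,
    A is the unmasked sum of map[i, i-w..i-1], B of map[i, i+1..i+w], and with
    E = (A+B)/2 the value is sign(B−A) * ((A−E)^2/E + (B−E)^2/E), 0 when A = B
    or E = 0. ``replace_ends`` zeroes the first and last ``buffer`` track
    positions (bins), where partial windows make the statistic unstable.
    """
    w = round(window_resolution / cmap.bin_size)
    if w < 1:
        raise ValueError(
            f"window_resolution {window_resolution} is below one bin ({cmap.bin_size} bp)"
        )
    n = cmap.n_bins
    if n <= 2 * w:
        raise DegenerateInputError(f"need more than {2 * w} bins, got {n}")
    masked0 = np.where(cmap.mask, 0.0, cmap.values)
    values = np.zeros(n)
    for i in range(n):
        lo = max(0, i - w)
        hi = min(n, i + w + 1)
        a = masked0[i, lo:i].sum()
        b = masked0[i, i + 1:hi].sum()
        e = (a + b) / 2.0
        if a == b or e == 0:
            continue
        values[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    if replace_ends and buffer > 0:
        values[:buffer] = 0.0
        values[n - buffer:] = 0.0
    return Track(values=values, defined=np.ones(n, dtype=bool),
                 kind="directionality", bin_size=cmap.bin_size)


def eigenvector_track(cmap: ContactMap) -> Track:
    """Leading eigenvector of the map's row-correlation matrix.

    Row pairs are correlated excluding masked cells pairwise; rows with an
    undefined correlation (constant or too short) are dropped and marked
    undefined. The unit-norm eigenvector of the largest eigenvalue is sign-
    oriented so that its correlation with the per-bin row-mean track is >= 0.
    """
    n = cmap.n_bins
    if cmap.mask.any():
        ma = np.ma.masked_array(cmap.values, mask=cmap.mask)
        corr = np.ma.corrcoef(ma)
        corr = np.asarray(corr.filled(np.nan))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(cmap.values)
    valid = np.isfinite(corr).sum(axis=1) >= 3
    defined = valid.copy()
    values = np.zeros(n)
    if valid.sum() < 3:
        return Track(values=values, defined=np.zeros(n, dtype=bool),
                     kind="eigenvector", bin_size=cmap.bin_size)
    sub = corr[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, 0.0)
    sub = (sub + sub.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(sub)
    vec = eigvecs[:, -1]
    vec = vec / np.linalg.norm(vec)
    row_mean = np.array([
        cmap.values[i][~cmap.mask[i]].mean() if (~cmap.mask[i]).any() else 0.0
        for i in np.where(valid)[0]
    ])
    if np.ptp(row_mean) > 0 and np.ptp(vec) > 0:
        if np.corrcoef(vec, row_mean)[0, 1] < 0:
            vec = -vec
    elif vec.sum() < 0:
        vec = -vec
    values[valid] = vec
    return Track(values=values, defined=defined, kind="eigenvector", bin_size=cmap.bin_size)


def distance_enrichment_track(cmap: ContactMap) -> Track:
    """Contact-decay profile: mean unmasked value at each distance |i−j| = d."""
    n = cmap.n_bins
    values = np.zeros(n)
    defined = np.zeros(n, dtype=bool)
    for d in range(n):
        idx = np.arange(n - d)
        sel = ~cmap.mask[idx, idx + d]
        if sel.any():
            values[d] = cmap.values[idx, idx + d][sel].mean()
            defined[d] = True
    return Track(values=values, defined=defined, kind="decay", bin_size=cmap.bin_size)


def compare_tracks(t1: Track, t2: Track, stat: str = "corr") -> ScoreRecord:
    """Collapse two same-kind tracks to a disruption score.

    Restricted to jointly defined positions. Eigenvector tracks are sign-
    aligned first (flip t2 when the Pearson correlation of the pair is
    negative) since the eigenvector sign is arbitrary. ``corr`` gives
    1 − Spearman, ``mse`` the mean squared difference.
    """
    if stat not in {"corr", "mse"}:
        raise ValueError(f"unknown stat {stat!r}")
    if t1.kind != t2.kind:
        raise TypeError(f"cannot compare {t1.kind} with {t2.kind} tracks")
    if t1.values.shape != t2.values.shape:
        raise ValueError("track lengths differ")
    method_id = f"{t1.kind}_{stat}"
    joint = t1.defined & t2.defined
    a = t1.values[joint]
    b = t2.values[joint]
    if a.size == 0:
        return ScoreRecord.undefined(method_id, stat)
    if t1.kind == "eigenvector" and a.size >= 2 and np.ptp(a) > 0 and np.ptp(b) > 0:
        if np.corrcoef(a, b)[0, 1] < 0:
            b = -b
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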