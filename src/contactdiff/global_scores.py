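"""Matrix-level disruption scores: MSE, Correlation, SSIM and SCC.

Every score is reported as a :class:`ScoreRecord` whose ``aligned`` value is
direction-aligned so that higher always means "more different": MSE-type
scores are already differences, similarity scores are mapped ``x -> 1 - x``.
Masked cells never contribute. Correlation/MSE are evaluated over the upper
triangle (including the diagonal) so that symmetric cells are not counted
twice.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .core import MapPair

__all__ = ["ScoreRecord", "mse_score", "correlation_score", "ssim_score", "scc_score"]


@dataclasses.dataclass
class ScoreRecord:
    """One method's score on one map pair.

    ``raw`` is the method's native statistic, ``aligned`` the disruption score
    (higher = more different), ``normalized`` an optional [0,1] rescaling filled
    in by :func:`contactdiff.normalize.minmax_normalize`. ``status`` is
    ``"undefined"`` when the statistic does not exist on the input (constant
    maps, empty masks, no detected features) — then raw/aligned are ``None``.
    """

    method_id: str
    variant: str = "none"
    raw: Optional[float] = None
    aligned: Optional[float] = None
    normalized: Optional[float] = None
    status: str = "ok"

    @classmethod
    def undefined(cls, method_id: str, variant: str = "none") -> "ScoreRecord":
        return cls(method_id=method_id, variant=variant, status="undefined")

    @property
    def defined(self) -> bool:
        return self.status == "ok"


def _upper_values(pair: MapPair) -> tuple[np.ndarray, np.ndarray]:
    """Unmasked upper-triangle (incl. diagonal) values of both maps."""
    n = pair.n_bins
    sel = np.triu(np.ones((n, n), dtype=bool)) & ~pair.shared_mask
    return pair.map_a.values[sel], pair.map_b.values[sel]


def mse_score(pair: MapPair) -> ScoreRecord:
    """Mean squared error between the two maps over unmasked cells."""
    a, b = _upper_values(pair)
    if a.size == 0:
        return ScoreRecord.undefined("mse", "mse")
    raw = float(np.mean((a - b) ** 2))
    return ScoreRecord(method_id="mse", variant="mse", raw=raw, aligned=raw)


def correlation_score(pair: MapPair, coefficient: str = "spearman") -> ScoreRecord:
    """1 − correlation between map values (Spearman by default, Pearson optional)."""
    if coefficient not in {"spearman", "pearson"}:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    a, b = _upper_values(pair)
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return ScoreRecord.undefined("correlation", "corr")
    if coefficient == "spearman":
        raw = float(stats.spearmanr(a, b).statistic)
    else:
        raw = float(stats.pearsonr(a, b).statistic)
    if not np.isfinite(raw):
        return ScoreRecord.undefined("correlation", "corr")
    return ScoreRecord(method_id="correlation", variant="corr", raw=raw, aligned=1.0 - raw)


def ssim_score(pair: MapPair, window: int = 7, k1: float = 0.01, k2: float = 0.03) -> ScoreRecord:
    """1 − mean structural similarity (Gaussian-weighted local windows).

    The dynamic range is the joint max − min of both maps' unmasked values.
    Masked cells are filled with each map's unmasked mean before windowing and
    the local SSIM image is averaged over unmasked cells only.
    """
    if pair.n_bins < window:
        raise ValueError(f"map side {pair.n_bins} smaller than SSIM window {window}")
    ok = ~pair.shared_mask
    if not ok.any():
        return ScoreRecord.undefined("ssim")
    va, vb = pair.map_a.values, pair.map_b.values
    joint = np.concatenate([va[ok], vb[ok]])
    data_range = float(joint.max() - joint.min())
    if data_range == 0:
        return ScoreRecord.undefined("ssim")
    if pair.shared_mask.any():
        va = np.where(ok, va, va[ok].mean())
        vb = np.where(ok, vb, vb[ok].mean())
    _, ssim_image = structural_similarity(
        va, vb, win_size=window, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False,
        K1=k1, K2=k2, data_range=data_range, full=True,
    )
    raw = float(ssim_image[ok].mean())
    return ScoreRecord(method_id="ssim", raw=raw, aligned=1.0 - raw)


def scc_score(pair: MapPair, max_distance_bins: Optional[int] = None) -> ScoreRecord:
    """1 − stratum-adjusted correlation coefficient.

    Cells are stratified by genomic distance |i−j| = k. Each stratum with at
    least 3 unmasked cells and nonzero variance in both maps contributes its
    Pearson correlation rho_k with weight N_k * sd(a_k) * sd(b_k); SCC is the
    weighted mean of the rho_k.
    """
    n = pair.n_bins
    kmax = n - 1 if max_distance_bins is None else min(max_distance_bins, n - 1)
    va, vb = pair.map_a.values, pair.map_b.values
    ok = ~pair.shared_mask
    num = 0.0
    den = 0.0
    used = 0
    for k in range(kmax + 1):
        idx = np.arange(n - k)
        sel = ok[idx, idx + k]
        a = va[idx, idx + k][sel]
        b = vb[idx, idx + k][sel]
        if a.size < 3:
            continue
        sda = a.std()
        sdb = b.std()
        if sda == 0 or sdb == 0:
            continue
        rho = float(np.corrcoef(a, b)[0, 1])
        w = a.size * sda * sdb
        num += w * rho
        den += w
        used += 1
    if used == 0 or den == 0:
        return ScoreRecord.undefined("scc")
    raw = num / den
    return ScoreRecord(method_id="scc", raw=raw, aligned=1.0 - raw)
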