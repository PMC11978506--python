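"""Benchmark scoring, ROC/PR evaluation and inter-method agreement summaries."""

from __future__ import annotations

import dataclasses
import warnings
from math import ceil
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import make_pair
from .features import call_boundaries, call_loops, overlap_score
from .global_scores import ScoreRecord, correlation_score, mse_score, scc_score, ssim_score
from .normalize import ScoreTable, minmax_normalize
from .simulator import BenchmarkPair
from .tracks import (
    compare_tracks,
    directionality_track,
    distance_enrichment_track,
    eigenvector_track,
    insulation_track,
)
from .triangle import triangle_score

__all__ = [
    "LabeledScores", "METHODS", "score_pair", "score_benchmark",
    "roc_auc", "pr_auc", "method_correlation_matrix", "top_fraction_overlap",
]


def _track_method(track_fn, stat) -> Callable:
    def run(pair) -> ScoreRecord:
        return compare_tracks(track_fn(pair.map_a), track_fn(pair.map_b), stat=stat)
    return run


def _overlap_method(caller) -> Callable:
    def run(pair) -> ScoreRecord:
        return overlap_score(caller(pair.map_a), caller(pair.map_b))
    return run


#: the scoring methods applicable to locus-specific (matrix-input) map pairs
METHODS: Dict[str, Callable] = {
    "mse": mse_score,
    "correlation": correlation_score,
    "ssim": ssim_score,
    "scc": scc_score,
    "insulation_corr": _track_method(insulation_track, "corr"),
    "insulation_mse": _track_method(insulation_track, "mse"),
    "directionality_corr": _track_method(directionality_track, "corr"),
    "directionality_mse": _track_method(directionality_track, "mse"),
    "eigenvector_corr": _track_method(eigenvector_track, "corr"),
    "decay_corr": _track_method(distance_enrichment_track, "corr"),
    "triangle_corr": lambda pair: triangle_score(pair, stat="corr"),
    "triangle_mse": lambda pair: triangle_score(pair, stat="mse"),
    "tads": _overlap_method(call_boundaries),
    "loops": _overlap_method(call_loops),
}

#: default benchmark panel: the 12 numeric methods (count-based callers opt-in)
DEFAULT_METHODS = [
    "mse", "correlation", "ssim", "scc",
    "insulation_corr", "insulation_mse",
    "directionality_corr", "directionality_mse",
    "eigenvector_corr", "decay_corr",
    "triangle_corr", "triangle_mse",
]


@dataclasses.dataclass
class LabeledScores:
    """Aligned disruption scores with 0/1 labels for one method."""

    labels: np.ndarray
    scores: np.ndarray
    method_id: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must have equal length")

    def defined(self) -> "LabeledScores":
        sel = np.isfinite(self.scores)
        return LabeledScores(self.labels[sel], self.scores[sel], self.method_id)


def score_pair(pair, methods: Optional[Sequence[str]] = None) -> Dict[str, ScoreRecord]:
    """Apply each named method to one MapPair."""
    out = {}
    for name in methods or DEFAULT_METHODS:
        try:
            fn = METHODS[name]
        except KeyError:
            raise KeyError(f"unknown method {name!r}") from None
        out[name] = fn(pair)
    return out


def score_benchmark(pairs: List[BenchmarkPair], methods: Optional[Sequence[str]] = None,
                    ) -> tuple[ScoreTable, Dict[str, LabeledScores]]:
    """Score every benchmark pair with every method and min-max normalize.

    Returns the normalized :class:`ScoreTable` plus per-method
    :class:`LabeledScores` (undefined records dropped). Methods with no
    defined score on any pair are dropped with a warning.
    """
    records = {}
    labels = []
    for idx, bp in enumerate(pairs):
        pair = make_pair(bp.map_a, bp.map_b)
        records[f"pair{idx:04d}"] = score_pair(pair, methods)
        labels.append(1 if bp.label == "positive" else 0)
    table = ScoreTable.from_records(records)
    labels = np.asarray(labels)
    drop = [c for c in table.aligned.columns if table.aligned[c].notna().sum() == 0]
    if drop:
        warnings.warn(f"methods with no defined scores dropped: {drop}", stacklevel=2)
        table.aligned = table.aligned.drop(columns=drop)
        table.raw = table.raw.drop(columns=drop)
    minmax_normalize(table)
    labeled = {}
    for col in table.normalized.columns:
        ls = LabeledScores(labels, table.normalized[col].to_numpy(), col).defined()
        labeled[col] = ls
    return table, labeled


def roc_auc(ls: LabeledScores) -> float:
    """ROC AUC as the Mann–Whitney probability that a random positive
    outscores a random negative; ties count one half."""
    ls = ls.defined()
    pos = ls.labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one score from each class")
    ranks = rankdata(ls.scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(ls: LabeledScores) -> float:
    """Average precision: sum over descending-score cutoffs of precision times
    recall increment; tied scores enter as one block."""
    ls = ls.defined()
    n_pos = int((ls.labels == 1).sum())
    if ls.labels.size == 0:
        raise ValueError("empty input")
    if n_pos == 0:
        raise ValueError("need at least one positive")
    order = np.argsort(-ls.scores, kind="stable")
    scores = ls.scores[order]
    labels = ls.labels[order]
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        block_tp = int(labels[i:j].sum())
        tp += block_tp
        seen += j - i
        if block_tp:
            precision = tp / seen
            ap += precision * (block_tp / n_pos)
        i = j
    return float(ap)


def method_correlation_matrix(table) -> pd.DataFrame:
    """Pairwise Pearson correlation between method score vectors.

    Rows where either method is undefined are excluded pairwise; the diagonal
    is 1.
    """
    df = table.aligned if isinstance(table, ScoreTable) else table
    corr = df.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def top_fraction_overlap(a: Sequence[float], b: Sequence[float], frac: float = 0.05) -> float:
    """Fraction of the top-``frac`` scorers shared between two methods.

    k = ceil(frac * n); the top-k sets are chosen by descending score with
    ties broken by stable index order.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    k = ceil(frac * len(a))
    top_a = set(np.argsort(-a, kind="stable")[:k])
    top_b = set(np.argsort(-b, kind="stable")[:k])
    return len(top_a & top_b) / k
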