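"""Score direction alignment, min-max normalization and reference scaling.

Methods report statistics on different native scales and directions
(correlations: high = similar; MSE: high = different). To compare methods,
similarity-type raw scores are first aligned as ``1 - x`` so that higher
always means more disrupted; aligned scores are then min-max normalized per
method across a collection of map pairs; optionally, scores are first divided
by the mean of a reference score set (e.g. the disruption caused by small
neutral edits) so that "2" means twice the reference disruption.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScoreTable", "METHOD_DIRECTIONS", "align_direction", "minmax_normalize",
           "reference_scale"]

#: direction of each method's *raw* statistic: "similarity" scores are mapped
#: x -> 1 - x during alignment, "difference" scores pass through.
METHOD_DIRECTIONS: Dict[str, str] = {
    "mse": "difference",
    "correlation": "similarity",
    "spearman": "similarity",
    "pearson": "similarity",
    "ssim": "similarity",
    "scc": "similarity",
    "insulation_corr": "similarity",
    "insulation_mse": "difference",
    "directionality_corr": "similarity",
    "directionality_mse": "difference",
    "eigenvector_corr": "similarity",
    "eigenvector_mse": "difference",
    "decay_corr": "similarity",
    "decay_mse": "difference",
    "triangle_corr": "similarity",
    "triangle_mse": "difference",
    "loops": "similarity",   # overlap ratio: 1 = identical feature sets
    "tads": "similarity",
}

#: note: the *_corr track methods store the raw Spearman coefficient, which is
#: a similarity; their ScoreRecord.aligned already carries 1 - r.


class ScoreTable:
    """Map-pair x method table of aligned scores (NaN = undefined record).

    Thin wrapper over a pandas DataFrame; ``raw`` holds raw statistics,
    ``aligned`` direction-aligned scores and ``normalized`` the min-max
    normalized scores once computed.
    """

    def __init__(self, aligned: pd.DataFrame, raw: pd.DataFrame | None = None):
        self.aligned = aligned
        self.raw = raw if raw is not None else aligned.copy()
        self.normalized: pd.DataFrame | None = None

    @classmethod
    def from_records(cls, records: Dict[str, Dict[str, "object"]]) -> "ScoreTable":
        """Build from {pair_id: {method_id: ScoreRecord}}."""
        raw = {}
        aligned = {}
        for pair_id, row in records.items():
            raw[pair_id] = {m: (r.raw if r.defined else np.nan) for m, r in row.items()}
            aligned[pair_id] = {m: (r.aligned if r.defined else np.nan) for m, r in row.items()}
        return cls(aligned=pd.DataFrame(aligned).T, raw=pd.DataFrame(raw).T)


def align_direction(method_id: str, raw: float) -> float:
    """Map a raw statistic to a disruption score (higher = more different)."""
    try:
        direction = METHOD_DIRECTIONS[method_id]
    except KeyError:
        raise KeyError(f"method {method_id!r} has no registered direction") from None
    return 1.0 - raw if direction == "similarity" else raw


def minmax_normalize(table) -> "ScoreTable | pd.DataFrame":
    """Per-method min-max normalization over defined cells.

    Accepts a :class:`ScoreTable` or a plain DataFrame of aligned scores.
    Constant columns map to all-0 (no spread observed = "no change" end);
    all-NaN columns are skipped with a warning. Undefined cells stay NaN.
    """
    df = table.aligned if isinstance(table, ScoreTable) else table
    out = df.copy()
    for col in df.columns:
        x = df[col]
        if x.notna().sum() == 0:
            warnings.warn(f"column {col!r} has no defined scores; skipped", stacklevel=2)
            continue
        lo, hi = x.min(), x.max()
        out[col] = 0.0 if hi == lo else (x - lo) / (hi - lo)
        out.loc[x.isna(), col] = np.nan
    if isinstance(table, ScoreTable):
        table.normalized = out
        return table
    return out


def reference_scale(scores: Sequence[float], reference_scores: Iterable[float]) -> np.ndarray:
    """Divide each score by the mean of a reference score set.

    A scaled score of 2 means twice the average disruption observed in the
    reference set (e.g. 100 neutral small-edit pairs).
    """
    ref = np.asarray(list(reference_scores), dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise ValueError("reference score set is empty")
    mean = ref.mean()
    if mean == 0 or not np.isfinite(mean):
        raise ValueError(f"reference mean is {mean}; cannot scale")
    return np.asarray(scores, dtype=float) / mean
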