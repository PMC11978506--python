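"""Contact-map data model, I/O, preprocessing and masking.

A contact map is a square symmetric matrix of log(observed/expected) contact
frequencies between genomic bins. Missing cells are carried as an explicit
boolean mask (true = missing) and never enter any mean, correlation or filter
downstream. Coordinates are 0-based; bin ``i`` covers the half-open genomic
interval ``[start + i*bin_size, start + (i+1)*bin_size)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ContactMap",
    "MapPair",
    "read_map",
    "write_map",
    "preprocess",
    "zero_fraction_filter",
    "make_pair",
]

#: clip bounds applied to log(O/E) values during preprocessing
CLIP_LOW = -2.0
CLIP_HIGH = 2.0


class DimensionError(ValueError):
    """Input matrix is not square or shapes are incompatible."""


class FormatError(ValueError):
    """Unknown or unreadable map file format."""


class DegenerateInputError(ValueError):
    """The operation is undefined on this input (e.g. fully masked map)."""


@dataclasses.dataclass
class ContactMap:
    """Square symmetric log(O/E) contact matrix with an explicit missing-cell mask.

    Parameters
    ----------
    values
        N x N float matrix. Entries under ``mask`` are ignored everywhere.
    bin_size
        Genomic width of one bin in base pairs.
    chrom, start
        Optional genomic anchor of bin 0 (0-based).
    mask
        N x N boolean, true where the cell is missing. Defaults to all-false.
    """

    values: np.ndarray
    bin_size: int = 2048
    chrom: Optional[str] = None
    start: Optional[int] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DimensionError(f"contact map must be square, got shape {self.values.shape}")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DimensionError("mask shape must match values shape")
        # non-finite cells are missing by definition
        bad = ~np.isfinite(self.values)
        if bad.any():
            self.mask = self.mask | bad | bad.T
            self.values = np.where(self.mask, 0.0, self.values)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def span_bp(self) -> int:
        """Genomic span covered by the map in base pairs (n_bins * bin_size)."""
        return self.n_bins * self.bin_size

    def copy(self) -> "ContactMap":
        return ContactMap(
            values=self.values.copy(),
            bin_size=self.bin_size,
            chrom=self.chrom,
            start=self.start,
            mask=self.mask.copy(),
        )

    def is_symmetric(self, tol: float = 1e-8) -> bool:
        ok = ~(self.mask | self.mask.T)
        return bool(np.all(np.abs(self.values - self.values.T)[ok] <= tol)) and bool(
            np.array_equal(self.mask, self.mask.T)
        )


@dataclasses.dataclass
class MapPair:
    """Two same-shape maps with the union of their masks applied to both."""

    map_a: ContactMap
    map_b: ContactMap
    shared_mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.map_a.n_bins

    @property
    def degenerate(self) -> bool:
        """True when no unmasked cell remains; all scores are then undefined."""
        return bool(self.shared_mask.all())


def _symmetrize(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mask symmetrized by union; values averaged where both (i,j),(j,i) present."""
    mask = mask | mask.T
    out = np.where(mask, 0.0, (values + values.T) / 2.0)
    return out, mask


def read_map(path, format: Optional[str] = None, bin_size: int = 2048,
             chrom: Optional[str] = None, start: Optional[int] = None) -> ContactMap:
    """Read a contact map from disk.

    Supported formats: ``dense-tsv`` (tab-separated text, ``nan`` marks missing
    cells) and ``binary-array`` (a single 2D float64 ``.npy`` array). The format
    is inferred from the extension when not given. Non-finite cells become
    masked, and near-symmetric inputs are symmetrized by averaging.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".tsv", ".txt", ".dat"}:
            format = "dense-tsv"
        elif suffix == ".npy":
            format = "binary-array"
        else:
            raise FormatError(f"cannot infer map format from extension {suffix!r}")
    if format == "dense-tsv":
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
    elif format == "binary-array":
        values = np.load(path)
    elif format == "cool-region":
        raise FormatError(
            "cool-region extraction requires the 'cooler' package, which is not "
            "available; export the region as dense-tsv or binary-array instead"
        )
    else:
        raise FormatError(f"unknown map format {format!r}")
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise DimensionError(f"map in {path} is not square: shape {values.shape}")
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    values, mask = _symmetrize(values, mask)
    return ContactMap(values=values, bin_size=bin_size, chrom=chrom, start=start, mask=mask)


def write_map(cmap: ContactMap, path, format: Optional[str] = None) -> None:
    """Write a map to disk; round-trips exactly for binary-array, to <=1e-9 for tsv."""
    path = Path(path)
    if format is None:
        format = "binary-array" if path.suffix.lower() == ".npy" else "dense-tsv"
    out = np.where(cmap.mask, np.nan, cmap.values)
    if format == "dense-tsv":
        np.savetxt(path, out, delimiter="\t", fmt="%.12g")
    elif format == "binary-array":
        np.save(path, out)
    else:
        raise FormatError(f"unknown map format {format!r}")


def _interpolate_1d(values: np.ndarray, missing: np.ndarray, axis: int) -> np.ndarray:
    """Linear interpolation along one axis; edge gaps take the nearest defined value."""
    arr = values.copy()
    if axis == 1:
        arr = arr.T
        missing = missing.T
    n = arr.shape[1]
    x = np.arange(n)
    for r in range(arr.shape[0]):
        miss = missing[r]
        if not miss.any():
            continue
        if miss.all():
            arr[r] = np.nan
            continue
        arr[r, miss] = np.interp(x[miss], x[~miss], arr[r, ~miss])
    return arr.T if axis == 1 else arr


def preprocess(cmap: ContactMap, clip_low: float = CLIP_LOW, clip_high: float = CLIP_HIGH,
               smooth_sigma: float = 0.0, interpolate: bool = False) -> ContactMap:
    """Clip, optionally fill missing cells, optionally Gaussian-smooth.

    Clipping bounds unmasked values into ``[clip_low, clip_high]``. When
    ``interpolate`` is set, missing cells are filled by linear interpolation
    along rows and along columns (averaging the two passes) and unmasked.
    Smoothing (``smooth_sigma`` in bins, applied after filling) convolves with
    a 2D Gaussian kernel. The result is re-symmetrized.
    """
    if clip_low >= clip_high:
        raise ValueError("clip_low must be < clip_high")
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be >= 0")
    out = cmap.copy()
    out.values = np.where(out.mask, out.values, np.clip(out.values, clip_low, clip_high))
    if interpolate and out.mask.any():
        if out.mask.all():
            raise DegenerateInputError("cannot interpolate a fully masked map")
        rows = _interpolate_1d(out.values + np.where(out.mask, np.nan, 0.0), out.mask, axis=0)
        cols = _interpolate_1d(out.values + np.where(out.mask, np.nan, 0.0), out.mask, axis=1)
        with np.errstate(invalid="ignore"):
            filled = np.nanmean(np.stack([rows, cols]), axis=0)
        out.values = np.where(out.mask, filled, out.values)
        out.mask = np.zeros_like(out.mask)
        # a fully masked row AND column leaves a NaN cell: keep it masked
        leftover = ~np.isfinite(out.values)
        if leftover.any():
            out.mask = leftover | leftover.T
            out.values = np.where(out.mask, 0.0, out.values)
    if smooth_sigma > 0:
        out.values = gaussian_filter(out.values, sigma=smooth_sigma)
    out.values, out.mask = _symmetrize(out.values, out.mask)
    return out


def zero_fraction_filter(cmap: ContactMap, threshold: float = 0.6) -> bool:
    """Flag unreliable maps: true (reject) iff the fraction of zero-valued cells
    exceeds ``threshold``. Masked cells count as zero."""
    zeros = (cmap.values == 0.0) | cmap.mask
    return bool(zeros.mean() > threshold)


def make_pair(a: ContactMap, b: ContactMap) -> MapPair:
    """Pair two maps for scoring, masking each with the union of both masks."""
    if a.values.shape != b.values.shape:
        raise DimensionError(f"map shapes differ: {a.values.shape} vs {b.values.shape}")
    if a.bin_size != b.bin_size:
        raise DimensionError(f"bin sizes differ: {a.bin_size} vs {b.bin_size}")
    shared = a.mask | b.mask
    a2, b2 = a.copy(), b.copy()
    a2.mask = shared.copy()
    b2.mask = shared.copy()
    return MapPair(map_a=a2, map_b=b2, shared_mask=shared)
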