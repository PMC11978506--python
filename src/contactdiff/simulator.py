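"""Parametric simulator of TAD-structured contact maps and controlled perturbations.

The generator builds log(O/E)-scale canvases (smoothed symmetric Gaussian
background) and superimposes explicit domain structure: uniform TAD blocks
between consecutive boundary elements, insulation-depleting stripes crossing
each boundary, and Gaussian corner-loop bumps. Six perturbation operators —
noise, resolution coarsening, contrast, intensity, size and substructure —
modify a map by a controlled degree, each an exact identity at its null
parameter. On top of these, :func:`make_benchmark` builds labeled
positive/negative map-pair sets (structural boundary removal vs purely
technical degradation) for ROC/PR evaluation, and :func:`sweep` produces
graded perturbation series for sensitivity curves.

All stochastic operators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom

from .core import ContactMap, CLIP_HIGH, CLIP_LOW

__all__ = [
    "PerturbationSpec", "BenchmarkPair", "PERTURBATION_RANGES",
    "make_canvas", "add_domain_structure", "add_tad",
    "perturb_noise", "perturb_resolution", "perturb_contrast",
    "perturb_intensity", "perturb_size", "perturb_substructure",
    "sweep", "make_benchmark", "plan_screen",
]

#: parameter range swept for each perturbation kind (null value first)
PERTURBATION_RANGES = {
    "noise": (0.0, 0.2),            # Gaussian noise s.d. on log(O/E) values
    "resolution": (2048.0, 50972.0),  # target bin size, bp
    "contrast": (1.0, 2.0),         # multiplicative scalar
    "intensity": (0.0, 0.2),        # additive scalar
    "size": (1.0, 1.1),             # zoom factor
    "substructure": (0.0, 1.0),     # mixing weight of the extra-boundary map
}


@dataclasses.dataclass
class PerturbationSpec:
    """Provenance of one perturbed map: kind, 1-based degree, parameter, seed."""

    kind: str
    degree_index: int
    parameter: float
    seed: Optional[int] = None


@dataclasses.dataclass
class BenchmarkPair:
    """Labeled map pair: positive = structural edit, negative = technical change."""

    map_a: ContactMap
    map_b: ContactMap
    label: str  # "positive" | "negative"
    provenance: dict
    seed: int


def _symmetric_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric Gaussian field whose every cell has standard deviation ``sd``
    (upper triangle drawn iid and mirrored)."""
    field = rng.normal(0.0, sd, size=(n, n))
    return np.triu(field) + np.triu(field, 1).T


def make_canvas(n_bins: int = 448, bin_size: int = 2048, background_sd: float = 0.02,
                smooth_sigma: float = 1.0, seed: Optional[int] = None) -> ContactMap:
    """Structureless near-zero log(O/E) canvas.

    A symmetric iid Gaussian field is smoothed with a 2D Gaussian kernel
    (``smooth_sigma`` bins, mimicking the smoothing applied to experimental
    maps) and rescaled so the realized cell s.d. equals ``background_sd``.
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    rng = np.random.default_rng(seed)
    if background_sd == 0:
        values = np.zeros((n_bins, n_bins))
    else:
        field = rng.normal(0.0, 1.0, size=(n_bins, n_bins))
        field = (field + field.T) / 2.0
        if smooth_sigma > 0:
            field = gaussian_filter(field, sigma=smooth_sigma)
        field *= background_sd / field.std()
        values = field
    return ContactMap(values=values, bin_size=bin_size)


def add_domain_structure(cmap: ContactMap, boundaries: Sequence[int],
                         amplitude: float = 0.8, boundary_depth: float = 0.6,
                         loop_amp: float = 0.5, stripe_width: int = 5,
                         loop_sigma: float = 2.0, clip: bool = True) -> ContactMap:
    """Superimpose TAD blocks, boundary depletion stripes and corner loops.

    ``boundaries`` is a sorted list of boundary bins. Each interval between
    consecutive boundaries becomes a TAD: a uniform ``+amplitude`` square
    block, a ``+loop_amp`` Gaussian bump (s.d. ``loop_sigma`` bins) at its
    far corner, and ``-boundary_depth`` depletion blocks of side
    ``stripe_width`` crossing the diagonal at every boundary (the insulation
    diamond signal a boundary leaves in real maps). Values are re-clipped to
    the standard (-2, 2) log(O/E) bounds unless ``clip`` is false.
    """
    n = cmap.n_bins
    bounds = sorted(int(b) for b in boundaries)
    if any(b < 0 or b >= n for b in bounds):
        raise ValueError("boundary bins must lie inside the map")
    out = cmap.copy()
    v = out.values
    # TAD blocks between consecutive boundaries
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        v[b0:b1, b0:b1] += amplitude
        if loop_amp != 0:
            gi = np.arange(n)
            gx = np.exp(-0.5 * ((gi - b0) / loop_sigma) ** 2)
            gy = np.exp(-0.5 * ((gi - (b1 - 1)) / loop_sigma) ** 2)
            bump = loop_amp * np.outer(gx, gy)
            v += bump + bump.T
    # depletion stripes crossing each boundary
    for b in bounds:
        r0, r1 = max(0, b - stripe_width), b
        c0, c1 = b, min(n, b + stripe_width)
        v[r0:r1, c0:c1] -= boundary_depth
        v[c0:c1, r0:r1] -= boundary_depth
    if clip:
        v[:] = np.clip(v, CLIP_LOW, CLIP_HIGH)
    out.values = (v + v.T) / 2.0
    return out


def add_tad(cmap: ContactMap, start_frac: float = 0.25, end_frac: float = 0.75,
            amplitude: float = 0.8, boundary_depth: float = 0.6,
            loop_amp: float = 0.5, **kwargs) -> ContactMap:
    """One TAD spanning ``[start_frac, end_frac)`` of the map (two boundaries)."""
    if not (0 <= start_frac < end_frac <= 1):
        raise ValueError("need 0 <= start_frac < end_frac <= 1")
    n = cmap.n_bins
    b0 = int(round(start_frac * n))
    b1 = int(round(end_frac * n))
    return add_domain_structure(cmap, [b0, b1], amplitude=amplitude,
                                boundary_depth=boundary_depth, loop_amp=loop_amp, **kwargs)


def perturb_noise(cmap: ContactMap, sd: float, seed: Optional[int] = None) -> ContactMap:
    """Add symmetric Gaussian noise of standard deviation ``sd``; sd=0 is the identity."""
    out = cmap.copy()
    if sd == 0:
        return out
    rng = np.random.default_rng(seed)
    out.values = out.values + _symmetric_noise(cmap.n_bins, sd, rng)
    return out


def perturb_resolution(cmap: ContactMap, new_bin_size: int,
                       expand_back: bool = True) -> ContactMap:
    """Coarsen resolution by averaging neighboring bins into larger bins.

    The integer factor is k = round(new_bin_size / bin_size); trailing
    remainder bins average into the last block. With ``expand_back`` each
    coarse value is repeated k x k so the output keeps the original shape and
    stays comparable with the input; the global mean is conserved exactly when
    the side is divisible by k.
    """
    if new_bin_size < cmap.bin_size:
        raise ValueError("new_bin_size must be >= current bin size")
    k = int(round(new_bin_size / cmap.bin_size))
    if k <= 1:
        return cmap.copy()
    n = cmap.n_bins
    edges = np.arange(0, n, k)
    vals = np.where(cmap.mask, 0.0, cmap.values)
    cnts = (~cmap.mask).astype(float)
    s = np.add.reduceat(np.add.reduceat(vals, edges, axis=0), edges, axis=1)
    c = np.add.reduceat(np.add.reduceat(cnts, edges, axis=0), edges, axis=1)
    coarse = np.where(c > 0, s / np.maximum(c, 1), 0.0)
    coarse_mask = c == 0
    if not expand_back:
        return ContactMap(values=coarse, bin_size=cmap.bin_size * k,
                          chrom=cmap.chrom, start=cmap.start, mask=coarse_mask)
    rep = np.repeat(np.repeat(coarse, k, axis=0), k, axis=1)[:n, :n]
    rep_mask = np.repeat(np.repeat(coarse_mask, k, axis=0), k, axis=1)[:n, :n]
    return ContactMap(values=rep, bin_size=cmap.bin_size, chrom=cmap.chrom,
                      start=cmap.start, mask=rep_mask)


def perturb_contrast(cmap: ContactMap, c: float) -> ContactMap:
    """Multiply all values by ``c``; c=1 is the identity."""
    out = cmap.copy()
    out.values = out.values * c
    return out


def perturb_intensity(cmap: ContactMap, a: float) -> ContactMap:
    """Add ``a`` to all values; a=0 is the identity."""
    out = cmap.copy()
    out.values = out.values + a
    return out


def perturb_size(cmap: ContactMap, f: float) -> ContactMap:
    """Enlarge the structure by bilinear zoom ``f`` about the origin, cropping
    back to the original dimensions; f=1 is the identity."""
    if f < 1:
        raise ValueError("size factor must be >= 1")
    out = cmap.copy()
    if f == 1:
        return out
    n = cmap.n_bins
    zoomed = zoom(cmap.values, f, order=1)[:n, :n]
    out.values = (zoomed + zoomed.T) / 2.0
    if cmap.mask.any():
        zm = zoom(cmap.mask.astype(float), f, order=0)[:n, :n] > 0.5
        out.mask = zm | zm.T
    return out


def perturb_substructure(cmap: ContactMap, sub_map: ContactMap, m: float) -> ContactMap:
    """Blend toward a variant map with extra internal structure:
    (1−m)·map + m·sub_map; m=0 is the identity, m=1 is sub_map."""
    if cmap.values.shape != sub_map.values.shape:
        raise ValueError("map shapes differ")
    if not 0 <= m <= 1:
        raise ValueError("m must lie in [0, 1]")
    out = cmap.copy()
    out.values = (1 - m) * cmap.values + m * sub_map.values
    if m > 0:
        out.mask = cmap.mask | sub_map.mask
    return out


def sweep(base: ContactMap, kind: str, K: int = 100, seed: Optional[int] = None,
          sub_map: Optional[ContactMap] = None,
          ) -> List[Tuple[PerturbationSpec, ContactMap]]:
    """Graded perturbation series: K maps with the parameter linearly spaced
    across the kind's range (null value first).

    For ``substructure`` the blended-in map defaults to the base map with an
    additional boundary element at the map center.
    """
    if kind not in PERTURBATION_RANGES:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    lo, hi = PERTURBATION_RANGES[kind]
    params = np.linspace(lo, hi, K)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(K)]
    if kind == "substructure" and sub_map is None:
        sub_map = add_domain_structure(base, [base.n_bins // 2])
    out = []
    for idx, (param, child_seed) in enumerate(zip(params, seeds), start=1):
        if kind == "noise":
            pm = perturb_noise(base, param, seed=child_seed)
        elif kind == "resolution":
            pm = perturb_resolution(base, int(round(param)))
        elif kind == "contrast":
            pm = perturb_contrast(base, param)
        elif kind == "intensity":
            pm = perturb_intensity(base, param)
        elif kind == "size":
            pm = perturb_size(base, param)
        else:
            pm = perturb_substructure(base, sub_map, param)
        out.append((PerturbationSpec(kind=kind, degree_index=idx,
                                     parameter=float(param), seed=child_seed), pm))
    return out


def _draw_boundaries(rng: np.random.Generator, n: int, count: int = 3,
                     lo_frac: float = 0.2, hi_frac: float = 0.8,
                     min_sep: int = 5, max_tries: int = 1000) -> List[int]:
    lo, hi = int(lo_frac * n), int(hi_frac * n)
    for _ in range(max_tries):
        pos = np.sort(rng.integers(lo, hi, size=count))
        if np.all(np.diff(pos) >= min_sep):
            return [int(p) for p in pos]
    raise RuntimeError("could not place boundaries with the requested separation")


def make_benchmark(n: int = 100, negative_kind: str = "resolution",
                   seed: Optional[int] = None, n_bins: int = 448,
                   bin_size: int = 2048, amplitude: float = 0.8,
                   boundary_depth: float = 0.6, loop_amp: float = 0.5,
                   noise_sd_range: Tuple[float, float] = (0.01, 0.1),
                   resolution_range: Tuple[float, float] = (2500.0, 25000.0),
                   ) -> List[BenchmarkPair]:
    """Labeled benchmark of ``n`` positive and ``n`` negative map pairs.

    Each draw builds a neutral map: a canvas with three boundary elements at
    random positions in the central 60% of the map (minimum separation 5
    bins) and TAD blocks between consecutive boundaries. The positive partner
    removes the middle boundary element (a genuine structural change); the
    negative partner degrades the neutral map technically — Gaussian noise
    with s.d. ~ U(0.01, 0.1), or resolution coarsened to a bin size
    ~ U(2,500, 25,000) bp and re-expanded to the original shape.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if negative_kind not in {"noise", "resolution"}:
        raise ValueError(f"unknown negative kind {negative_kind!r}")
    ss = np.random.SeedSequence(seed)
    pairs: List[BenchmarkPair] = []
    for i, child in enumerate(ss.spawn(n)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        canvas_seed = int(rng.integers(0, 2**31))
        bounds = _draw_boundaries(rng, n_bins)
        canvas = make_canvas(n_bins=n_bins, bin_size=bin_size, seed=canvas_seed)
        structure = dict(amplitude=amplitude, boundary_depth=boundary_depth,
                         loop_amp=loop_amp)
        neutral = add_domain_structure(canvas, bounds, **structure)
        positive = add_domain_structure(canvas, [bounds[0], bounds[2]], **structure)
        if negative_kind == "noise":
            sd = float(rng.uniform(*noise_sd_range))
            negative = perturb_noise(neutral, sd, seed=int(rng.integers(0, 2**31)))
            neg_prov = {"kind": "noise", "sd": sd}
        else:
            new_bin = float(rng.uniform(*resolution_range))
            negative = perturb_resolution(neutral, int(round(new_bin)), expand_back=True)
            neg_prov = {"kind": "resolution", "new_bin_size": new_bin}
        pairs.append(BenchmarkPair(
            map_a=neutral, map_b=positive, label="positive",
            provenance={"kind": "boundary-removal", "boundaries": bounds,
                        "removed": bounds[1], **structure},
            seed=child_seed))
        pairs.append(BenchmarkPair(
            map_a=neutral, map_b=negative, label="negative",
            provenance={**neg_prov, "boundaries": bounds}, seed=child_seed))
    return pairs


def plan_screen(per_category: int = 7500,
                categories: Sequence[str] = ("insertion", "deletion", "random-deletion"),
                seed: Optional[int] = None) -> pd.DataFrame:
    """Manifest for an in silico perturbation screen.

    One record per planned map pair: category label, within-category index and
    a reproducible seed. The manifest enumerates the workload (pair
    construction and scoring happen downstream).
    """
    if per_category < 1:
        raise ValueError("per_category must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(per_category * len(categories)) % (2**31)
    records = []
    k = 0
    for cat in categories:
        for i in range(per_category):
            records.append({"category": cat, "index": i, "seed": int(seeds[k])})
            k += 1
    return pd.DataFrame.from_records(records)
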