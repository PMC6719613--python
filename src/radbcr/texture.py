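"""Texture matrices and radiomic features on discretized tumor ROIs.

Implements the gray-level size-zone matrix (GLSZM), gray-level run-length
matrix (GLRLM) and gray-level co-occurrence matrix (GLCM) together with a
documented feature catalog (matrix features, first-order intensity
statistics and shape descriptors), following the Image Biomarker
Standardisation Initiative (IBSI) conventions:

* GLSZM zones are connected components (26-neighbour by default) of
  constant gray level inside the ROI; ``s(i, j)`` counts zones of level
  ``i`` and size ``j`` voxels.  A homogeneous lesion has few large zones,
  a heterogeneous one many small zones, so small-zone emphasis (SZE)
  decreases with heterogeneity.
* GLRLM runs are maximal collinear sequences of equal-level voxels; the 13
  unique 3-D directions are scanned and the per-direction matrices summed
  ("merged" aggregation) before feature computation.
* GLCM counts symmetric co-occurrences at Chebyshev distance 1 over the
  same 13 directions.

Features undefined on degenerate ROIs (a single occupied gray level, zero
variance) are returned as NaN, never coerced to 0.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .imaging import (
    DiscretizationScheme,
    DiscretizedROI,
    ImageVolume,
    ROIMask,
    discretize,
    masked_intensities,
)
from .wavelets import SUBBAND_LABELS, WaveletBank

__all__ = [
    "DIRECTIONS_13",
    "GLSZM",
    "GLRLM",
    "GLCM",
    "label_zones",
    "build_glszm",
    "build_glrlm",
    "build_glcm",
    "sze",
    "szlge",
    "hgre",
    "glszm_features",
    "glrlm_features",
    "glcm_features",
    "first_order_features",
    "shape_features",
    "extract_all",
    "make_key",
    "parse_key",
    "base_feature",
    "expected_row_length",
    "GLSZM_FEATURES",
    "GLRLM_FEATURES",
    "GLCM_FEATURES",
    "FIRST_ORDER_FEATURES",
    "SHAPE_FEATURES",
]

#: The 13 unique 3-D scan directions (offsets with positive leading sign).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and next(c for c in d if c != 0) > 0
)
assert len(DIRECTIONS_13) == 13


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


# ---------------------------------------------------------------------------
# matrices


@dataclass
class GLSZM:
    """Size-zone matrix: ``counts[i-1, j-1]`` zones of level i, size j."""

    counts: np.ndarray
    n_voxels: int

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.counts.shape[0] + 1)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.counts.shape[1] + 1)


@dataclass
class GLRLM:
    """Run-length matrix aggregated over the 13 directions."""

    counts: np.ndarray
    n_voxels: int
    n_directions: int = 13

    @property
    def n_runs(self) -> int:
        return int(self.counts.sum())

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.counts.shape[0] + 1)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(1, self.counts.shape[1] + 1)


@dataclass
class GLCM:
    """Symmetric co-occurrence matrix at distance 1 over 13 directions."""

    counts: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts


def label_zones(
    disc: DiscretizedROI, connectivity: int = 26
) -> list[tuple[int, int]]:
    """Enumerate (gray level, zone size) for every zone of the ROI.

    Zones are connected components, under the given connectivity, of each
    constant-level region; every ROI voxel belongs to exactly one zone.
    """
    structure = _structure(connectivity)
    levels = disc.levels
    out: list[tuple[int, int]] = []
    for lvl in np.unique(levels[levels > 0]):
        lab, n = ndimage.label(levels == lvl, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            out.extend((int(lvl), int(s)) for s in sizes)
    return out


def build_glszm(disc: DiscretizedROI, connectivity: int = 26) -> GLSZM:
    """Tabulate zones into the size-zone matrix s(i, j)."""
    zones = label_zones(disc, connectivity)
    g = disc.n_levels
    jmax = max(s for _, s in zones)
    counts = np.zeros((g, jmax), dtype=np.int64)
    for lvl, size in zones:
        counts[lvl - 1, size - 1] += 1
    return GLSZM(counts, disc.n_voxels)


def _shifted(arr: np.ndarray, offset: tuple[int, int, int], fill=0) -> np.ndarray:
    """out[p] = arr[p + offset], `fill` outside the array bounds."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for ax, o in enumerate(offset):
        n = arr.shape[ax]
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _runs_one_direction(levels: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Per-level run-length counts along one direction.

    Uses the sliding-window identity: with c_k(i) = number of k-long
    constant-level windows of level i, the number of maximal runs of
    length exactly j is c_j - 2*c_{j+1} + c_{j+2}.
    """
    a = levels
    # same[p]: voxel p and p+offset both in ROI with equal level
    nb = _shifted(a, offset)
    same = (a > 0) & (nb == a)
    window = a > 0
    window_counts: list[np.ndarray] = []
    k = 1
    while window.any():
        window_counts.append(np.bincount(a[window], minlength=n_levels + 1)[1:])
        step = tuple(c * (k - 1) for c in offset)
        window = window & _shifted(same, step, fill=False)
        k += 1
    c = np.asarray(window_counts)  # (max_len, G)
    padded = np.vstack([c, np.zeros((2, n_levels), dtype=c.dtype)])
    exact = padded[:-2] - 2 * padded[1:-1] + padded[2:]
    return exact.T  # (G, max_len)


def build_glrlm(disc: DiscretizedROI) -> GLRLM:
    """Run-length matrix summed over the 13 unique 3-D directions."""
    g = disc.n_levels
    per_dir = [_runs_one_direction(disc.levels, d, g) for d in DIRECTIONS_13]
    lmax = max(m.shape[1] for m in per_dir)
    counts = np.zeros((g, lmax), dtype=np.int64)
    for m in per_dir:
        counts[:, : m.shape[1]] += m
    return GLRLM(counts, disc.n_voxels)


def build_glcm(disc: DiscretizedROI) -> GLCM:
    """Symmetric distance-1 co-occurrence counts over 13 directions."""
    a = disc.levels
    g = disc.n_levels
    counts = np.zeros((g, g), dtype=np.int64)
    for d in DIRECTIONS_13:
        nb = _shifted(a, d)
        valid = (a > 0) & (nb > 0)
        if valid.any():
            idx = (a[valid] - 1) * g + (nb[valid] - 1)
            counts += np.bincount(idx, minlength=g * g).reshape(g, g)
    counts = counts + counts.T
    return GLCM(counts)


# ---------------------------------------------------------------------------
# matrix features


def sze(m: GLSZM) -> float:
    """Small zone emphasis: (1/N_s) sum s(i,j)/j^2, in (0, 1].

    Lower values indicate a more heterogeneous intensity distribution
    (many small zones); a single zone of size N gives 1/N^2.
    """
    ns = m.n_zones
    if ns == 0:
        raise ValueError("empty GLSZM")
    return float((m.counts / m.sizes[None, :] ** 2).sum() / ns)


def szlge(m: GLSZM) -> float:
    """Small zone low gray-level emphasis: (1/N_s) sum s(i,j)/(i^2 j^2)."""
    ns = m.n_zones
    if ns == 0:
        raise ValueError("empty GLSZM")
    w = m.counts / (m.levels[:, None] ** 2 * m.sizes[None, :] ** 2)
    return float(w.sum() / ns)


def hgre(m: GLRLM) -> float:
    """High gray-level run emphasis: (1/N_r) sum i^2 r(i,j), >= 1."""
    nr = m.n_runs
    if nr == 0:
        raise ValueError("empty GLRLM")
    return float((m.counts * m.levels[:, None] ** 2).sum() / nr)


def _szm_rlm_features(counts: np.ndarray, n_total: int,
                      zone_pct_denom: int) -> "OrderedDict[str, float]":
    i = np.arange(1, counts.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=float)[None, :]
    s = counts.astype(float)
    p = s / n_total
    feats: OrderedDict[str, float] = OrderedDict()
    feats["SE"] = float((s / j**2).sum() / n_total)   # small/short emphasis
    feats["LE"] = float((s * j**2).sum() / n_total)   # large/long emphasis
    feats["LGE"] = float((s / i**2).sum() / n_total)
    feats["HGE"] = float((s * i**2).sum() / n_total)
    feats["SLGE"] = float((s / (i**2 * j**2)).sum() / n_total)
    feats["SHGE"] = float((s * i**2 / j**2).sum() / n_total)
    feats["LLGE"] = float((s * j**2 / i**2).sum() / n_total)
    feats["LHGE"] = float((s * i**2 * j**2).sum() / n_total)
    feats["GLN"] = float((s.sum(axis=1) ** 2).sum() / n_total)
    feats["SN"] = float((s.sum(axis=0) ** 2).sum() / n_total)
    feats["PCT"] = float(n_total / zone_pct_denom)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    feats["GLV"] = float((p * (i - mu_i) ** 2).sum())
    feats["SV"] = float((p * (j - mu_j) ** 2).sum())
    nz = p[p > 0]
    feats["ENT"] = float(-(nz * np.log2(nz)).sum())
    return feats


#: Catalog names (suffixes are appended to the family tag in feature keys).
GLSZM_FEATURES = (
    "SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
    "GLNZ", "ZSN", "ZP", "GLV", "ZSV", "ZSE",
)
GLRLM_FEATURES = (
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "RGLN", "RLN", "RP", "RGLV", "RLV", "RE",
)
GLCM_FEATURES = (
    "JointEnergy", "Contrast", "Dissimilarity", "Homogeneity",
    "JointEntropy", "Correlation",
)
FIRST_ORDER_FEATURES = (
    "Mean", "Variance", "Skewness", "Kurtosis", "Median", "Min", "Max",
    "P10", "P90", "Energy", "Entropy", "Uniformity",
)
SHAPE_FEATURES = ("VolumeMm3", "SurfaceMm2", "Sphericity", "MaxDiameterMm")


def glszm_features(m: GLSZM) -> "OrderedDict[str, float]":
    raw = _szm_rlm_features(m.counts, m.n_zones, m.n_voxels)
    return OrderedDict(zip(GLSZM_FEATURES, raw.values()))


def glrlm_features(m: GLRLM) -> "OrderedDict[str, float]":
    # run percentage uses the merged denominator: 13 directions * N_voxels
    raw = _szm_rlm_features(m.counts, m.n_runs, m.n_directions * m.n_voxels)
    return OrderedDict(zip(GLRLM_FEATURES, raw.values()))


def glcm_features(m: GLCM) -> "OrderedDict[str, float]":
    p = m.probabilities
    g = p.shape[0]
    i = np.arange(1, g + 1, dtype=float)[:, None]
    j = np.arange(1, g + 1, dtype=float)[None, :]
    feats: OrderedDict[str, float] = OrderedDict()
    feats["JointEnergy"] = float((p**2).sum())
    feats["Contrast"] = float((p * (i - j) ** 2).sum())
    feats["Dissimilarity"] = float((p * np.abs(i - j)).sum())
    feats["Homogeneity"] = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    feats["JointEntropy"] = float(-(nz * np.log2(nz)).sum()) if nz.size else float("nan")
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    var_i = float((p * (i - mu_i) ** 2).sum())
    var_j = float((p * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        feats["Correlation"] = float("nan")  # degenerate: one gray level
    else:
        cov = float((p * (i - mu_i) * (j - mu_j)).sum())
        feats["Correlation"] = cov / math.sqrt(var_i * var_j)
    return feats


# ---------------------------------------------------------------------------
# first-order and shape


def first_order_features(
    values: np.ndarray, n_bins: int = 64
) -> "OrderedDict[str, float]":
    """Intensity statistics on the raw ROI values.

    Entropy and uniformity are computed on a fixed-bin-number histogram
    (``n_bins`` bins over the ROI range); variance is the population
    variance.  Skewness/kurtosis of a constant ROI are reported as 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity list")
    mu = float(x.mean())
    var = float(x.var())
    feats: OrderedDict[str, float] = OrderedDict()
    feats["Mean"] = mu
    feats["Variance"] = var
    if var > 0:
        sd = math.sqrt(var)
        feats["Skewness"] = float(((x - mu) ** 3).mean() / sd**3)
        feats["Kurtosis"] = float(((x - mu) ** 4).mean() / sd**4 - 3.0)
    else:
        feats["Skewness"] = 0.0
        feats["Kurtosis"] = 0.0
    feats["Median"] = float(np.median(x))
    feats["Min"] = float(x.min())
    feats["Max"] = float(x.max())
    feats["P10"] = float(np.percentile(x, 10))
    feats["P90"] = float(np.percentile(x, 90))
    feats["Energy"] = float((x**2).sum())
    lo, hi = x.min(), x.max()
    if hi == lo:
        hist = np.array([x.size], dtype=float)
    else:
        idx = np.minimum((n_bins * (x - lo) / (hi - lo)).astype(int), n_bins - 1)
        hist = np.bincount(idx, minlength=n_bins).astype(float)
    prob = hist / hist.sum()
    nz = prob[prob > 0]
    feats["Entropy"] = float(-(nz * np.log2(nz)).sum())
    feats["Uniformity"] = float((prob**2).sum())
    return feats


def shape_features(mask: ROIMask, spacing) -> "OrderedDict[str, float]":
    """Voxel-count volume, face-adjacency surface area, sphericity and
    maximum 3-D diameter (largest center-to-center voxel distance)."""
    m = mask.data
    sx, sy, sz = (float(s) for s in spacing)
    n = int(m.sum())
    volume = n * sx * sy * sz
    face_areas = (sy * sz, sx * sz, sx * sy)
    surface = 0.0
    for ax, area in enumerate(face_areas):
        for o in (1, -1):
            off = [0, 0, 0]
            off[ax] = o
            nb = _shifted(m.astype(np.int8), tuple(off), fill=0)
            surface += area * float((m & (nb == 0)).sum())
    sphericity = (math.pi ** (1 / 3)) * (6 * volume) ** (2 / 3) / surface
    coords = np.argwhere(m).astype(float) * np.array([sx, sy, sz])
    if len(coords) == 1:
        diam = 0.0
    else:
        pts = coords
        if len(coords) > 400:
            try:
                hull = ConvexHull(coords)
                pts = coords[hull.vertices]
            except QhullError:
                pass  # flat/degenerate ROIs: brute force below
        diam = float(pdist(pts).max())
    feats: OrderedDict[str, float] = OrderedDict()
    feats["VolumeMm3"] = volume
    feats["SurfaceMm2"] = surface
    feats["Sphericity"] = sphericity
    feats["MaxDiameterMm"] = diam
    return feats


# ---------------------------------------------------------------------------
# feature-variant keys and full extraction


def make_key(sequence: str, subband: str, scheme_label: str, feature: str) -> str:
    return f"{sequence}|{subband}|{scheme_label}|{feature}"


def parse_key(key: str) -> tuple[str, str, str, str]:
    seq, band, scheme, feature = key.split("|")
    return seq, band, scheme, feature


def base_feature(key: str) -> tuple[str, str]:
    """The (sequence, feature-name) pair; sub-band and discretization are
    the 'parametrization' axes over which one variant is retained."""
    seq, _band, _scheme, feature = parse_key(key)
    return seq, feature


def expected_row_length(n_sequences: int, n_schemes: int) -> int:
    """Closed-form feature count per patient for the documented catalog."""
    per_combo = len(GLSZM_FEATURES) + len(GLRLM_FEATURES) + len(GLCM_FEATURES)
    return n_sequences * (
        len(SUBBAND_LABELS) * n_schemes * per_combo
        + len(FIRST_ORDER_FEATURES)
        + len(SHAPE_FEATURES)
    )


def _crop_to_bbox(data: np.ndarray, mask: np.ndarray):
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return data[sl], mask[sl]


def extract_all(
    banks: dict[str, WaveletBank],
    mask: ROIMask | dict[str, ROIMask],
    schemes: list[DiscretizationScheme],
    connectivity: int = 26,
    spacing=(1.0, 1.0, 1.0),
) -> "OrderedDict[str, float]":
    """One feature-table row: every (sequence, sub-band, scheme, feature).

    Texture families are computed per sub-band and discretization scheme;
    first-order and shape features once per sequence on the original image.
    Keys are emitted in a canonical order (sequences sorted, sub-bands in
    bank order, schemes sorted by label), so the result is independent of
    the order in which schemes are supplied.
    """
    schemes = sorted(schemes, key=lambda s: s.label)
    row: "OrderedDict[str, float]" = OrderedDict()
    for seq in sorted(banks):
        bank = banks[seq]
        seq_mask = mask[seq] if isinstance(mask, dict) else mask
        if bank.shape != seq_mask.shape:
            raise ValueError(
                f"{seq}: bank shape {bank.shape} != mask shape {seq_mask.shape}"
            )
        vals = masked_intensities(
            ImageVolume(bank["ORIG"], spacing, seq), seq_mask
        )
        for name, v in first_order_features(vals).items():
            row[make_key(seq, "ORIG", "RAW", f"FO{name}")] = v
        for name, v in shape_features(seq_mask, spacing).items():
            row[make_key(seq, "ORIG", "RAW", f"SH{name}")] = v
        for band in SUBBAND_LABELS:
            img, msk = _crop_to_bbox(bank[band], seq_mask.data)
            vol = ImageVolume(img, spacing, f"{seq}:{band}")
            roi = ROIMask(msk)
            for scheme in schemes:
                disc = discretize(vol, roi, scheme)
                with np.errstate(divide="ignore", invalid="ignore"):
                    zm = build_glszm(disc, connectivity)
                    for name, v in glszm_features(zm).items():
                        row[make_key(seq, band, scheme.label, name)] = v
                    rm = build_glrlm(disc)
                    for name, v in glrlm_features(rm).items():
                        row[make_key(seq, band, scheme.label, name)] = v
                    cm = build_glcm(disc)
                    for name, v in glcm_features(cm).items():
                        row[make_key(seq, band, scheme.label, name)] = v
    return row
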