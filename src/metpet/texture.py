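"""3D gray-level texture features over a delineated tumor region.

The masked SUV image is resampled to G (default 64) discrete gray levels
from the region minimum to maximum,

    q(x) = 1 + floor(G · (SUV(x) − min) / (max − min)),  clamped to G,

and a 36-feature battery is computed from five families:

* histogram (4): skewness, kurtosis, entropy, energy;
* gray-level co-occurrence matrix, GLCM (7): homogeneity, energy, contrast,
  correlation, entropy, dissimilarity, variance;
* gray-level run-length matrix, GLRLM (11): SRE, LRE, LGRE, HGRE, SRLGE,
  SRHGE, LRLGE, LRHGE, GLNUr, RLNU, RP;
* neighborhood gray-level difference statistics, NGLDM (3): coarseness,
  contrast, busyness;
* gray-level zone-size matrix, GLZLM (11): SZE, LZE, LGZE, HGZE, SZLGE,
  SZHGE, LZLGE, LZHGE, GLNUz, ZLNU, ZP.

GLCM and GLRLM aggregate all 13 unique 3D neighbor directions into a single
matrix (not 13 per-direction matrices); the 13-direction set together with
its negatives covers the full 26-neighborhood and is closed under axis
permutations and flips, making the aggregated features exactly invariant to
those symmetries.  Pairs, runs, zones and neighborhoods never cross the
region boundary.  Offsets are in voxel units regardless of physical
spacing (the usual radiomics convention — documented, not configurable).
Entropies are in bits (log base 2).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation import (
    MIN_TEXTURE_VOXELS,
    SUVVolume,
    TumorSegmentation,
    WARN_TEXTURE_VOXELS,
)

__all__ = [
    "FEATURE_NAMES",
    "QuantizedTumor",
    "GLCM",
    "GLRLM",
    "GLZLM",
    "FeatureVector",
    "EmptyMaskError",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "compute_ngldm_features",
    "compute_glzlm",
    "glzlm_features",
    "histogram_features",
    "extract_all",
    "DIRECTIONS_13",
]

#: The 13 unique 3D neighbor offsets (one per antipodal pair of the
#: 26-neighborhood): first nonzero component positive, lexicographic order.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Frozen roster of the 36 feature names, in reporting order.
FEATURE_NAMES: tuple[str, ...] = (
    "hist_skewness",
    "hist_kurtosis",
    "hist_entropy",
    "hist_energy",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_entropy",
    "glcm_dissimilarity",
    "glcm_variance",
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_lgre",
    "glrlm_hgre",
    "glrlm_srlge",
    "glrlm_srhge",
    "glrlm_lrlge",
    "glrlm_lrhge",
    "glrlm_glnur",
    "glrlm_rlnu",
    "glrlm_rp",
    "ngldm_coarseness",
    "ngldm_contrast",
    "ngldm_busyness",
    "glzlm_sze",
    "glzlm_lze",
    "glzlm_lgze",
    "glzlm_hgze",
    "glzlm_szlge",
    "glzlm_szhge",
    "glzlm_lzlge",
    "glzlm_lzhge",
    "glzlm_glnuz",
    "glzlm_zlnu",
    "glzlm_zp",
)
assert len(FEATURE_NAMES) == 36


class EmptyMaskError(ValueError):
    pass


@dataclass(frozen=True)
class QuantizedTumor:
    """Masked integer image with gray levels 1..n_levels inside the mask."""

    levels: np.ndarray  # int array; 0 outside the mask
    mask: np.ndarray
    n_levels: int
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class GLCM:
    """Symmetric, normalized gray-level co-occurrence matrix (sum = 1)."""

    matrix: np.ndarray  # (G, G)
    distance: int
    directions: tuple[tuple[int, int, int], ...]


@dataclass(frozen=True)
class GLRLM:
    """Aggregated gray-level run-length matrix: integer run counts M(i, l)."""

    matrix: np.ndarray  # (G, Lmax)
    n_runs: int
    n_voxels: int
    n_directions: int
    directions: tuple[tuple[int, int, int], ...]


@dataclass(frozen=True)
class GLZLM:
    """Gray-level zone-size matrix: counts of 26-connected iso-level zones."""

    matrix: np.ndarray  # (G, Zmax)
    n_zones: int
    n_voxels: int


@dataclass
class FeatureVector:
    """The 36 named texture features for one tumor, plus any warnings."""

    values: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must contain exactly the 36 canonical features")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(
    suv_values: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 64,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> QuantizedTumor:
    """Resample masked intensities to ``n_levels`` discrete gray levels.

    Levels run from the region minimum (level 1) to the region maximum
    (level ``n_levels``); a constant-valued region maps entirely to level 1.
    The min–max normalization makes every downstream feature invariant to
    multiplying the input by a positive constant.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot quantize an empty mask")
    vals = np.asarray(suv_values, dtype=float)
    lo = vals[mask].min()
    hi = vals[mask].max()
    levels = np.zeros(vals.shape, dtype=np.int32)
    if hi > lo:
        q = 1 + np.floor(n_levels * (vals[mask] - lo) / (hi - lo))
        levels[mask] = np.minimum(q, n_levels).astype(np.int32)
    else:
        levels[mask] = 1
    return QuantizedTumor(levels=levels, mask=mask, n_levels=n_levels, voxel_spacing=voxel_spacing)


def _offset_pairs(qt: QuantizedTumor, offset: tuple[int, int, int]):
    """Gray-level values at in-mask voxel pairs separated by ``offset``."""
    sl_a, sl_b = [], []
    for axis, o in enumerate(offset):
        n = qt.levels.shape[axis]
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = qt.mask[sl_a] & qt.mask[sl_b]
    return qt.levels[sl_a][valid], qt.levels[sl_b][valid]


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def compute_glcm(
    qt: QuantizedTumor,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> GLCM:
    """Co-occurrence counts of level pairs at the given voxel distance.

    Counts are accumulated over all directions into one matrix, symmetrized
    by also counting each reversed pair, then normalized to sum 1.
    """
    if not qt.mask.any():
        raise EmptyMaskError("empty mask")
    g = qt.n_levels
    counts = np.zeros((g, g), dtype=np.int64)
    for d in directions:
        off = tuple(distance * o for o in d)
        a, b = _offset_pairs(qt, off)
        np.add.at(counts, (a - 1, b - 1), 1)
    counts = counts + counts.T  # symmetrize: count reversed pairs too
    total = counts.sum()
    if total == 0:
        raise EmptyMaskError("mask contains no in-mask neighbor pairs")
    return GLCM(matrix=counts / total, distance=distance, directions=tuple(directions))


def glcm_features(m: GLCM) -> dict[str, float]:
    """Haralick-style features of a symmetric normalized co-occurrence matrix.

    correlation = Σ (i−μ)(j−μ) p(i,j) / σ² with μ, σ² the (shared) marginal
    mean and variance; defined as 0 when σ² = 0.  entropy is in bits.
    """
    p = m.matrix
    g = p.shape[0]
    i = np.arange(1, g + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_i = p.sum(axis=1)  # marginal (symmetric => same for rows/cols)
    mu = float((i * p_i).sum())
    var = float(((i - mu) ** 2 * p_i).sum())
    nz = p[p > 0]
    cov = float((((ii - mu) * (jj - mu)) * p).sum())
    return {
        "glcm_homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_contrast": float((p * (ii - jj) ** 2).sum()),
        "glcm_correlation": cov / var if var > 0 else 0.0,
        "glcm_entropy": float(-(nz * np.log2(nz)).sum()),
        "glcm_dissimilarity": float((p * np.abs(ii - jj)).sum()),
        "glcm_variance": var,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def compute_glrlm(
    qt: QuantizedTumor,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> GLRLM:
    """Maximal in-mask constant-level runs, aggregated over directions.

    A run along direction d is a maximal sequence of in-mask voxels of equal
    level; runs truncate at the mask boundary.  Counts from all directions
    accumulate into one matrix M(level, length).
    """
    if not qt.mask.any():
        raise EmptyMaskError("empty mask")
    shape = qt.levels.shape
    g = qt.n_levels
    run_counts: dict[tuple[int, int], int] = {}
    mask = qt.mask
    levels = qt.levels
    coords = np.argwhere(mask)
    max_len = 1
    for d in directions:
        d_arr = np.array(d)
        # run starts: in-mask voxels whose predecessor along d is absent or differs
        prev = coords - d_arr
        in_grid = np.all((prev >= 0) & (prev < shape), axis=1)
        starts = np.ones(len(coords), dtype=bool)
        pg = prev[in_grid]
        same = mask[pg[:, 0], pg[:, 1], pg[:, 2]] & (
            levels[pg[:, 0], pg[:, 1], pg[:, 2]]
            == levels[coords[in_grid, 0], coords[in_grid, 1], coords[in_grid, 2]]
        )
        starts[np.where(in_grid)[0][same]] = False
        for x0 in coords[starts]:
            lev = int(levels[tuple(x0)])
            length = 1
            x = x0 + d_arr
            while (
                np.all(x >= 0)
                and np.all(x < shape)
                and mask[tuple(x)]
                and levels[tuple(x)] == lev
            ):
                length += 1
                x = x + d_arr
            run_counts[(lev, length)] = run_counts.get((lev, length), 0) + 1
            max_len = max(max_len, length)
    matrix = np.zeros((g, max_len), dtype=np.int64)
    for (lev, length), c in run_counts.items():
        matrix[lev - 1, length - 1] = c
    return GLRLM(
        matrix=matrix,
        n_runs=int(matrix.sum()),
        n_voxels=qt.n_voxels,
        n_directions=len(directions),
        directions=tuple(directions),
    )


def _rlm_family(matrix: np.ndarray, n_runs: int, prefix: str) -> dict[str, float]:
    """Shared run-length / zone-size emphasis formulas.

    matrix rows are gray levels i = 1..G, columns run lengths (zone sizes)
    l = 1..Lmax; n_runs is the total count N.
    """
    g, lmax = matrix.shape
    i = np.arange(1, g + 1)[:, None].astype(float)
    l = np.arange(1, lmax + 1)[None, :].astype(float)
    m = matrix.astype(float)
    n = float(n_runs)
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    return {
        f"{prefix}_s": float((m / l**2).sum() / n),       # short emphasis
        f"{prefix}_l": float((m * l**2).sum() / n),       # long emphasis
        f"{prefix}_lg": float((m / i**2).sum() / n),      # low gray-level
        f"{prefix}_hg": float((m * i**2).sum() / n),      # high gray-level
        f"{prefix}_slg": float((m / (i**2 * l**2)).sum() / n),
        f"{prefix}_shg": float((m * i**2 / l**2).sum() / n),
        f"{prefix}_llg": float((m * l**2 / i**2).sum() / n),
        f"{prefix}_lhg": float((m * i**2 * l**2).sum() / n),
        f"{prefix}_glnu": float((row**2).sum() / n),
        f"{prefix}_lnu": float((col**2).sum() / n),
    }


def glrlm_features(m: GLRLM) -> dict[str, float]:
    """SRE/LRE/LGRE/HGRE/joint emphases, non-uniformities, run percentage.

    RP = n_runs / (n_masked_voxels × n_directions) so that RP ∈ (0, 1] under
    the aggregated-direction convention (each direction contributes at most
    one run per voxel).
    """
    if m.n_runs <= 0:
        raise ValueError("run-length matrix has no runs")
    fam = _rlm_family(m.matrix, m.n_runs, "r")
    return {
        "glrlm_sre": fam["r_s"],
        "glrlm_lre": fam["r_l"],
        "glrlm_lgre": fam["r_lg"],
        "glrlm_hgre": fam["r_hg"],
        "glrlm_srlge": fam["r_slg"],
        "glrlm_srhge": fam["r_shg"],
        "glrlm_lrlge": fam["r_llg"],
        "glrlm_lrhge": fam["r_lhg"],
        "glrlm_glnur": fam["r_glnu"],
        "glrlm_rlnu": fam["r_lnu"],
        "glrlm_rp": m.n_runs / (m.n_voxels * m.n_directions),
    }


# ---------------------------------------------------------------------------
# NGLDM (neighborhood gray-level difference statistics)
# ---------------------------------------------------------------------------

def compute_ngldm_features(qt: QuantizedTumor) -> dict[str, float]:
    """Coarseness, contrast and busyness from 26-neighborhood differences.

    For every in-mask voxel with at least one in-mask 26-neighbor, A(x) is
    the mean level of its in-mask neighbors.  With n_i the number of such
    voxels at level i, p_i = n_i / N, and s_i = Σ |i − A(x)| over them:

        coarseness = 1 / Σ_i p_i s_i
        contrast   = [Σ_i Σ_j p_i p_j (i−j)² / (Ng(Ng−1))] · [Σ_i s_i / N]
        busyness   = Σ_i p_i s_i / Σ_{i,j: p>0} |i·p_i − j·p_j|

    Degenerate denominators (constant region, single occupied level) return
    0 by convention.
    """
    if not qt.mask.any():
        raise EmptyMaskError("empty mask")
    # neighbor sums accumulate in sorted order so the result is bit-identical
    # under axis permutations/flips of the volume (reduction order canonical)
    pad_lev = np.pad(qt.levels.astype(float), 1)
    pad_msk = np.pad(qt.mask, 1)
    shape = qt.levels.shape
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    stack = np.empty((26,) + shape)
    nbr_count = np.zeros(shape, dtype=np.int64)
    for idx, (da, db, dc) in enumerate(offsets):
        sl = (slice(1 + da, 1 + da + shape[0]),
              slice(1 + db, 1 + db + shape[1]),
              slice(1 + dc, 1 + dc + shape[2]))
        m = pad_msk[sl]
        stack[idx] = np.where(m, pad_lev[sl], 0.0)
        nbr_count += m
    stack.sort(axis=0)
    nbr_sum = stack.sum(axis=0)
    valid = qt.mask & (nbr_count > 0)
    if not valid.any():
        raise EmptyMaskError("mask has no voxel with an in-mask 26-neighbor")
    lev = qt.levels[valid].astype(float)
    a = nbr_sum[valid] / nbr_count[valid]
    diffs = np.abs(lev - a)
    g = qt.n_levels
    lev_idx = qt.levels[valid] - 1
    order = np.lexsort((diffs, lev_idx))  # canonical per-level accumulation
    n_i = np.bincount(lev_idx, minlength=g).astype(float)
    s_i = np.bincount(lev_idx[order], weights=diffs[order], minlength=g)
    n_total = n_i.sum()
    p_i = n_i / n_total
    ps = float((p_i * s_i).sum())

    coarseness = 1.0 / ps if ps > 0 else 0.0

    occupied = p_i > 0
    ng = int(occupied.sum())
    i_vals = np.arange(1, g + 1, dtype=float)
    if ng > 1:
        ii, jj = np.meshgrid(i_vals, i_vals, indexing="ij")
        contrast = float(
            (np.outer(p_i, p_i) * (ii - jj) ** 2).sum() / (ng * (ng - 1)) * (s_i.sum() / n_total)
        )
    else:
        contrast = 0.0

    ip = i_vals * p_i
    ip_occ = ip[occupied]
    denom = float(np.abs(ip_occ[:, None] - ip_occ[None, :]).sum())
    busyness = ps / denom if denom > 0 else 0.0

    return {
        "ngldm_coarseness": coarseness,
        "ngldm_contrast": contrast,
        "ngldm_busyness": busyness,
    }


# ---------------------------------------------------------------------------
# GLZLM
# ---------------------------------------------------------------------------

def compute_glzlm(qt: QuantizedTumor) -> GLZLM:
    """Zone-size counts: zones are maximal 26-connected equal-level sets."""
    if not qt.mask.any():
        raise EmptyMaskError("empty mask")
    g = qt.n_levels
    zone_counts: dict[tuple[int, int], int] = {}
    zmax = 1
    for lev in np.unique(qt.levels[qt.mask]):
        labels, n = ndimage.label(qt.mask & (qt.levels == lev), structure=_CONN26)
        sizes = np.bincount(labels.ravel())[1:]
        for size in sizes:
            zone_counts[(int(lev), int(size))] = zone_counts.get((int(lev), int(size)), 0) + 1
            zmax = max(zmax, int(size))
    matrix = np.zeros((g, zmax), dtype=np.int64)
    for (lev, size), c in zone_counts.items():
        matrix[lev - 1, size - 1] = c
    return GLZLM(matrix=matrix, n_zones=int(matrix.sum()), n_voxels=qt.n_voxels)


def glzlm_features(m: GLZLM) -> dict[str, float]:
    """Zone-size analogues of the run-length features; ZP = n_zones / n_voxels."""
    if m.n_zones <= 0:
        raise ValueError("zone-size matrix has no zones")
    fam = _rlm_family(m.matrix, m.n_zones, "z")
    return {
        "glzlm_sze": fam["z_s"],
        "glzlm_lze": fam["z_l"],
        "glzlm_lgze": fam["z_lg"],
        "glzlm_hgze": fam["z_hg"],
        "glzlm_szlge": fam["z_slg"],
        "glzlm_szhge": fam["z_shg"],
        "glzlm_lzlge": fam["z_llg"],
        "glzlm_lzhge": fam["z_lhg"],
        "glzlm_glnuz": fam["z_glnu"],
        "glzlm_zlnu": fam["z_lnu"],
        "glzlm_zp": m.n_zones / m.n_voxels,
    }


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def histogram_features(qt: QuantizedTumor) -> dict[str, float]:
    """Moments and entropy of the normalized gray-level histogram.

    Skewness is m3/m2^1.5 and kurtosis m4/m2² (Pearson, not excess); both
    are 0 by convention on a zero-variance region.  Entropy in bits;
    energy = Σ p².
    """
    if not qt.mask.any():
        raise EmptyMaskError("empty mask")
    n = qt.n_voxels
    p = np.bincount(qt.levels[qt.mask] - 1, minlength=qt.n_levels) / n
    # moments from the histogram, not the voxel list: the accumulation order
    # is then fixed by gray level, so results are bit-identical under any
    # spatial rearrangement of the voxels
    k = np.arange(1, qt.n_levels + 1, dtype=float)
    mu = float((k * p).sum())
    m2 = float(((k - mu) ** 2 * p).sum())
    if m2 > 0:
        skew = float(((k - mu) ** 3 * p).sum()) / m2**1.5
        kurt = float(((k - mu) ** 4 * p).sum()) / m2**2
    else:
        skew = 0.0
        kurt = 0.0
    nz = p[p > 0]
    return {
        "hist_skewness": float(skew),
        "hist_kurtosis": float(kurt),
        "hist_entropy": float(-(nz * np.log2(nz)).sum()),
        "hist_energy": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

def extract_all(
    seg: TumorSegmentation,
    suv: SUVVolume,
    n_levels: int = 64,
    distance: int = 1,
    fill_boundary_holes: bool = True,
) -> FeatureVector:
    """Quantize the tumor and compute the full 36-feature battery.

    The texture region is the delineated boundary's interior: with
    ``fill_boundary_holes`` (default) internal sub-threshold cavities —
    e.g. necrotic foci falling below the delineation threshold — are
    included, so low-accumulation segments inside the boundary contribute
    low gray levels (this is what makes LGRE sensitive to small necrotic
    foci).  Set it to False to restrict strictly to supra-threshold voxels.
    """
    region = seg.mask
    if fill_boundary_holes:
        region = ndimage.binary_fill_holes(seg.mask)
    n = int(region.sum())
    warnings_ = list(seg.warnings)
    if n < MIN_TEXTURE_VOXELS:
        raise EmptyMaskError(
            f"texture region has {n} voxels; at least {MIN_TEXTURE_VOXELS} required"
        )
    if n < WARN_TEXTURE_VOXELS:
        msg = f"texture region has {n} voxels (< {WARN_TEXTURE_VOXELS}); features may be unstable"
        warnings_.append(msg)
        _warnings.warn(msg, stacklevel=2)

    qt = quantize(suv.values, region, n_levels=n_levels, voxel_spacing=suv.voxel_spacing)
    values: dict[str, float] = {}
    values.update(histogram_features(qt))
    values.update(glcm_features(compute_glcm(qt, distance=distance)))
    values.update(glrlm_features(compute_glrlm(qt)))
    values.update(compute_ngldm_features(qt))
    values.update(glzlm_features(compute_glzlm(qt)))
    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    if not all(np.isfinite(v) for v in ordered.values()):
        bad = [k for k, v in ordered.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite features: {bad}")
    return FeatureVector(values=ordered, warnings=warnings_)
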