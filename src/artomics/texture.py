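"""First-order and grey-level texture features of a 3D image inside a VOI.

The catalogue of record is 93 features per (image, VOI):

* first-order statistics        18
* grey-level co-occurrence      24  (GLCM)
* grey-level run length         16  (GLRLM)
* grey-level size zone          16  (GLSZM)
* grey-level dependence         14  (GLDM)
* neighbouring grey tone diff    5  (NGTDM)

Conventions (fixed so independent brute-force oracles can reproduce them):

* Discretisation: fixed bin width ``floor((x - min)/w) + 1`` or fixed bin
  count ``ceil(n (x - min)/range)`` clipped to ``[1, n]``; levels are
  1-based.
* GLCM: 13 unique 3D directions at Chebyshev distance 1, symmetric
  matrices, each direction's matrix normalised then averaged; features
  computed once on the averaged matrix.
* GLRLM: run matrices of the same 13 directions summed into one matrix;
  run percentage uses ``n_voxels * n_directions`` as its denominator.
* GLSZM: zones are 26-connected components of constant grey level.
* GLDM: dependence of a voxel = 1 + number of its in-mask 26-neighbours
  with identical grey level (alpha = 0).
* NGTDM: neighbourhood average over in-mask 26-neighbours; voxels with no
  in-mask neighbour count towards ``n_i`` but contribute 0 to ``s_i``.
* Degenerate cases (single grey level, zero variance) fall back to the
  documented constants below instead of NaN.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

EPS = np.spacing(1.0)

#: fallback for NGTDM coarseness when the denominator vanishes
COARSENESS_MAX = 1e6

#: the 13 unique 3D directions at Chebyshev distance 1
DIRECTIONS_13: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26: Tuple[Tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def discretize(
    values: np.ndarray,
    bin_width: Optional[float] = None,
    n_bins: Optional[int] = None,
) -> np.ndarray:
    """Map intensities to integer grey levels 1..Ng.

    Exactly one of ``bin_width`` (fixed bin size, CT-like) or ``n_bins``
    (fixed bin count, MR-like) must be given.
    """
    if (bin_width is None) == (n_bins is None):
        raise ValueError("specify exactly one of bin_width or n_bins")
    x = np.asarray(values, dtype=np.float64)
    lo = x.min()
    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        return (np.floor((x - lo) / bin_width) + 1).astype(np.int64)
    rng = x.max() - lo
    if rng == 0:
        return np.ones(x.shape, dtype=np.int64)
    lev = np.ceil(n_bins * (x - lo) / rng).astype(np.int64)
    return np.clip(lev, 1, n_bins)


# ---------------------------------------------------------------------------
# first order


def first_order_features(values: np.ndarray, levels: np.ndarray) -> Dict[str, float]:
    """18 first-order statistics of raw intensities inside the VOI.

    ``levels`` are the discretised grey levels of the same voxels (entropy
    and uniformity are histogram-based).
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    if n == 0:
        raise ValueError("empty VOI")
    counts = np.bincount(np.asarray(levels).ravel())[1:]
    p = counts[counts > 0] / n
    mean = x.mean()
    var = x.var()  # population variance
    m2 = var
    if m2 > 0:
        m3 = np.mean((x - mean) ** 3)
        m4 = np.mean((x - mean) ** 4)
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # non-excess (Pearson) kurtosis
    else:
        skew, kurt = 0.0, 0.0
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    return {
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float(np.sum(p**2)),
        "StandardDeviation": float(np.sqrt(var)),
    }


# ---------------------------------------------------------------------------
# GLCM


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, d):
    """Index pairs (a, b) of grey levels of in-mask voxels separated by d."""
    sl_a = tuple(
        slice(max(0, -o), levels.shape[k] - max(0, o)) for k, o in enumerate(d)
    )
    sl_b = tuple(
        slice(max(0, o), levels.shape[k] + min(0, o)) for k, o in enumerate(d)
    )
    valid = mask[sl_a] & mask[sl_b]
    return levels[sl_a][valid], levels[sl_b][valid]


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Direction-averaged symmetric normalised co-occurrence matrix."""
    acc = np.zeros((n_levels, n_levels), dtype=np.float64)
    n_dirs = 0
    for d in DIRECTIONS_13:
        a, b = _shifted_pairs(levels, mask, d)
        if a.size == 0:
            continue
        counts = np.bincount(
            (a - 1) * n_levels + (b - 1), minlength=n_levels * n_levels
        ).reshape(n_levels, n_levels)
        counts = counts + counts.T  # symmetric
        acc += counts / counts.sum()
        n_dirs += 1
    if n_dirs == 0:
        raise ValueError("VOI too small for co-occurrence computation")
    return acc / n_dirs


def glcm_features(P: np.ndarray) -> Dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))
    # p_{x+y}: k = 2..2Ng ; p_{x-y}: k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1)
    psum = np.bincount((I + J).ravel() - 2, weights=P.ravel(), minlength=2 * ng - 1)
    kdiff = np.arange(0, ng)
    pdiff = np.bincount(np.abs(I - J).ravel(), weights=P.ravel(), minlength=ng)
    nz = P > 0
    HX = -np.sum(px[px > 0] * np.log2(px[px > 0]))
    HY = -np.sum(py[py > 0] * np.log2(py[py > 0]))
    HXY = -np.sum(P[nz] * np.log2(P[nz]))
    pxy = np.outer(px, py)
    HXY1 = -np.sum(P[pxy > 0] * np.log2(pxy[pxy > 0] + EPS))
    HXY2 = -np.sum(pxy[pxy > 0] * np.log2(pxy[pxy > 0]))
    imc1 = (HXY - HXY1) / max(HX, HY) if max(HX, HY) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (HXY2 - HXY))))
    if sx > 0 and sy > 0:
        corr = (np.sum(I * J * P) - ux * uy) / (sx * sy)
    else:
        corr = 1.0
    da = float(np.sum(kdiff * pdiff))
    off = I != J
    # MCC: second largest eigenvalue of Q
    if ng > 1 and np.count_nonzero(px) > 1:
        keep = px > 0
        Psub = P[np.ix_(keep, keep)]
        pxs = px[keep]
        pys = py[keep]
        Q = (Psub / pxs[:, None]) @ (Psub / pys[:, None]).T
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": float(np.sum(I * J * P)),
        "JointAverage": ux,
        "ClusterProminence": float(np.sum((I + J - ux - uy) ** 4 * P)),
        "ClusterShade": float(np.sum((I + J - ux - uy) ** 3 * P)),
        "ClusterTendency": float(np.sum((I + J - ux - uy) ** 2 * P)),
        "Contrast": float(np.sum((I - J) ** 2 * P)),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -np.sum(pdiff[pdiff > 0] * np.log2(pdiff[pdiff > 0]))
        ),
        "DifferenceVariance": float(np.sum((kdiff - da) ** 2 * pdiff)),
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": float(HXY),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "Idm": float(np.sum(P / (1 + (I - J) ** 2))),
        "Idmn": float(np.sum(P / (1 + ((I - J) / ng) ** 2))),
        "Id": float(np.sum(P / (1 + np.abs(I - J)))),
        "Idn": float(np.sum(P / (1 + np.abs(I - J) / ng))),
        "InverseVariance": float(np.sum(P[off] / (I[off] - J[off]) ** 2)),
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(ksum * psum)),
        "SumEntropy": float(-np.sum(psum[psum > 0] * np.log2(psum[psum > 0]))),
        "SumSquares": float(np.sum((I - ux) ** 2 * P)),
        "MCC": mcc,
    }


# ---------------------------------------------------------------------------
# GLRLM


def _runs_along_direction(levels: np.ndarray, mask: np.ndarray, d):
    """Grey level and length of every maximal run along direction d."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    dvec = np.asarray(d)
    d2 = int(dvec @ dvec)
    # t advances by d2 per step along the line; the integer anchor
    # idx*d2 - t*d is constant on a line and identifies it exactly
    t = idx @ dvec
    anchor = idx * d2 - np.outer(t, dvec)
    # pack the integer anchor into a single line code, then sort once by
    # (line, t) via a combined integer key
    amin = anchor.min(axis=0)
    arng = anchor.max(axis=0) - amin + 1
    line_id = np.ravel_multi_index((anchor - amin).T, arng)
    tmin, tmax = int(t.min()), int(t.max())
    key = line_id * (tmax - tmin + 1) + (t - tmin)
    order = np.argsort(key, kind="stable")
    lid = line_id[order]
    ts = t[order]
    lev = levels[tuple(idx[order].T)]
    same_line = lid[1:] == lid[:-1]
    consecutive = (ts[1:] - ts[:-1]) == d2
    same_level = lev[1:] == lev[:-1]
    cont = same_line & consecutive & same_level
    # run starts where the previous voxel does not continue the run
    starts = np.concatenate(([True], ~cont))
    run_id = np.cumsum(starts) - 1
    lengths = np.bincount(run_id)
    run_levels = lev[starts]
    return run_levels, lengths


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts P(level, run_length) summed over the 13 directions."""
    all_lev = []
    all_len = []
    for d in DIRECTIONS_13:
        lv, ln = _runs_along_direction(levels, mask, d)
        all_lev.append(lv)
        all_len.append(ln)
    lv = np.concatenate(all_lev)
    ln = np.concatenate(all_len)
    max_len = int(ln.max())
    P = np.bincount(
        (lv - 1) * max_len + (ln - 1), minlength=n_levels * max_len
    ).reshape(n_levels, max_len)
    return P.astype(np.float64)


def _rl_family_features(
    P: np.ndarray, n_voxels: int, row_name: str, col_name: str, pct_name: str
) -> Dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas (rows = grey level, cols = size)."""
    ns = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    r = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    I, R = np.meshgrid(i, r, indexing="ij")
    mu_i = np.sum(i * pg) / ns
    mu_r = np.sum(r * pr) / ns
    pnorm = P / ns
    nzp = pnorm[pnorm > 0]
    short = "Small" if row_name == "Zone" else "Short"
    long_ = "Large" if row_name == "Zone" else "Long"
    unit = "Area" if row_name == "Zone" else "Run"
    return {
        f"{short}{unit}Emphasis": float(np.sum(P / R**2) / ns),
        f"{long_}{unit}Emphasis": float(np.sum(P * R**2) / ns),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / ns),
        "GrayLevelNonUniformityNormalized": float(np.sum(pg**2) / ns**2),
        f"{col_name}NonUniformity": float(np.sum(pr**2) / ns),
        f"{col_name}NonUniformityNormalized": float(np.sum(pr**2) / ns**2),
        pct_name: float(ns / n_voxels),
        "GrayLevelVariance": float(np.sum(pg / ns * (i - mu_i) ** 2)),
        f"{row_name}Variance": float(np.sum(pr / ns * (r - mu_r) ** 2)),
        f"{row_name}Entropy": float(-np.sum(nzp * np.log2(nzp))),
        "LowGrayLevelEmphasis": float(np.sum(P / I**2) / ns),
        "HighGrayLevelEmphasis": float(np.sum(P * I**2) / ns),
        f"{short}{unit}LowGrayLevelEmphasis": float(np.sum(P / (I**2 * R**2)) / ns),
        f"{short}{unit}HighGrayLevelEmphasis": float(np.sum(P * I**2 / R**2) / ns),
        f"{long_}{unit}LowGrayLevelEmphasis": float(np.sum(P * R**2 / I**2) / ns),
        f"{long_}{unit}HighGrayLevelEmphasis": float(np.sum(P * I**2 * R**2) / ns),
    }


def glrlm_features(P: np.ndarray, n_voxels: int, n_directions: int = 13) -> Dict[str, float]:
    feats = _rl_family_features(P, n_voxels * n_directions, "Run", "RunLength", "RunPercentage")
    ren = {
        "LowGrayLevelEmphasis": "LowGrayLevelRunEmphasis",
        "HighGrayLevelEmphasis": "HighGrayLevelRunEmphasis",
        "ShortRunLowGrayLevelEmphasis": "ShortRunLowGrayLevelEmphasis",
    }
    return {ren.get(k, k): v for k, v in feats.items()}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone counts: 26-connected components of constant grey level."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zone_levels = []
    zone_sizes = []
    masked = np.where(mask, levels, 0)
    # per-level bounding boxes in one pass; label each level within its box
    boxes = ndimage.find_objects(masked)
    for g, obj in enumerate(boxes, start=1):
        if obj is None:
            continue
        lab, n = ndimage.label(masked[obj] == g, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_levels.extend([g] * n)
        zone_sizes.extend(sizes.tolist())
    zone_levels = np.asarray(zone_levels, dtype=np.int64)
    zone_sizes = np.asarray(zone_sizes, dtype=np.int64)
    max_size = int(zone_sizes.max())
    P = np.bincount(
        (zone_levels - 1) * max_size + (zone_sizes - 1),
        minlength=n_levels * max_size,
    ).reshape(n_levels, max_size)
    return P.astype(np.float64)


def glszm_features(P: np.ndarray, n_voxels: int) -> Dict[str, float]:
    feats = _rl_family_features(P, n_voxels, "Zone", "SizeZone", "ZonePercentage")
    ren = {
        "LowGrayLevelEmphasis": "LowGrayLevelZoneEmphasis",
        "HighGrayLevelEmphasis": "HighGrayLevelZoneEmphasis",
    }
    return {ren.get(k, k): v for k, v in feats.items()}


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts P(level, dependence); alpha = 0 (exact equality)."""
    dep = np.ones(levels.shape, dtype=np.int64)  # the centre voxel itself
    for d in OFFSETS_26:
        sl_a = tuple(
            slice(max(0, -o), levels.shape[k] - max(0, o)) for k, o in enumerate(d)
        )
        sl_b = tuple(
            slice(max(0, o), levels.shape[k] + min(0, o)) for k, o in enumerate(d)
        )
        eq = (levels[sl_a] == levels[sl_b]) & mask[sl_a] & mask[sl_b]
        dep[sl_a] += eq
    lev = levels[mask]
    dp = dep[mask]
    max_dep = int(dp.max())
    P = np.bincount(
        (lev - 1) * max_dep + (dp - 1), minlength=n_levels * max_dep
    ).reshape(n_levels, max_dep)
    return P.astype(np.float64)


def gldm_features(P: np.ndarray) -> Dict[str, float]:
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)
    d = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    I, D = np.meshgrid(i, d, indexing="ij")
    mu_i = np.sum(i * pg) / nz
    mu_d = np.sum(d * pd_) / nz
    pnorm = P / nz
    nzp = pnorm[pnorm > 0]
    return {
        "SmallDependenceEmphasis": float(np.sum(P / D**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(P * D**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "DependenceNonUniformity": float(np.sum(pd_**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(pd_**2) / nz**2),
        "GrayLevelVariance": float(np.sum(pg / nz * (i - mu_i) ** 2)),
        "DependenceVariance": float(np.sum(pd_ / nz * (d - mu_d) ** 2)),
        "DependenceEntropy": float(-np.sum(nzp * np.log2(nzp))),
        "LowGrayLevelEmphasis": float(np.sum(P / I**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(P * I**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (I**2 * D**2)) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * I**2 / D**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * D**2 / I**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * I**2 * D**2) / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level voxel counts n_i and coarseness sums s_i.

    The neighbourhood average uses in-mask 26-neighbours only; voxels with
    no in-mask neighbour contribute 0 to ``s_i``.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    lv = np.where(mask, levels, 0).astype(np.float64)
    nsum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    ncount = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    lev = levels[mask]
    has_nb = ncount[mask] > 0
    avg = np.zeros(lev.shape)
    avg[has_nb] = nsum[mask][has_nb] / ncount[mask][has_nb]
    diff = np.where(has_nb, np.abs(lev - avg), 0.0)
    n_i = np.bincount(lev - 1, minlength=n_levels).astype(np.float64)
    s_i = np.bincount(lev - 1, weights=diff, minlength=n_levels)
    return n_i, s_i


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> Dict[str, float]:
    nvp = n_i.sum()
    p_i = n_i / nvp
    present = p_i > 0
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)
    ngp = int(present.sum())
    ip = i[present]
    pp = p_i[present]
    sp = s_i[present]
    coars_den = float(np.sum(pp * sp))
    coarseness = 1.0 / coars_den if coars_den > 0 else COARSENESS_MAX
    if ngp > 1:
        II, JJ = np.meshgrid(ip, ip, indexing="ij")
        PPi, PPj = np.meshgrid(pp, pp, indexing="ij")
        contrast = (
            np.sum(PPi * PPj * (II - JJ) ** 2)
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        busy_den = float(np.sum(np.abs(II * PPi - JJ * PPj)))
        busyness = float(np.sum(pp * sp)) / busy_den if busy_den > 0 else 0.0
        SSi, SSj = np.meshgrid(sp, sp, indexing="ij")
        complexity = float(
            np.sum(np.abs(II - JJ) * (PPi * SSi + PPj * SSj) / (PPi + PPj)) / nvp
        )
        s_sum = float(s_i.sum())
        strength = (
            float(np.sum((PPi + PPj) * (II - JJ) ** 2)) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# assembled catalogue

FAMILY_SIZES = {
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}

N_INTENSITY_FEATURES = sum(FAMILY_SIZES.values())  # 93


def intensity_features(
    values: np.ndarray,
    mask: np.ndarray,
    bin_width: Optional[float] = None,
    n_bins: Optional[int] = None,
) -> Dict[str, float]:
    """The full 93-feature catalogue for one image restricted to one VOI.

    ``values``/``mask`` should be cropped to (a padding of) the VOI
    bounding box for efficiency; results depend only on in-mask voxels.
    VOIs smaller than 8 voxels are rejected as degenerate.
    """
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox < 8:
        raise ValueError(f"VOI too small for texture analysis ({n_vox} voxels)")
    # tighten to the mask bounding box plus one voxel: no feature looks
    # further than one voxel outside the VOI
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    values, mask = values[sl], mask[sl]
    in_vals = values[mask]
    lev_in = discretize(in_vals, bin_width=bin_width, n_bins=n_bins)
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = lev_in
    ng = int(lev_in.max())

    out: Dict[str, float] = {}
    for name, v in first_order_features(in_vals, lev_in).items():
        out[f"firstorder_{name}"] = v
    for name, v in glcm_features(glcm_matrix(levels, mask, ng)).items():
        out[f"glcm_{name}"] = v
    for name, v in glrlm_features(glrlm_matrix(levels, mask, ng), n_vox).items():
        out[f"glrlm_{name}"] = v
    for name, v in glszm_features(glszm_matrix(levels, mask, ng), n_vox).items():
        out[f"glszm_{name}"] = v
    for name, v in gldm_features(gldm_matrix(levels, mask, ng)).items():
        out[f"gldm_{name}"] = v
    n_i, s_i = ngtdm_table(levels, mask, ng)
    for name, v in ngtdm_features(n_i, s_i).items():
        out[f"ngtdm_{name}"] = v
    assert len(out) == N_INTENSITY_FEATURES
    return out
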