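"""Gray-level texture features on a masked 3D ROI.

Implements the pinned 92-feature catalog: 18 first-order statistics and the
GLCM (23), GLRLM (16), GLSZM (16), GLDM (14) and NGTDM (5) matrix families.

Conventions (frozen; catalog identity depends on them):

* intensities inside the mask are discretized to a fixed number of gray
  levels (default 32) between the ROI minimum and maximum, which makes all
  matrix-family features invariant to affine intensity rescaling;
* co-occurrence and run-length matrices are built at distance 1 over the 13
  unique 3D offsets and averaged across offsets (GLCM matrices are
  symmetrized and normalized per offset before averaging);
* zones (GLSZM) and dependencies/neighborhoods (GLDM, NGTDM) use the full
  26-connected 3D neighborhood; the GLDM similarity tolerance is 0;
* any statistic whose denominator vanishes on a degenerate ROI returns its
  defined limit (e.g. GLCM contrast 0 and correlation 1 on a single gray
  level, NGTDM coarseness capped at 1e6).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

from seqradiomics.manifest import (
    FIRST_ORDER_FEATURES,
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    TEXTURE_FEATURE_IDS,
)
from seqradiomics.types import ImageVolume, TumorMask

#: The 13 unique distance-1 offsets in 3D (one per symmetric direction pair).
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: All 26 neighbor offsets (both directions of each pair).
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)

COARSENESS_CAP = 1e6


def discretize(values: np.ndarray, bin_count: int = 32) -> np.ndarray:
    """Map intensities to integer gray levels 1..bin_count.

    Uses equal-width bins spanning [min, max] of ``values``; a constant input
    maps to level 1 everywhere.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.ones(values.shape, dtype=np.int64)
    levels = np.floor((values - lo) / (hi - lo) * bin_count).astype(np.int64) + 1
    return np.clip(levels, 1, bin_count)


def _crop_to_bbox(voxels: np.ndarray, roi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.nonzero(roi)
    slices = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return voxels[slices], roi[slices]


def _shift(arr: np.ndarray, d: Sequence[int], fill=0) -> np.ndarray:
    """Return out with out[i] = arr[i + d], filling outside the array."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, di in zip(arr.shape, d):
        if di >= 0:
            src.append(slice(di, n))
            dst.append(slice(0, n - di))
        else:
            src.append(slice(0, n + di))
            dst.append(slice(-di, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, roi: np.ndarray, n_levels: int,
                offsets: Sequence[Sequence[int]] = OFFSETS_13) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix averaged over offsets.

    For each offset the co-occurrence counts of (level_i, level_j) pairs over
    voxels that are both in the ROI are symmetrized and normalized to sum 1;
    the per-offset matrices are then averaged (offsets with no valid pair are
    skipped).
    """
    mats = []
    lv = np.where(roi, levels, 0)
    for d in offsets:
        ok = roi & _shift(roi, d, False)
        if not ok.any():
            continue
        a = lv[ok] - 1
        b = (_shift(lv, d)[ok]) - 1
        counts = np.zeros((n_levels, n_levels))
        np.add.at(counts, (a, b), 1.0)
        counts = counts + counts.T  # symmetrize
        mats.append(counts / counts.sum())
    if not mats:
        raise ValueError("ROI has no co-occurring voxel pairs")
    return np.mean(mats, axis=0)


def glrlm_matrix(levels: np.ndarray, roi: np.ndarray, n_levels: int,
                 offsets: Sequence[Sequence[int]] = OFFSETS_13) -> np.ndarray:
    """Run-length count matrix R[g, l-1], averaged over offsets.

    A run is a maximal set of collinear consecutive ROI voxels sharing one
    gray level. Counts are averaged across the 13 directions, so the total
    run count stays on the scale of a single direction.
    """
    max_run = max(roi.shape)
    lv = np.where(roi, levels, 0)
    total = np.zeros((n_levels, max_run))
    for d in offsets:
        cont = roi & _shift(roi, d, False) & (lv == _shift(lv, d))
        # forward run length from each voxel: R[i] = 1 + cont[i] * R[i + d]
        run = np.ones(roi.shape, dtype=np.int64)
        for _ in range(max_run - 1):
            nxt = 1 + cont * _shift(run, d)
            if np.array_equal(nxt, run):
                break
            run = nxt
        back = tuple(-di for di in d)
        starts = roi & ~(_shift(roi, back, False) & (lv == _shift(lv, back)))
        np.add.at(total, (lv[starts] - 1, run[starts] - 1), 1.0)
    return total / len(offsets)


def glszm_matrix(levels: np.ndarray, roi: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix S[g, s-1] with 26-connected zones."""
    n_vox = int(roi.sum())
    counts = np.zeros((n_levels, n_vox))
    structure = np.ones((3, 3, 3), dtype=bool)
    lv = np.where(roi, levels, 0)
    for g in np.unique(lv[roi]):
        lab, n_zones = ndimage.label(lv == g, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[g - 1, s - 1] += 1.0
    return counts


def gldm_matrix(levels: np.ndarray, roi: np.ndarray, n_levels: int,
                alpha: float = 0.0) -> np.ndarray:
    """Dependence count matrix D[g, j-1].

    A neighbor is dependent when its gray level differs from the center by at
    most ``alpha``; the dependence size j of a voxel is 1 plus its number of
    dependent 26-neighbors (so j >= 1 always).
    """
    lv = np.where(roi, levels, 0)
    dep = np.zeros(roi.shape, dtype=np.int64)
    for d in OFFSETS_26:
        nb = _shift(lv, d)
        ok = roi & _shift(roi, d, False)
        dep += (ok & (np.abs(lv - nb) <= alpha)).astype(np.int64)
    counts = np.zeros((n_levels, 27))
    np.add.at(counts, (lv[roi] - 1, dep[roi]), 1.0)
    return counts


def ngtdm_table(levels: np.ndarray, roi: np.ndarray,
                n_levels: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Neighborhood gray-tone difference table.

    Returns (n_g, s_g, n_valid): per gray level the count of valid voxels,
    the summed absolute difference from the mean of the in-ROI 26-neighbors,
    and the total number of valid voxels (those with >= 1 ROI neighbor).
    """
    lv = np.where(roi, levels, 0).astype(float)
    nb_sum = np.zeros(roi.shape)
    nb_cnt = np.zeros(roi.shape)
    for d in OFFSETS_26:
        ok = _shift(roi, d, False)
        nb_sum += np.where(ok, _shift(lv, d), 0.0)
        nb_cnt += ok
    valid = roi & (nb_cnt > 0)
    diff = np.zeros(roi.shape)
    diff[valid] = np.abs(lv[valid] - nb_sum[valid] / nb_cnt[valid])
    n_g = np.zeros(n_levels)
    s_g = np.zeros(n_levels)
    np.add.at(n_g, levels[valid] - 1, 1.0)
    np.add.at(s_g, levels[valid] - 1, diff[valid])
    return n_g, s_g, int(valid.sum())


# ---------------------------------------------------------------------------
# Feature computations per family
# ---------------------------------------------------------------------------

def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def first_order_features(intensities: np.ndarray, voxel_volume_mm3: float,
                         bin_count: int = 32) -> dict[str, float]:
    x = np.asarray(intensities, dtype=float)
    n = x.size
    mean = x.mean()
    m2 = ((x - mean) ** 2).mean()
    m3 = ((x - mean) ** 3).mean()
    m4 = ((x - mean) ** 4).mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    mid = x[(x >= p10) & (x <= p90)]
    hist = np.bincount(discretize(x, bin_count) - 1, minlength=bin_count)
    p = hist / n
    energy = float((x ** 2).sum())
    return {
        "mean": float(mean),
        "variance": float(m2),
        "skewness": float(m3 / m2 ** 1.5) if m2 > 0 else 0.0,
        "kurtosis": float(m4 / m2 ** 2) if m2 > 0 else 0.0,
        "median": float(p50),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "interquartile_range": float(p75 - p25),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": (
            float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
        ),
        "root_mean_squared": float(np.sqrt((x ** 2).mean())),
        "energy": energy,
        "total_energy": energy * voxel_volume_mm3,
        "entropy": _entropy_bits(p),
        "uniformity": float((p ** 2).sum()),
    }


def glcm_features(P: np.ndarray, n_levels: int) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # diagonal (difference) and cross-diagonal (sum) probability vectors
    k_diff = np.arange(ng, dtype=float)  # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(I - J).astype(int), P)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (I + J).astype(int) - 2, P)

    da = float((k_diff * p_diff).sum())
    hxy = _entropy_bits(P.ravel())
    hx = _entropy_bits(px)
    outer = np.outer(px, px)
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-(P[nz] * np.log2(outer[nz])).sum())
    nz2 = outer > 0
    hxy2 = float(-(outer[nz2] * np.log2(outer[nz2])).sum())
    denom = max(hx, hx)  # HX == HY by symmetry
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = I != J
    ac = float((I * J * P).sum())
    corr = (ac - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    return {
        "autocorrelation": ac,
        "joint_average": mu,
        "cluster_prominence": float(((I + J - 2 * mu) ** 4 * P).sum()),
        "cluster_shade": float(((I + J - 2 * mu) ** 3 * P).sum()),
        "cluster_tendency": float(((I + J - 2 * mu) ** 2 * P).sum()),
        "contrast": float(((I - J) ** 2 * P).sum()),
        "correlation": float(corr),
        "difference_average": da,
        "difference_entropy": _entropy_bits(p_diff),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "joint_energy": float((P ** 2).sum()),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "idmn": float((P / (1.0 + ((I - J) / n_levels) ** 2)).sum()),
        "id": float((P / (1.0 + np.abs(I - J))).sum()),
        "idn": float((P / (1.0 + np.abs(I - J) / n_levels)).sum()),
        "inverse_variance": float((P[off] / (I - J)[off] ** 2).sum()),
        "maximum_probability": float(P.max()),
        "sum_average": float((k_sum * p_sum).sum()),
        "sum_entropy": _entropy_bits(p_sum),
        "sum_squares": float(((I - mu) ** 2 * P).sum()),
    }


def _size_matrix_features(M: np.ndarray, n_voxels: int,
                          kind: str) -> dict[str, float]:
    """Shared gray-level x size features for GLRLM (runs) and GLSZM (zones)."""
    total = M.sum()
    if total <= 0:
        raise ValueError("empty gray-level size matrix")
    p = M / total
    g = np.arange(1, M.shape[0] + 1, dtype=float)
    s = np.arange(1, M.shape[1] + 1, dtype=float)
    G, S = np.meshgrid(g, s, indexing="ij")
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_g = float((g * pg).sum())
    mu_s = float((s * ps).sum())
    names = {
        "glrlm": ("short_run_emphasis", "long_run_emphasis",
                  "run_length_nonuniformity", "run_length_nonuniformity_normalized",
                  "run_percentage", "run_variance", "run_entropy",
                  "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
                  "short_run_low_gray_level_emphasis",
                  "short_run_high_gray_level_emphasis",
                  "long_run_low_gray_level_emphasis",
                  "long_run_high_gray_level_emphasis"),
        "glszm": ("small_area_emphasis", "large_area_emphasis",
                  "size_zone_nonuniformity", "size_zone_nonuniformity_normalized",
                  "zone_percentage", "zone_variance", "zone_entropy",
                  "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
                  "small_area_low_gray_level_emphasis",
                  "small_area_high_gray_level_emphasis",
                  "large_area_low_gray_level_emphasis",
                  "large_area_high_gray_level_emphasis"),
    }[kind]
    (sre, lre, sn, snn, pct, svar, sent,
     lgl, hgl, slgl, shgl, llgl, lhgl) = names
    out = {
        sre: float((p / S ** 2).sum()),
        lre: float((p * S ** 2).sum()),
        "gray_level_nonuniformity": float(((M.sum(axis=1)) ** 2).sum() / total),
        "gray_level_nonuniformity_normalized": float((pg ** 2).sum()),
        sn: float(((M.sum(axis=0)) ** 2).sum() / total),
        snn: float((ps ** 2).sum()),
        pct: float(total / n_voxels),
        "gray_level_variance": float((pg * (g - mu_g) ** 2).sum()),
        svar: float((ps * (s - mu_s) ** 2).sum()),
        sent: _entropy_bits(p.ravel()),
        lgl: float((p / G ** 2).sum()),
        hgl: float((p * G ** 2).sum()),
        slgl: float((p / (G ** 2 * S ** 2)).sum()),
        shgl: float((p * G ** 2 / S ** 2).sum()),
        llgl: float((p * S ** 2 / G ** 2).sum()),
        lhgl: float((p * G ** 2 * S ** 2).sum()),
    }
    return out


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _size_matrix_features(R, n_voxels, "glrlm")


def glszm_features(S: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _size_matrix_features(S, n_voxels, "glszm")


def gldm_features(D: np.ndarray) -> dict[str, float]:
    total = D.sum()
    p = D / total
    g = np.arange(1, D.shape[0] + 1, dtype=float)
    j = np.arange(1, D.shape[1] + 1, dtype=float)
    G, J = np.meshgrid(g, j, indexing="ij")
    pg = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_g = float((g * pg).sum())
    mu_j = float((j * pj).sum())
    return {
        "small_dependence_emphasis": float((p / J ** 2).sum()),
        "large_dependence_emphasis": float((p * J ** 2).sum()),
        "gray_level_nonuniformity": float(((D.sum(axis=1)) ** 2).sum() / total),
        "dependence_nonuniformity": float(((D.sum(axis=0)) ** 2).sum() / total),
        "dependence_nonuniformity_normalized": float((pj ** 2).sum()),
        "gray_level_variance": float((pg * (g - mu_g) ** 2).sum()),
        "dependence_variance": float((pj * (j - mu_j) ** 2).sum()),
        "dependence_entropy": _entropy_bits(p.ravel()),
        "low_gray_level_emphasis": float((p / G ** 2).sum()),
        "high_gray_level_emphasis": float((p * G ** 2).sum()),
        "small_dependence_low_gray_level_emphasis": float((p / (G ** 2 * J ** 2)).sum()),
        "small_dependence_high_gray_level_emphasis": float((p * G ** 2 / J ** 2).sum()),
        "large_dependence_low_gray_level_emphasis": float((p * J ** 2 / G ** 2).sum()),
        "large_dependence_high_gray_level_emphasis": float((p * G ** 2 * J ** 2).sum()),
    }


def ngtdm_features(n_g: np.ndarray, s_g: np.ndarray, n_valid: int) -> dict[str, float]:
    if n_valid == 0:
        raise ValueError("NGTDM has no valid voxels")
    present = n_g > 0
    g = np.arange(1, n_g.size + 1, dtype=float)[present]
    p = (n_g / n_valid)[present]
    s = s_g[present]
    ngp = int(present.sum())
    ps_total = float((p * s).sum())
    coarseness = 1.0 / ps_total if ps_total > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)
    Gi, Gj = np.meshgrid(g, g, indexing="ij")
    Pi, Pj = np.meshgrid(p, p, indexing="ij")
    Si, Sj = np.meshgrid(s, s, indexing="ij")
    if ngp > 1:
        contrast = float((Pi * Pj * (Gi - Gj) ** 2).sum() / (ngp * (ngp - 1))) \
            * float(s.sum()) / n_valid
    else:
        contrast = 0.0
    busy_den = float(np.abs(g * p - (g * p)[:, None]).sum())
    busyness = ps_total / busy_den if busy_den > 0 else 0.0
    complexity = float((np.abs(Gi - Gj) * (Pi * Si + Pj * Sj) / (Pi + Pj)).sum()) \
        / n_valid
    s_total = float(s.sum())
    strength = (float(((Pi + Pj) * (Gi - Gj) ** 2).sum()) / s_total
                if s_total > 0 else 0.0)
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# Top-level entry point
# ---------------------------------------------------------------------------

def compute_texture_features(volume: ImageVolume, mask: TumorMask,
                             bin_count: int = 32,
                             offsets: Sequence[Sequence[int]] = OFFSETS_13,
                             ) -> dict[str, float]:
    """Compute the 92 catalog texture features of one masked volume.

    Returns a dict keyed by ``"family_name"`` ids in the frozen catalog
    order. Voxels outside the mask never influence the result.
    """
    if not mask.same_grid(volume):
        raise ValueError("mask grid does not match volume grid")
    vox, roi = _crop_to_bbox(volume.voxels, mask.voxels)
    intensities = vox[roi]
    levels = discretize(np.where(roi, vox, intensities.min()), bin_count)
    n_vox = int(roi.sum())
    voxel_volume = float(np.prod(volume.spacing))

    out: dict[str, float] = {}
    fo = first_order_features(intensities, voxel_volume, bin_count)
    out.update({f"firstorder_{k}": fo[k] for k in FIRST_ORDER_FEATURES})

    try:
        P = glcm_matrix(levels, roi, bin_count, offsets)
    except ValueError:
        # no co-occurring pair exists (single or fully isolated voxels):
        # collapse to the single-gray-level degenerate limits
        P = np.zeros((bin_count, bin_count))
        P[0, 0] = 1.0
    g = glcm_features(P, bin_count)
    out.update({f"glcm_{k}": g[k] for k in GLCM_FEATURES})

    r = glrlm_features(glrlm_matrix(levels, roi, bin_count, offsets), n_vox)
    out.update({f"glrlm_{k}": r[k] for k in GLRLM_FEATURES})

    z = glszm_features(glszm_matrix(levels, roi, bin_count), n_vox)
    out.update({f"glszm_{k}": z[k] for k in GLSZM_FEATURES})

    d = gldm_features(gldm_matrix(levels, roi, bin_count))
    out.update({f"gldm_{k}": d[k] for k in GLDM_FEATURES})

    n_t = ngtdm_table(levels, roi, bin_count)
    if n_t[2] == 0:  # no voxel has an in-ROI neighbor
        n = ngtdm_features(np.array([1.0]), np.array([0.0]), 1)
    else:
        n = ngtdm_features(*n_t)
    out.update({f"ngtdm_{k}": n[k] for k in NGTDM_FEATURES})

    assert list(out.keys()) == list(TEXTURE_FEATURE_IDS)
    return out
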