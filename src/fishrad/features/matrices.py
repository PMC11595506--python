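"""The five texture-matrix families: GLCM, GLRLM, GLSZM, GLDM, NGTDM.

All builders operate on a gray-level array in which 0 marks pixels
outside the region and levels 1..Ng mark pixels inside; matrices are
indexed by the gray-level *values actually present* in the region, which
enter the feature formulas directly (e.g. LowGrayLevelEmphasis weights by
1/i^2 with i the level value, not the row index).

Aggregation conventions:

* GLCM and GLRLM are built per in-plane angle (4 unit offsets at
  distance 1); features are computed per angle and the mean over angles
  is reported.  Angles contributing no pixel pairs/runs are dropped.
* GLSZM zones use 8-connectivity; GLDM dependence uses the Chebyshev-1
  neighborhood with tolerance alpha (default 0) and matrix column
  ``d + 1`` for a pixel with ``d`` dependent neighbors; NGTDM uses the
  8-neighborhood mean tone, excluding pixels with no in-mask neighbor.

Degenerate single-level conventions are fixed so that a one-bin
discretization never produces NaN: GLCM Correlation = 1, Imc1 = Imc2 = 0,
MCC = 1; NGTDM Coarseness is capped at 1e6 when its denominator is zero.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label as _sk_label


COARSENESS_CAP = 1e6

#: In-plane unit offsets (row, col) at distance 1.
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_FEATURES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
]

GLRLM_FEATURES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

GLSZM_FEATURES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]

GLDM_FEATURES = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]

NGTDM_FEATURES = [
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
]

_NEIGHBOR_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)



def _entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy (base 2) over the nonzero probabilities.

    Summing only where p > 0 keeps degenerate one-cell distributions at
    exactly 0 instead of an O(eps) residue that downstream relative-error
    analyses would amplify.
    """
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _crop(levels: np.ndarray) -> np.ndarray:
    """Crop the level grid to the bounding box of the region."""
    rows, cols = np.nonzero(levels)
    return levels[rows.min():rows.max() + 1, cols.min():cols.max() + 1]


def _present_levels(levels: np.ndarray) -> np.ndarray:
    lv = np.unique(levels)
    return lv[lv > 0]


def _index_of(levels: np.ndarray, gray_levels: np.ndarray) -> np.ndarray:
    """Map level values to 0-based matrix row indices (0 level -> -1)."""
    idx = np.searchsorted(gray_levels, levels)
    idx = np.clip(idx, 0, len(gray_levels) - 1)
    out = np.where(levels > 0, idx, -1)
    return out


# ---------------------------------------------------------------------------
# GLCM

def build_glcm(levels: np.ndarray, offset: tuple[int, int],
               gray_levels: np.ndarray | None = None) -> np.ndarray:
    """Symmetrized co-occurrence count matrix for one offset.

    Returns raw (unnormalized) symmetric counts, shape ``(K, K)`` over
    the present gray levels.
    """
    levels = _crop(np.asarray(levels))
    if gray_levels is None:
        gray_levels = _present_levels(levels)
    k = len(gray_levels)
    idx = _index_of(levels, gray_levels)
    dr, dc = offset
    h, w = levels.shape
    r0 = slice(max(0, -dr), min(h, h - dr))
    c0 = slice(max(0, -dc), min(w, w - dc))
    r1 = slice(max(0, dr), min(h, h + dr))
    c1 = slice(max(0, dc), min(w, w + dc))
    a = idx[r0, c0]
    b = idx[r1, c1]
    valid = (a >= 0) & (b >= 0)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (a[valid], b[valid]), 1)
    return counts + counts.T


def _glcm_features_single(counts: np.ndarray, g: np.ndarray) -> dict[str, float]:
    p = counts.astype(np.float64)
    p /= p.sum()
    k = len(g)
    gi = g.astype(np.float64)
    i = gi[:, None]
    j = gi[None, :]

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((px * gi).sum())
    uy = float((py * gi).sum())
    sigx = float(np.sqrt((px * (gi - ux) ** 2).sum()))
    sigy = float(np.sqrt((py * (gi - uy) ** 2).sum()))

    diff = np.abs(i - j).astype(np.int64)
    summ = (i + j).astype(np.int64)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel())
    p_sum = np.bincount(summ.ravel(), weights=p.ravel())
    kd = np.arange(len(p_diff), dtype=np.float64)
    ks = np.arange(len(p_sum), dtype=np.float64)
    da = float((p_diff * kd).sum())
    sa = float((p_sum * ks).sum())

    hxy = _entropy_bits(p)
    pxpy = px[:, None] * py[None, :]
    # cross-entropy of p against px*py; p > 0 implies pxpy > 0
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    hxy2 = _entropy_bits(pxpy)
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)

    if k == 1:
        correlation, imc1, imc2, mcc = 1.0, 0.0, 0.0, 1.0
    else:
        if sigx * sigy == 0:
            correlation = 1.0
        else:
            correlation = (float((p * i * j).sum()) - ux * uy) / (sigx * sigy)
        denom = max(hx, hy)
        imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(px[:, None] > 0, p / np.where(px[:, None] > 0, px[:, None], 1.0), 0.0)
            b = np.where(py[None, :] > 0, p / np.where(py[None, :] > 0, py[None, :], 1.0), 0.0)
        q = a @ b.T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if len(eig) > 1 else 1.0

    off_diag = diff > 0
    inverse_variance = float((p[off_diag] / (i - j)[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    ng = float(k)
    return {
        "Autocorrelation": float((p * i * j).sum()),
        "ClusterProminence": float((p * (i + j - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (i + j - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (i + j - ux - uy) ** 2).sum()),
        "Contrast": float((p * (i - j) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy_bits(p_diff),
        "DifferenceVariance": float((p_diff * (kd - da) ** 2).sum()),
        "Id": float((p / (1.0 + np.abs(i - j))).sum()),
        "Idm": float((p / (1.0 + (i - j) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (i - j) ** 2 / ng ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(i - j) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inverse_variance,
        "JointAverage": ux,
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": sa,
        "SumEntropy": _entropy_bits(p_sum),
        "SumSquares": float((p * (i - ux) ** 2).sum()),
    }


_GLCM_DEGENERATE = {name: 0.0 for name in GLCM_FEATURES}
_GLCM_DEGENERATE.update(
    Autocorrelation=1.0, Correlation=1.0, Id=1.0, Idm=1.0, Idmn=1.0, Idn=1.0,
    JointAverage=1.0, JointEnergy=1.0, MCC=1.0, MaximumProbability=1.0,
    SumAverage=2.0,
)


def glcm_features(levels: np.ndarray) -> dict[str, float]:
    """Mean over angles of the 24 co-occurrence features."""
    levels = _crop(np.asarray(levels))
    g = _present_levels(levels)
    per_angle = []
    for offset in GLCM_OFFSETS:
        counts = build_glcm(levels, offset, g)
        if counts.sum() == 0:
            continue
        per_angle.append(_glcm_features_single(counts, g))
    if not per_angle:
        # single pixel: no pair at any angle; 1x1 conventions
        return dict(_GLCM_DEGENERATE)
    return {name: float(np.mean([f[name] for f in per_angle])) for name in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLRLM

def _rle_lines(lines) -> tuple[np.ndarray, np.ndarray]:
    """Run values and lengths across many 1D level lines (0 breaks runs)."""
    pieces = []
    for ln in lines:
        pieces.append(np.asarray(ln, dtype=np.int64))
        pieces.append(np.zeros(1, dtype=np.int64))
    seq = np.concatenate(pieces)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(seq)]))
    values = seq[starts]
    lengths = ends - starts
    keep = values > 0
    return values[keep], lengths[keep]


def _direction_lines(levels: np.ndarray, direction: tuple[int, int]):
    h, w = levels.shape
    if direction == (0, 1):
        return list(levels)
    if direction == (1, 0):
        return list(levels.T)
    if direction == (1, 1):
        return [np.diagonal(levels, off) for off in range(-h + 1, w)]
    if direction == (1, -1):
        fl = np.fliplr(levels)
        return [np.diagonal(fl, off) for off in range(-h + 1, w)]
    raise ValueError(f"unknown direction {direction}")


def build_glrlm(levels: np.ndarray, direction: tuple[int, int],
                gray_levels: np.ndarray | None = None) -> np.ndarray:
    """Run-length count matrix P(level, run length) for one direction."""
    levels = _crop(np.asarray(levels))
    if gray_levels is None:
        gray_levels = _present_levels(levels)
    values, lengths = _rle_lines(_direction_lines(levels, direction))
    max_len = max(levels.shape)
    counts = np.zeros((len(gray_levels), max_len), dtype=np.int64)
    idx = np.searchsorted(gray_levels, values)
    np.add.at(counts, (idx, lengths - 1), 1)
    return counts


def _rlm_style_features(counts: np.ndarray, g: np.ndarray, n_pixels: int,
                        names: dict[str, str]) -> dict[str, float]:
    """Shared formula block for GLRLM (runs) and GLSZM (zones).

    ``names`` maps the generic formula keys to the family's feature names.
    """
    p = counts.astype(np.float64)
    nr = p.sum()
    i = g.astype(np.float64)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    pn = p / nr
    mu_i = float((pn * i).sum())
    mu_j = float((pn * j).sum())
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    # one gray level -> the gray-level variance is exactly 0; the float
    # formula leaves an O(eps) residue that relative-error analyses amplify
    glv = 0.0 if len(g) == 1 else float((pn * (i - mu_i) ** 2).sum())
    out = {
        names["SE"]: float((p / j ** 2).sum() / nr),
        names["LE"]: float((p * j ** 2).sum() / nr),
        names["GLN"]: float((p_i ** 2).sum() / nr),
        names["GLNN"]: float((p_i ** 2).sum() / nr ** 2),
        names["SN"]: float((p_j ** 2).sum() / nr),
        names["SNN"]: float((p_j ** 2).sum() / nr ** 2),
        names["PCT"]: float(nr / n_pixels),
        names["GLV"]: glv,
        names["SV"]: float((pn * (j - mu_j) ** 2).sum()),
        names["ENT"]: _entropy_bits(pn),
        names["LGL"]: float((p / i ** 2).sum() / nr),
        names["HGL"]: float((p * i ** 2).sum() / nr),
        names["SLGL"]: float((p / (i ** 2 * j ** 2)).sum() / nr),
        names["SHGL"]: float((p * i ** 2 / j ** 2).sum() / nr),
        names["LLGL"]: float((p * j ** 2 / i ** 2).sum() / nr),
        names["LHGL"]: float((p * i ** 2 * j ** 2).sum() / nr),
    }
    return out


_GLRLM_NAMES = dict(
    SE="ShortRunEmphasis", LE="LongRunEmphasis",
    GLN="GrayLevelNonUniformity", GLNN="GrayLevelNonUniformityNormalized",
    SN="RunLengthNonUniformity", SNN="RunLengthNonUniformityNormalized",
    PCT="RunPercentage", GLV="GrayLevelVariance", SV="RunVariance",
    ENT="RunEntropy", LGL="LowGrayLevelRunEmphasis", HGL="HighGrayLevelRunEmphasis",
    SLGL="ShortRunLowGrayLevelEmphasis", SHGL="ShortRunHighGrayLevelEmphasis",
    LLGL="LongRunLowGrayLevelEmphasis", LHGL="LongRunHighGrayLevelEmphasis",
)

_GLSZM_NAMES = dict(
    SE="SmallAreaEmphasis", LE="LargeAreaEmphasis",
    GLN="GrayLevelNonUniformity", GLNN="GrayLevelNonUniformityNormalized",
    SN="SizeZoneNonUniformity", SNN="SizeZoneNonUniformityNormalized",
    PCT="ZonePercentage", GLV="GrayLevelVariance", SV="ZoneVariance",
    ENT="ZoneEntropy", LGL="LowGrayLevelZoneEmphasis", HGL="HighGrayLevelZoneEmphasis",
    SLGL="SmallAreaLowGrayLevelEmphasis", SHGL="SmallAreaHighGrayLevelEmphasis",
    LLGL="LargeAreaLowGrayLevelEmphasis", LHGL="LargeAreaHighGrayLevelEmphasis",
)


def glrlm_features(levels: np.ndarray) -> dict[str, float]:
    """Mean over the 4 directions of the 16 run-length features."""
    levels = _crop(np.asarray(levels))
    g = _present_levels(levels)
    n_pixels = int((levels > 0).sum())
    per_angle = []
    for direction in GLCM_OFFSETS:
        counts = build_glrlm(levels, direction, g)
        if counts.sum() == 0:
            continue
        per_angle.append(_rlm_style_features(counts, g, n_pixels, _GLRLM_NAMES))
    return {name: float(np.mean([f[name] for f in per_angle])) for name in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM

def build_glszm(levels: np.ndarray, gray_levels: np.ndarray | None = None) -> np.ndarray:
    """Size-zone count matrix P(level, zone size); zones 8-connected."""
    levels = _crop(np.asarray(levels))
    if gray_levels is None:
        gray_levels = _present_levels(levels)
    # label() joins neighbors of *equal* value, so one call covers all levels
    lab = _sk_label(levels, background=0, connectivity=2)
    n_zones = lab.max()
    if n_zones == 0:
        return np.zeros((len(gray_levels), 1), dtype=np.int64)
    sizes = np.bincount(lab.ravel())[1:]
    flat_lab = lab.ravel()
    order = np.argsort(flat_lab, kind="stable")
    first = np.searchsorted(flat_lab[order], np.arange(1, n_zones + 1))
    zone_levels = levels.ravel()[order[first]]
    counts = np.zeros((len(gray_levels), int(sizes.max())), dtype=np.int64)
    idx = np.searchsorted(gray_levels, zone_levels)
    np.add.at(counts, (idx, sizes - 1), 1)
    return counts


def glszm_features(levels: np.ndarray) -> dict[str, float]:
    """The 16 size-zone features (single matrix; no angles)."""
    levels = _crop(np.asarray(levels))
    g = _present_levels(levels)
    n_pixels = int((levels > 0).sum())
    counts = build_glszm(levels, g)
    return _rlm_style_features(counts, g, n_pixels, _GLSZM_NAMES)


# ---------------------------------------------------------------------------
# GLDM

def _neighbor_shifts(arr: np.ndarray):
    """Yield (shifted array, validity mask) for each of the 8 neighbors."""
    h, w = arr.shape
    for dr, dc in _NEIGHBOR_OFFSETS:
        shifted = np.zeros_like(arr)
        valid = np.zeros(arr.shape, dtype=bool)
        r_dst = slice(max(0, -dr), min(h, h - dr))
        c_dst = slice(max(0, -dc), min(w, w - dc))
        r_src = slice(max(0, dr), min(h, h + dr))
        c_src = slice(max(0, dc), min(w, w + dc))
        shifted[r_dst, c_dst] = arr[r_src, c_src]
        valid[r_dst, c_dst] = True
        yield shifted, valid


def build_gldm(levels: np.ndarray, alpha: int = 0,
               gray_levels: np.ndarray | None = None) -> np.ndarray:
    """Dependence count matrix P(level, d + 1).

    ``d`` for a pixel is the number of in-mask Chebyshev-1 neighbors
    whose level differs by at most ``alpha``; the matrix column index is
    ``d`` (so column ``d`` corresponds to dependence size ``d + 1`` in
    the feature formulas).
    """
    levels = _crop(np.asarray(levels))
    if gray_levels is None:
        gray_levels = _present_levels(levels)
    in_mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for shifted, valid in _neighbor_shifts(levels):
        ok = in_mask & valid & (shifted > 0) & (np.abs(levels - shifted) <= alpha)
        dep += ok
    counts = np.zeros((len(gray_levels), 9), dtype=np.int64)
    idx = np.searchsorted(gray_levels, levels[in_mask])
    np.add.at(counts, (idx, dep[in_mask]), 1)
    return counts


def gldm_features(levels: np.ndarray, alpha: int = 0) -> dict[str, float]:
    """The 14 dependence features (single matrix; no angles)."""
    levels = _crop(np.asarray(levels))
    g = _present_levels(levels)
    counts = build_gldm(levels, alpha, g)
    p = counts.astype(np.float64)
    nz = p.sum()
    i = g.astype(np.float64)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]  # j = d + 1
    pn = p / nz
    mu_i = float((pn * i).sum())
    mu_j = float((pn * j).sum())
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    glv = 0.0 if len(g) == 1 else float((pn * (i - mu_i) ** 2).sum())
    return {
        "DependenceEntropy": _entropy_bits(pn),
        "DependenceNonUniformity": float((p_j ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((p_j ** 2).sum() / nz ** 2),
        "DependenceVariance": float((pn * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((p_i ** 2).sum() / nz),
        "GrayLevelVariance": glv,
        "HighGrayLevelEmphasis": float((p * i ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((p * j ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i ** 2 * j ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j ** 2 / i ** 2).sum() / nz),
        "LowGrayLevelEmphasis": float((p / i ** 2).sum() / nz),
        "SmallDependenceEmphasis": float((p / j ** 2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i ** 2 / j ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i ** 2 * j ** 2)).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM

def build_ngtdm(levels: np.ndarray,
                gray_levels: np.ndarray | None = None):
    """Neighborhood gray-tone difference vectors (n_i, p_i, s_i).

    Pixels without any in-mask neighbor have no defined neighborhood
    tone and are excluded.
    """
    levels = _crop(np.asarray(levels))
    if gray_levels is None:
        gray_levels = _present_levels(levels)
    in_mask = levels > 0
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    for shifted, valid in _neighbor_shifts(levels):
        ok = valid & (shifted > 0)
        nbr_sum += np.where(ok, shifted, 0)
        nbr_cnt += ok
    usable = in_mask & (nbr_cnt > 0)
    k = len(gray_levels)
    n_i = np.zeros(k, dtype=np.int64)
    s_i = np.zeros(k, dtype=np.float64)
    if usable.any():
        avg = nbr_sum[usable] / nbr_cnt[usable]
        lv = levels[usable].astype(np.float64)
        idx = np.searchsorted(gray_levels, levels[usable])
        np.add.at(n_i, idx, 1)
        np.add.at(s_i, idx, np.abs(lv - avg))
    total = n_i.sum()
    p_i = n_i / total if total > 0 else np.zeros(k)
    return n_i, p_i, s_i


def ngtdm_features(levels: np.ndarray) -> dict[str, float]:
    """The 5 neighborhood gray-tone difference features."""
    levels = _crop(np.asarray(levels))
    g = _present_levels(levels)
    n_i, p_i, s_i = build_ngtdm(levels, g)
    n_total = int(n_i.sum())
    if n_total == 0:
        return {"Busyness": 0.0, "Coarseness": COARSENESS_CAP,
                "Complexity": 0.0, "Contrast": 0.0, "Strength": 0.0}
    present = p_i > 0
    gv = g.astype(np.float64)
    ngp = int(present.sum())

    denom_coarse = float((p_i * s_i).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    i = gv[present][:, None]
    j = gv[present][None, :]
    pi = p_i[present][:, None]
    pj = p_i[present][None, :]
    si = s_i[present][:, None]
    sj = s_i[present][None, :]

    if ngp > 1:
        contrast = float((pi * pj * (i - j) ** 2).sum()) / (ngp * (ngp - 1))
        contrast *= float(s_i.sum()) / n_total
    else:
        contrast = 0.0

    busy_denom = float(np.abs(i * pi - j * pj).sum())
    busyness = denom_coarse / busy_denom if busy_denom > 0 else 0.0

    complexity = float((np.abs(i - j) * (pi * si + pj * sj) / (pi + pj)).sum()) / n_total

    s_total = float(s_i.sum())
    strength = float(((pi + pj) * (i - j) ** 2).sum()) / s_total if s_total > 0 else 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
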