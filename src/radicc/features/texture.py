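"""Texture-matrix feature families: GLCM, GLRLM, GLSZM, GLDM and NGTDM.

All five families operate on a :class:`~radicc.features.discretize.DiscretizedROI`.
Conventions (matching the IBSI/PyRadiomics defaults):

* GLCM and GLRLM use the 13 unique 3-D direction vectors at Chebyshev
  distance 1; each feature is computed per direction and averaged without
  distance weighting.  GLCM matrices are symmetrized before normalization.
* GLSZM zones and GLDM/NGTDM neighbourhoods use 26-connectivity.
* The GLDM dependence count of a voxel is 1 + the number of 26-neighbours
  inside the ROI whose gray level differs by at most ``alpha`` (default 0);
  the voxel is always dependent on itself, so the count is >= 1.
* Voxels outside the ROI break runs and are excluded from neighbourhoods.

Degenerate single-level ROIs follow the usual conventions: MCC = 1,
cluster shade/prominence = 0, NGTDM complexity = 0, etc.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

_EPS = np.spacing(1.0)

# 13 unique direction vectors: first nonzero component positive
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0) or (dx > 0)
)

OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Flattened views of ``arr`` at relative offset ``d`` (a at 0, b at d)."""
    sl_a, sl_b = [], []
    for o, n in zip(d, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)].ravel(), arr[tuple(sl_b)].ravel()


# --------------------------------------------------------------------------
# GLCM


def glcm_matrices(droi: DiscretizedROI) -> np.ndarray:
    """Symmetrized (unnormalized) co-occurrence matrices, one per direction.

    Directions that produce no in-ROI voxel pair (possible for very thin
    ROIs) are dropped.  Returns an array of shape (n_directions, ng, ng).
    """
    lv = droi.levels
    ng = droi.ng
    mats = []
    for d in DIRECTIONS_13:
        a, b = _shifted_views(lv, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        counts = np.bincount(
            (a[valid].astype(np.int64) - 1) * ng + (b[valid] - 1),
            minlength=ng * ng).reshape(ng, ng).astype(np.float64)
        mats.append(counts + counts.T)
    if not mats:
        # single isolated voxel: co-occurrence of the voxel with itself is
        # undefined; use a one-entry matrix so degenerate conventions apply
        m = np.zeros((ng, ng))
        m[droi.levels.max() - 1, droi.levels.max() - 1] = 1.0
        mats.append(m)
    return np.stack(mats)


_GLCM_ALL = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)


def glcm_features(droi: DiscretizedROI,
                  names: "set[str] | None" = None) -> dict[str, float]:
    """The 24 co-occurrence features (or a requested subset).

    Feature groups that are not requested are skipped entirely, which makes
    extracting a handful of named features much cheaper than the full set.
    """
    want = set(_GLCM_ALL) if names is None else set(names)
    unknown = want - set(_GLCM_ALL)
    if unknown:
        raise KeyError(f"unknown GLCM features {sorted(unknown)}")
    mats = glcm_matrices(droi)
    ng = droi.ng
    # drop gray levels absent from every matrix: they contribute nothing to
    # any sum over P, and the remaining formulas use the actual level values
    occ_lv = np.where(mats.sum(axis=(0, 2)) + mats.sum(axis=(0, 1)) > 0)[0]
    mats = mats[np.ix_(np.arange(mats.shape[0]), occ_lv, occ_lv)]
    g = (occ_lv + 1).astype(np.float64)
    P = mats / mats.sum(axis=(1, 2), keepdims=True)            # (D, m, m)
    D = P.shape[0]
    m = len(g)
    px = P.sum(axis=2)                                         # (D, m)
    py = P.sum(axis=1)                                         # = px by symmetry
    ux = (px * g).sum(axis=1)                                  # (D,)
    uy = (py * g).sum(axis=1)

    ii = g[:, None] * np.ones((1, m))
    jj = ii.T
    idiff = np.abs(ii - jj)

    def total(expr):                                           # sum_ij P * expr
        return (P * expr[None, :, :]).sum(axis=(1, 2))

    feats: dict[str, np.ndarray] = {}

    if want & {"Autocorrelation", "Correlation"}:
        autocorrelation = total(ii * jj)
        feats["Autocorrelation"] = autocorrelation
    if "JointAverage" in want:
        feats["JointAverage"] = ux
    if want & {"ClusterTendency", "ClusterShade", "ClusterProminence"}:
        cdev = (ii + jj)[None, :, :] - 2.0 * ux[:, None, None]
        pc2 = P * cdev ** 2
        feats["ClusterTendency"] = pc2.sum(axis=(1, 2))
        if want & {"ClusterShade", "ClusterProminence"}:
            pc3 = pc2 * cdev
            feats["ClusterShade"] = pc3.sum(axis=(1, 2))
            feats["ClusterProminence"] = (pc3 * cdev).sum(axis=(1, 2))
    if "Contrast" in want:
        feats["Contrast"] = total((ii - jj) ** 2)
    if "Correlation" in want:
        sigx = np.sqrt((px * (g[None, :] - ux[:, None]) ** 2).sum(axis=1))
        sigy = np.sqrt((py * (g[None, :] - uy[:, None]) ** 2).sum(axis=1))
        cov = autocorrelation - ux * uy
        with np.errstate(invalid="ignore", divide="ignore"):
            feats["Correlation"] = np.where(sigx * sigy > 0,
                                            cov / (sigx * sigy + _EPS), 1.0)

    if want & {"DifferenceAverage", "DifferenceEntropy", "DifferenceVariance",
               "SumAverage", "SumEntropy"}:
        # sum / difference distributions over the actual level values
        p_sum = np.zeros((D, 2 * ng - 1))    # k = i + j in 2..2ng -> index k-2
        p_diff = np.zeros((D, ng))           # k = |i - j| in 0..ng-1
        sum_idx = (ii + jj - 2).astype(np.int64).ravel()
        diff_idx = idiff.astype(np.int64).ravel()
        for d in range(D):
            p_sum[d] = np.bincount(sum_idx, weights=P[d].ravel(),
                                   minlength=2 * ng - 1)
            p_diff[d] = np.bincount(diff_idx, weights=P[d].ravel(), minlength=ng)
        ks = np.arange(2, 2 * ng + 1, dtype=np.float64)
        kd = np.arange(0, ng, dtype=np.float64)
        difference_average = (p_diff * kd).sum(axis=1)
        feats["DifferenceAverage"] = difference_average
        feats["DifferenceEntropy"] = -(p_diff * np.log2(p_diff + _EPS)).sum(axis=1)
        feats["DifferenceVariance"] = (
            p_diff * (kd[None, :] - difference_average[:, None]) ** 2).sum(axis=1)
        feats["SumAverage"] = (p_sum * ks).sum(axis=1)
        feats["SumEntropy"] = -(p_sum * np.log2(p_sum + _EPS)).sum(axis=1)

    if "JointEnergy" in want:
        feats["JointEnergy"] = (P ** 2).sum(axis=(1, 2))
    if want & {"JointEntropy", "Imc1", "Imc2"}:
        joint_entropy = -(P * np.log2(P + _EPS)).sum(axis=(1, 2))
        feats["JointEntropy"] = joint_entropy
    if want & {"Imc1", "Imc2"}:
        hx = -(px * np.log2(px + _EPS)).sum(axis=1)
        hy = -(py * np.log2(py + _EPS)).sum(axis=1)
        pxpy = px[:, :, None] * py[:, None, :]
        log_pxpy = np.log2(pxpy + _EPS)
        hxy1 = -(P * log_pxpy).sum(axis=(1, 2))
        hxy2 = -(pxpy * log_pxpy).sum(axis=(1, 2))
        hmax = np.maximum(hx, hy)
        with np.errstate(invalid="ignore", divide="ignore"):
            feats["Imc1"] = np.where(hmax > 0,
                                     (joint_entropy - hxy1) / (hmax + _EPS), 0.0)
        feats["Imc2"] = np.sqrt(
            np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0, None))

    if "Idm" in want:
        feats["Idm"] = total(1.0 / (1.0 + (ii - jj) ** 2))
    if "Idmn" in want:
        feats["Idmn"] = total(1.0 / (1.0 + ((ii - jj) / ng) ** 2))
    if "Id" in want:
        feats["Id"] = total(1.0 / (1.0 + idiff))
    if "Idn" in want:
        feats["Idn"] = total(1.0 / (1.0 + idiff / ng))
    if "InverseVariance" in want:
        off = idiff > 0
        feats["InverseVariance"] = np.array([
            (P[d][off] / idiff[off] ** 2).sum() if off.any() else 0.0
            for d in range(D)])
    if "MaximumProbability" in want:
        feats["MaximumProbability"] = P.max(axis=(1, 2))
    if "SumSquares" in want:
        feats["SumSquares"] = (P * (ii[None, :, :] - ux[:, None, None]) ** 2
                               ).sum(axis=(1, 2))

    if "MCC" in want:
        mcc = np.empty(D)
        for d in range(D):
            occ = px[d] > 0
            if occ.sum() <= 1:
                mcc[d] = 1.0
                continue
            p = P[d][np.ix_(occ, occ)]
            pxo = px[d][occ]
            # Q = Dx^-1 P Dy^-1 P^T shares its spectrum with the symmetric
            # S = Dx^-1/2 P Dy^-1 P^T Dx^-1/2 (similarity); symmetrized P
            # means px == py
            root = np.sqrt(pxo)
            b = (p / root[:, None]) / root[None, :]
            ev = np.linalg.eigvalsh(b @ b.T)
            mcc[d] = np.sqrt(max(ev[-2], 0.0))
        feats["MCC"] = mcc

    return {k: float(np.mean(v)) for k, v in feats.items() if k in want}


# --------------------------------------------------------------------------
# GLRLM


def glrlm_matrices(droi: DiscretizedROI) -> list[np.ndarray]:
    """Run-length matrices P(level, run_length), one per direction.

    Runs are maximal straight sequences of equal-level ROI voxels; non-ROI
    voxels break runs.
    """
    lv = droi.levels
    coords = np.argwhere(lv > 0)
    levels = lv[lv > 0].astype(np.int64)
    ng = droi.ng
    max_run = int(max(lv.shape))
    mats = []
    for d in DIRECTIONS_13:
        dvec = np.asarray(d)
        w = int((dvec != 0).sum())            # step of the line parameter
        t = coords @ dvec
        keys = coords * w - t[:, None] * dvec  # invariant along the line
        # encode (line key, position) as one sortable integer: consecutive
        # voxels of a line differ by exactly w, different lines by more
        kmin = keys.min(axis=0)
        kspan = keys.max(axis=0) - kmin + 1
        code = ((keys[:, 0] - kmin[0]) * kspan[1] + (keys[:, 1] - kmin[1]))
        code = (code * kspan[2] + (keys[:, 2] - kmin[2]))
        tmin = int(t.min())
        tspan = int(t.max()) - tmin + 1 + w
        code = code * tspan + (t - tmin)
        order = np.argsort(code, kind="stable")
        code_s = code[order]
        lv_s = levels[order]
        new_run = np.ones(len(code_s), dtype=bool)
        if len(code_s) > 1:
            # consecutive voxels of one line differ by w in the code
            new_run[1:] = (code_s[1:] - code_s[:-1] != w) | (lv_s[1:] != lv_s[:-1])
        run_id = np.cumsum(new_run) - 1
        run_len = np.bincount(run_id)
        run_lv = lv_s[new_run]
        mat = np.bincount((run_lv - 1) * max_run + (run_len - 1),
                          minlength=ng * max_run).reshape(ng, max_run).astype(np.float64)
        mats.append(mat)
    return mats


def _rl_family_features(P: np.ndarray, n_voxels: int, kind: str,
                        g: np.ndarray | None = None,
                        r: np.ndarray | None = None) -> dict[str, float]:
    """Shared formulas for run-length (kind='Run') and size-zone (kind='Zone').

    ``g`` and ``r`` carry the gray-level and run-length/zone-size values of
    the matrix rows/columns (defaults: 1..shape).
    """
    ng, nmax = P.shape
    if g is None:
        g = np.arange(1, ng + 1, dtype=np.float64)
    if r is None:
        r = np.arange(1, nmax + 1, dtype=np.float64)
    ns = P.sum()
    pg = P.sum(axis=1)          # per gray level
    pr = P.sum(axis=0)          # per run length / zone size
    p = P / ns
    mu_g = (p.sum(axis=1) * g).sum()
    mu_r = (p.sum(axis=0) * r).sum()

    if kind == "Run":
        names = {
            "ShortRunEmphasis": (pr / r ** 2).sum() / ns,
            "LongRunEmphasis": (pr * r ** 2).sum() / ns,
            "GrayLevelNonUniformity": (pg ** 2).sum() / ns,
            "GrayLevelNonUniformityNormalized": (pg ** 2).sum() / ns ** 2,
            "RunLengthNonUniformity": (pr ** 2).sum() / ns,
            "RunLengthNonUniformityNormalized": (pr ** 2).sum() / ns ** 2,
            "RunPercentage": ns / n_voxels,
            "GrayLevelVariance": (p * ((g[:, None] - mu_g) ** 2)).sum(),
            "RunVariance": (p * ((r[None, :] - mu_r) ** 2)).sum(),
            "RunEntropy": -(p * np.log2(p + _EPS)).sum(),
            "LowGrayLevelRunEmphasis": (pg / g ** 2).sum() / ns,
            "HighGrayLevelRunEmphasis": (pg * g ** 2).sum() / ns,
            "ShortRunLowGrayLevelEmphasis": (P / (g[:, None] ** 2 * r[None, :] ** 2)).sum() / ns,
            "ShortRunHighGrayLevelEmphasis": (P * g[:, None] ** 2 / r[None, :] ** 2).sum() / ns,
            "LongRunLowGrayLevelEmphasis": (P * r[None, :] ** 2 / g[:, None] ** 2).sum() / ns,
            "LongRunHighGrayLevelEmphasis": (P * g[:, None] ** 2 * r[None, :] ** 2).sum() / ns,
        }
    else:
        names = {
            "SmallAreaEmphasis": (pr / r ** 2).sum() / ns,
            "LargeAreaEmphasis": (pr * r ** 2).sum() / ns,
            "GrayLevelNonUniformity": (pg ** 2).sum() / ns,
            "GrayLevelNonUniformityNormalized": (pg ** 2).sum() / ns ** 2,
            "SizeZoneNonUniformity": (pr ** 2).sum() / ns,
            "SizeZoneNonUniformityNormalized": (pr ** 2).sum() / ns ** 2,
            "ZonePercentage": ns / n_voxels,
            "GrayLevelVariance": (p * ((g[:, None] - mu_g) ** 2)).sum(),
            "ZoneVariance": (p * ((r[None, :] - mu_r) ** 2)).sum(),
            "ZoneEntropy": -(p * np.log2(p + _EPS)).sum(),
            "LowGrayLevelZoneEmphasis": (pg / g ** 2).sum() / ns,
            "HighGrayLevelZoneEmphasis": (pg * g ** 2).sum() / ns,
            "SmallAreaLowGrayLevelEmphasis": (P / (g[:, None] ** 2 * r[None, :] ** 2)).sum() / ns,
            "SmallAreaHighGrayLevelEmphasis": (P * g[:, None] ** 2 / r[None, :] ** 2).sum() / ns,
            "LargeAreaLowGrayLevelEmphasis": (P * r[None, :] ** 2 / g[:, None] ** 2).sum() / ns,
            "LargeAreaHighGrayLevelEmphasis": (P * g[:, None] ** 2 * r[None, :] ** 2).sum() / ns,
        }
    return {k: float(v) for k, v in names.items()}


def glrlm_features(droi: DiscretizedROI) -> dict[str, float]:
    per_dir = [_rl_family_features(P, droi.n_voxels, "Run")
               for P in glrlm_matrices(droi)]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLSZM


def _glszm_entries(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray]:
    """(gray level, zone size) of every 26-connected zone."""
    lv = droi.levels
    structure = np.ones((3, 3, 3), dtype=bool)
    order = np.argsort(lv.ravel(), kind="stable")
    flat = lv.ravel()[order]
    start = np.searchsorted(flat, 1)          # skip background
    coords = np.column_stack(np.unravel_index(order[start:], lv.shape))
    flat = flat[start:]
    bounds = np.flatnonzero(np.diff(flat)) + 1
    zones_g, zones_s = [], []
    for seg, g in zip(np.split(coords, bounds),
                      np.concatenate(([flat[0]], flat[bounds])) if len(flat) else []):
        lo = seg.min(axis=0)
        hi = seg.max(axis=0) + 1
        box = np.zeros(tuple(hi - lo), dtype=bool)
        box[tuple((seg - lo).T)] = True
        labeled, n = ndimage.label(box, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        zones_g.extend([int(g)] * n)
        zones_s.extend(sizes.tolist())
    return np.asarray(zones_g, dtype=np.int64), np.asarray(zones_s, dtype=np.int64)


def glszm_matrix(droi: DiscretizedROI) -> np.ndarray:
    """Size-zone matrix P(level, zone_size) with 26-connected zones."""
    zg, zs = _glszm_entries(droi)
    P = np.zeros((droi.ng, int(zs.max())))
    np.add.at(P, (zg - 1, zs - 1), 1.0)
    return P


def glszm_features(droi: DiscretizedROI) -> dict[str, float]:
    zg, zs = _glszm_entries(droi)
    # compact representation: rows/columns restricted to occupied gray
    # levels and observed zone sizes, carrying their actual values
    gv, gi = np.unique(zg, return_inverse=True)
    sv, si = np.unique(zs, return_inverse=True)
    P = np.zeros((len(gv), len(sv)))
    np.add.at(P, (gi, si), 1.0)
    return _rl_family_features(P, droi.n_voxels, "Zone",
                               g=gv.astype(np.float64), r=sv.astype(np.float64))


# --------------------------------------------------------------------------
# GLDM


def gldm_matrix(droi: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P(level, dependence_count); count includes the
    center voxel, so it ranges 1..27."""
    lv = droi.levels
    dep = np.ones(lv.shape, dtype=np.int64)     # the voxel itself
    for d in OFFSETS_26:
        a, b = _shifted_views(lv, d)
        hit = (a > 0) & (b > 0) & (np.abs(a.astype(np.int64) - b) <= alpha)
        # a-view covers a sub-box of lv; scatter back via the same slicing
        sl_a = tuple(slice(0, n - o) if o >= 0 else slice(-o, n)
                     for o, n in zip(d, lv.shape))
        tmp = np.zeros(lv.shape, dtype=np.int64)
        tmp[sl_a] = hit.reshape(tmp[sl_a].shape)
        dep += tmp
    roi = lv > 0
    levels = lv[roi].astype(np.int64)
    deps = dep[roi]
    P = np.bincount((levels - 1) * 27 + (deps - 1),
                    minlength=droi.ng * 27).reshape(droi.ng, 27).astype(np.float64)
    return P[:, :deps.max()]


def gldm_features(droi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    P = gldm_matrix(droi, alpha)
    ng, nd = P.shape
    g = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nd + 1, dtype=np.float64)
    nz = P.sum()
    pg = P.sum(axis=1)
    pj = P.sum(axis=0)
    p = P / nz
    mu_g = (p.sum(axis=1) * g).sum()
    mu_j = (p.sum(axis=0) * j).sum()
    feats = {
        "SmallDependenceEmphasis": (pj / j ** 2).sum() / nz,
        "LargeDependenceEmphasis": (pj * j ** 2).sum() / nz,
        "GrayLevelNonUniformity": (pg ** 2).sum() / nz,
        "DependenceNonUniformity": (pj ** 2).sum() / nz,
        "DependenceNonUniformityNormalized": (pj ** 2).sum() / nz ** 2,
        "GrayLevelVariance": (p * (g[:, None] - mu_g) ** 2).sum(),
        "DependenceVariance": (p * (j[None, :] - mu_j) ** 2).sum(),
        "DependenceEntropy": -(p * np.log2(p + _EPS)).sum(),
        "LowGrayLevelEmphasis": (pg / g ** 2).sum() / nz,
        "HighGrayLevelEmphasis": (pg * g ** 2).sum() / nz,
        "SmallDependenceLowGrayLevelEmphasis": (P / (g[:, None] ** 2 * j[None, :] ** 2)).sum() / nz,
        "SmallDependenceHighGrayLevelEmphasis": (P * g[:, None] ** 2 / j[None, :] ** 2).sum() / nz,
        "LargeDependenceLowGrayLevelEmphasis": (P * j[None, :] ** 2 / g[:, None] ** 2).sum() / nz,
        "LargeDependenceHighGrayLevelEmphasis": (P * g[:, None] ** 2 * j[None, :] ** 2).sum() / nz,
    }
    return {k: float(v) for k, v in feats.items()}


# --------------------------------------------------------------------------
# NGTDM


def ngtdm_table(droi: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occupancy n_i and summed absolute deviation s_i.

    s_i sums |i - A(v)| over ROI voxels of level i, where A(v) is the mean
    level of the voxel's 26-neighbours inside the ROI; voxels with no ROI
    neighbour are excluded.  Returns (n, s, n_valid_voxels).
    """
    lv = droi.levels.astype(np.float64)
    roi = droi.levels > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_sum = ndimage.convolve(lv * roi, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(roi.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = roi & (nbr_cnt > 0)
    ivals = droi.levels[valid]
    a = nbr_sum[valid] / nbr_cnt[valid]
    n = np.bincount(ivals, minlength=droi.ng + 1)[1:].astype(np.float64)
    s = np.zeros(droi.ng)
    np.add.at(s, ivals - 1, np.abs(ivals - a))
    return n, s, int(valid.sum())


def ngtdm_features(droi: DiscretizedROI) -> dict[str, float]:
    n, s, nvp = ngtdm_table(droi)
    if nvp == 0:
        # isolated voxels only: no neighbourhood exists
        return {k: 0.0 for k in
                ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")} | {
                    "Coarseness": 1e6}
    p = n / nvp
    g = np.arange(1, droi.ng + 1, dtype=np.float64)
    occ = p > 0
    ngp = int(occ.sum())
    ps = (p * s).sum()

    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        gi = g[occ]
        pi = p[occ]
        si = s[occ]
        dif2 = (gi[:, None] - gi[None, :]) ** 2
        contrast = ((pi[:, None] * pi[None, :] * dif2).sum()
                    / (ngp * (ngp - 1))) * (s.sum() / nvp)
        denom = np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum()
        busyness = ps / denom if denom > 0 else 0.0
        pairs = (np.abs(gi[:, None] - gi[None, :])
                 * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                 / (pi[:, None] + pi[None, :]))
        complexity = pairs.sum() / nvp
        strength = (((pi[:, None] + pi[None, :]) * dif2).sum() / s.sum()
                    if s.sum() > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
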