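"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain enumeration (nested loops, all-pairs
distances, explicit sums) so it shares no code path with the package; it is
deliberately slow and only ever applied to tiny inputs.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy import stats

ALL_26 = [(dx, dy, dz)
          for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
          if (dx, dy, dz) != (0, 0, 0)]
HALF_13 = [d for d in ALL_26 if d > (0, 0, 0)]


def _in_grid(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


# --------------------------------------------------------------------------
# GLCM


def glcm_matrix_pairs(levels, d):
    """Ordered-pair counts for offsets +d and -d combined (= symmetrized)."""
    ng = int(levels.max())
    P = np.zeros((ng, ng))
    shape = levels.shape
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        for sign in (1, -1):
            q = tuple(p[a] + sign * d[a] for a in range(3))
            if _in_grid(q, shape) and levels[q] > 0:
                P[levels[p] - 1, levels[q] - 1] += 1
    return P


def glcm_features_naive(levels):
    ng = int(levels.max())
    eps = np.spacing(1.0)
    per_dir = []
    for d in HALF_13:
        M = glcm_matrix_pairs(levels, d)
        if M.sum() == 0:
            continue
        P = M / M.sum()
        px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
        py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
        ux = sum((i + 1) * px[i] for i in range(ng))
        uy = sum((j + 1) * py[j] for j in range(ng))
        sx = math.sqrt(sum(px[i] * ((i + 1) - ux) ** 2 for i in range(ng)))
        sy = math.sqrt(sum(py[j] * ((j + 1) - uy) ** 2 for j in range(ng)))
        psum = [0.0] * (2 * ng + 1)
        pdif = [0.0] * ng
        for i in range(ng):
            for j in range(ng):
                psum[(i + 1) + (j + 1)] += P[i, j]
                pdif[abs(i - j)] += P[i, j]
        f = {}
        f["Autocorrelation"] = sum((i + 1) * (j + 1) * P[i, j]
                                   for i in range(ng) for j in range(ng))
        f["JointAverage"] = ux
        for name, power in (("ClusterTendency", 2), ("ClusterShade", 3),
                            ("ClusterProminence", 4)):
            f[name] = sum(((i + 1) + (j + 1) - ux - uy) ** power * P[i, j]
                          for i in range(ng) for j in range(ng))
        f["Contrast"] = sum((i - j) ** 2 * P[i, j]
                            for i in range(ng) for j in range(ng))
        cov = sum((i + 1) * (j + 1) * P[i, j] for i in range(ng)
                  for j in range(ng)) - ux * uy
        f["Correlation"] = cov / (sx * sy + eps) if sx * sy > 0 else 1.0
        da = sum(k * pdif[k] for k in range(ng))
        f["DifferenceAverage"] = da
        f["DifferenceEntropy"] = -sum(pdif[k] * math.log2(pdif[k] + eps)
                                      for k in range(ng))
        f["DifferenceVariance"] = sum((k - da) ** 2 * pdif[k] for k in range(ng))
        f["SumAverage"] = sum(k * psum[k] for k in range(2, 2 * ng + 1))
        f["SumEntropy"] = -sum(psum[k] * math.log2(psum[k] + eps)
                               for k in range(2, 2 * ng + 1))
        f["JointEnergy"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
        hxy = -sum(P[i, j] * math.log2(P[i, j] + eps)
                   for i in range(ng) for j in range(ng))
        f["JointEntropy"] = hxy
        hx = -sum(px[i] * math.log2(px[i] + eps) for i in range(ng))
        hy = -sum(py[j] * math.log2(py[j] + eps) for j in range(ng))
        hxy1 = -sum(P[i, j] * math.log2(px[i] * py[j] + eps)
                    for i in range(ng) for j in range(ng))
        hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j] + eps)
                    for i in range(ng) for j in range(ng))
        f["Imc1"] = (hxy - hxy1) / (max(hx, hy) + eps) if max(hx, hy) > 0 else 0.0
        f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
        f["Idm"] = sum(P[i, j] / (1.0 + (i - j) ** 2)
                       for i in range(ng) for j in range(ng))
        f["Idmn"] = sum(P[i, j] / (1.0 + ((i - j) / ng) ** 2)
                        for i in range(ng) for j in range(ng))
        f["Id"] = sum(P[i, j] / (1.0 + abs(i - j))
                      for i in range(ng) for j in range(ng))
        f["Idn"] = sum(P[i, j] / (1.0 + abs(i - j) / ng)
                       for i in range(ng) for j in range(ng))
        f["InverseVariance"] = sum(P[i, j] / (i - j) ** 2
                                   for i in range(ng) for j in range(ng) if i != j)
        f["MaximumProbability"] = max(P[i, j] for i in range(ng) for j in range(ng))
        f["SumSquares"] = sum(((i + 1) - ux) ** 2 * P[i, j]
                              for i in range(ng) for j in range(ng))
        occ = [i for i in range(ng) if px[i] > 0]
        if len(occ) <= 1:
            f["MCC"] = 1.0
        else:
            Q = np.zeros((len(occ), len(occ)))
            for a, i in enumerate(occ):
                for b, j in enumerate(occ):
                    Q[a, b] = sum(P[i, k] * P[j, k] / (px[i] * py[k])
                                  for k in range(ng) if py[k] > 0)
            ev = sorted(np.real(np.linalg.eigvals(Q)))
            f["MCC"] = math.sqrt(max(ev[-2], 0.0))
        per_dir.append(f)
    if not per_dir:
        return None
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLRLM


def glrlm_runs(levels, d):
    """All maximal runs (level, length) along direction d, by walking lines."""
    shape = levels.shape
    runs = []
    for p in np.ndindex(shape):
        prev = tuple(p[a] - d[a] for a in range(3))
        # p starts a line iff its predecessor is off-grid
        if _in_grid(prev, shape):
            continue
        line = []
        q = p
        while _in_grid(q, shape):
            line.append(levels[q])
            q = tuple(q[a] + d[a] for a in range(3))
        run_level, run_len = 0, 0
        for v in line + [0]:
            if v == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    runs.append((run_level, run_len))
                run_level, run_len = v, 1
    return runs


def _rl_features_naive(entries, n_voxels, kind):
    """entries: list of (gray level, run length / zone size[, count])."""
    eps = np.spacing(1.0)
    expanded = []
    for e in entries:
        if len(e) == 3:
            expanded.extend([(e[0], e[1])] * int(e[2]))
        else:
            expanded.append(tuple(e))
    ns = len(expanded)
    glv = [g for g, _ in expanded]
    rlv = [r for _, r in expanded]
    mu_g = sum(glv) / ns
    mu_r = sum(rlv) / ns
    from collections import Counter
    by_g = Counter(glv)
    by_r = Counter(rlv)
    by_gr = Counter(expanded)
    f = {}
    f["short"] = sum(1.0 / r ** 2 for r in rlv) / ns
    f["long"] = sum(float(r) ** 2 for r in rlv) / ns
    f["gln"] = sum(c ** 2 for c in by_g.values()) / ns
    f["glnn"] = sum(c ** 2 for c in by_g.values()) / ns ** 2
    f["rln"] = sum(c ** 2 for c in by_r.values()) / ns
    f["rlnn"] = sum(c ** 2 for c in by_r.values()) / ns ** 2
    f["pct"] = ns / n_voxels
    f["glv"] = sum((g - mu_g) ** 2 for g in glv) / ns
    f["rlv"] = sum((r - mu_r) ** 2 for r in rlv) / ns
    f["entropy"] = -sum((c / ns) * math.log2(c / ns + eps)
                        for c in by_gr.values())
    f["lgl"] = sum(1.0 / g ** 2 for g in glv) / ns
    f["hgl"] = sum(float(g) ** 2 for g in glv) / ns
    f["sl"] = sum(1.0 / (g ** 2 * r ** 2) for g, r in expanded) / ns
    f["sh"] = sum(g ** 2 / r ** 2 for g, r in expanded) / ns
    f["ll"] = sum(r ** 2 / g ** 2 for g, r in expanded) / ns
    f["lh"] = sum(float(g * r) ** 2 for g, r in expanded) / ns
    if kind == "Run":
        names = {"ShortRunEmphasis": "short", "LongRunEmphasis": "long",
                 "GrayLevelNonUniformity": "gln",
                 "GrayLevelNonUniformityNormalized": "glnn",
                 "RunLengthNonUniformity": "rln",
                 "RunLengthNonUniformityNormalized": "rlnn",
                 "RunPercentage": "pct", "GrayLevelVariance": "glv",
                 "RunVariance": "rlv", "RunEntropy": "entropy",
                 "LowGrayLevelRunEmphasis": "lgl",
                 "HighGrayLevelRunEmphasis": "hgl",
                 "ShortRunLowGrayLevelEmphasis": "sl",
                 "ShortRunHighGrayLevelEmphasis": "sh",
                 "LongRunLowGrayLevelEmphasis": "ll",
                 "LongRunHighGrayLevelEmphasis": "lh"}
    else:
        names = {"SmallAreaEmphasis": "short", "LargeAreaEmphasis": "long",
                 "GrayLevelNonUniformity": "gln",
                 "GrayLevelNonUniformityNormalized": "glnn",
                 "SizeZoneNonUniformity": "rln",
                 "SizeZoneNonUniformityNormalized": "rlnn",
                 "ZonePercentage": "pct", "GrayLevelVariance": "glv",
                 "ZoneVariance": "rlv", "ZoneEntropy": "entropy",
                 "LowGrayLevelZoneEmphasis": "lgl",
                 "HighGrayLevelZoneEmphasis": "hgl",
                 "SmallAreaLowGrayLevelEmphasis": "sl",
                 "SmallAreaHighGrayLevelEmphasis": "sh",
                 "LargeAreaLowGrayLevelEmphasis": "ll",
                 "LargeAreaHighGrayLevelEmphasis": "lh"}
    return {k: float(f[v]) for k, v in names.items()}


def glrlm_features_naive(levels):
    n_voxels = int((levels > 0).sum())
    per_dir = []
    for d in HALF_13:
        runs = glrlm_runs(levels, d)
        per_dir.append(_rl_features_naive(runs, n_voxels, "Run"))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# --------------------------------------------------------------------------
# GLSZM (zones by breadth-first search, 26-connected)


def glszm_zones(levels):
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in np.ndindex(shape):
        if levels[p] == 0 or seen[p]:
            continue
        g = levels[p]
        size = 0
        queue = deque([p])
        seen[p] = True
        while queue:
            q = queue.popleft()
            size += 1
            for d in ALL_26:
                r = tuple(q[a] + d[a] for a in range(3))
                if _in_grid(r, shape) and not seen[r] and levels[r] == g:
                    seen[r] = True
                    queue.append(r)
        zones.append((int(g), size))
    return zones


def glszm_features_naive(levels):
    return _rl_features_naive(glszm_zones(levels), int((levels > 0).sum()), "Zone")


# --------------------------------------------------------------------------
# GLDM


def gldm_features_naive(levels, alpha=0):
    shape = levels.shape
    entries = []
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        dep = 1  # the center voxel itself
        for d in ALL_26:
            q = tuple(p[a] + d[a] for a in range(3))
            if _in_grid(q, shape) and levels[q] > 0 \
                    and abs(int(levels[p]) - int(levels[q])) <= alpha:
                dep += 1
        entries.append((int(levels[p]), dep))
    eps = np.spacing(1.0)
    nz = len(entries)
    from collections import Counter
    by_g = Counter(g for g, _ in entries)
    by_j = Counter(j for _, j in entries)
    by_gj = Counter(entries)
    mu_g = sum(g for g, _ in entries) / nz
    mu_j = sum(j for _, j in entries) / nz
    return {
        "SmallDependenceEmphasis": sum(1.0 / j ** 2 for _, j in entries) / nz,
        "LargeDependenceEmphasis": sum(float(j) ** 2 for _, j in entries) / nz,
        "GrayLevelNonUniformity": sum(c ** 2 for c in by_g.values()) / nz,
        "DependenceNonUniformity": sum(c ** 2 for c in by_j.values()) / nz,
        "DependenceNonUniformityNormalized": sum(c ** 2 for c in by_j.values()) / nz ** 2,
        "GrayLevelVariance": sum((g - mu_g) ** 2 for g, _ in entries) / nz,
        "DependenceVariance": sum((j - mu_j) ** 2 for _, j in entries) / nz,
        "DependenceEntropy": -sum((c / nz) * math.log2(c / nz + eps)
                                  for c in by_gj.values()),
        "LowGrayLevelEmphasis": sum(1.0 / g ** 2 for g, _ in entries) / nz,
        "HighGrayLevelEmphasis": sum(float(g) ** 2 for g, _ in entries) / nz,
        "SmallDependenceLowGrayLevelEmphasis":
            sum(1.0 / (g ** 2 * j ** 2) for g, j in entries) / nz,
        "SmallDependenceHighGrayLevelEmphasis":
            sum(g ** 2 / j ** 2 for g, j in entries) / nz,
        "LargeDependenceLowGrayLevelEmphasis":
            sum(j ** 2 / g ** 2 for g, j in entries) / nz,
        "LargeDependenceHighGrayLevelEmphasis":
            sum(float(g * j) ** 2 for g, j in entries) / nz,
    }


# --------------------------------------------------------------------------
# NGTDM


def ngtdm_features_naive(levels):
    shape = levels.shape
    ng = int(levels.max())
    n = [0.0] * (ng + 1)
    s = [0.0] * (ng + 1)
    nvp = 0
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        nbrs = []
        for d in ALL_26:
            q = tuple(p[a] + d[a] for a in range(3))
            if _in_grid(q, shape) and levels[q] > 0:
                nbrs.append(int(levels[q]))
        if not nbrs:
            continue
        nvp += 1
        i = int(levels[p])
        n[i] += 1
        s[i] += abs(i - sum(nbrs) / len(nbrs))
    if nvp == 0:
        return {"Coarseness": 1e6, "Contrast": 0.0, "Busyness": 0.0,
                "Complexity": 0.0, "Strength": 0.0}
    p_i = [c / nvp for c in n]
    occ = [i for i in range(1, ng + 1) if p_i[i] > 0]
    ngp = len(occ)
    ps = sum(p_i[i] * s[i] for i in occ)
    out = {"Coarseness": 1.0 / ps if ps > 0 else 1e6}
    if ngp > 1:
        out["Contrast"] = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                               for i in occ for j in occ)
                           / (ngp * (ngp - 1))) * (sum(s[1:]) / nvp)
        denom = sum(abs(i * p_i[i] - j * p_i[j]) for i in occ for j in occ)
        out["Busyness"] = ps / denom if denom > 0 else 0.0
        out["Complexity"] = sum(abs(i - j) * (p_i[i] * s[i] + p_i[j] * s[j])
                                / (p_i[i] + p_i[j])
                                for i in occ for j in occ) / nvp
        tot_s = sum(s[1:])
        out["Strength"] = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                               for i in occ for j in occ) / tot_s
                           if tot_s > 0 else 0.0)
    else:
        out.update({"Contrast": 0.0, "Busyness": 0.0, "Complexity": 0.0,
                    "Strength": 0.0})
    return {k: float(v) for k, v in out.items()}


# --------------------------------------------------------------------------
# First-order


def firstorder_features_naive(values, hist_counts, spacing):
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    p10, p25, p75, p90 = (float(np.percentile(values, q)) for q in (10, 25, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    probs = [c / n for c in hist_counts if c > 0]
    energy = sum(v ** 2 for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": energy * spacing[0] * spacing[1] * spacing[2],
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": float(np.median(values)),
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": (sum((v - mean) ** 3 for v in x) / n) / sd ** 3 if sd > 0 else 0.0,
        "Kurtosis": (sum((v - mean) ** 4 for v in x) / n) / var ** 2 if sd > 0 else 0.0,
        "Variance": var,
        "Uniformity": sum(p ** 2 for p in probs),
    }


# --------------------------------------------------------------------------
# Geometry metrics


def boundary_set(mask):
    shape = mask.shape
    out = []
    for p in np.ndindex(shape):
        if not mask[p]:
            continue
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            q = tuple(p[a] + d[a] for a in range(3))
            if not _in_grid(q, shape) or not mask[q]:
                out.append(p)
                break
    return out


def _dist(p, q, spacing):
    return math.sqrt(sum(((p[a] - q[a]) * spacing[a]) ** 2 for a in range(3)))


def dice_naive(a, b):
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def surface_dice_naive(a, b, spacing, tol):
    sa = boundary_set(a)
    sb = boundary_set(b)
    hits = sum(1 for p in sa if min(_dist(p, q, spacing) for q in sb) <= tol)
    hits += sum(1 for q in sb if min(_dist(p, q, spacing) for p in sa) <= tol)
    return hits / (len(sa) + len(sb))


def hausdorff_naive(a, b, spacing):
    sa = boundary_set(a)
    sb = boundary_set(b)
    d_ab = max(min(_dist(p, q, spacing) for q in sb) for p in sa)
    d_ba = max(min(_dist(p, q, spacing) for p in sa) for q in sb)
    return max(d_ab, d_ba)


# --------------------------------------------------------------------------
# ICC(A,1) via explicit cell sums (independent of the package's ANOVA path)


def icc_a1_naive(y, alpha=0.05):
    """Point estimate and F-based 95% bounds from explicit sums of squares."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.sum() / (n * k)
    msr = sum((row.sum() / k - grand) ** 2 for row in y) * k / (n - 1)
    msc = sum((y[:, j].sum() / n - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (y[i, j] - y[i].sum() / k - y[:, j].sum() / n + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    nu = ((a * msc + b * mse) ** 2
          / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, nu)
    f2 = stats.f.ppf(1 - alpha / 2, nu, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return icc, lower, upper, (msr, msc, mse)
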