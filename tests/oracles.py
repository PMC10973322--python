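"""Independent brute-force enumerators for the texture feature families.

Everything here is written as plain Python loops directly from the matrix
definitions, deliberately sharing no code with the package implementation.
Used as the reference in oracle-equivalence tests on small random ROIs.
"""

from __future__ import annotations

import math

import numpy as np


def discretize_oracle(hu, mask, bin_width):
    lo = min(hu[idx] for idx in zip(*np.nonzero(mask)))
    lv = np.zeros(hu.shape, dtype=int)
    for idx in zip(*np.nonzero(mask)):
        lv[idx] = int(math.floor((hu[idx] - lo) / bin_width)) + 1
    return lv, int(lv.max())


def _in(shape, p):
    return all(0 <= p[i] < shape[i] for i in range(3))


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix_oracle(lv, mask, ng, angle):
    c = np.zeros((ng, ng))
    for p in zip(*np.nonzero(mask)):
        q = tuple(p[i] + angle[i] for i in range(3))
        if _in(mask.shape, q) and mask[q]:
            c[lv[p] - 1, lv[q] - 1] += 1
            c[lv[q] - 1, lv[p] - 1] += 1  # symmetric
    return c / c.sum() if c.sum() else None


def glcm_features_oracle(lv, mask, ng, angles):
    per = []
    for a in angles:
        p = glcm_matrix_oracle(lv, mask, ng, a)
        if p is not None:
            per.append(_glcm_from_matrix(p))
    keys = per[0].keys()
    return {k: float(np.mean([d[k] for d in per])) for k in keys}


def _glcm_from_matrix(p):
    ng = p.shape[0]
    feats = {}
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum(((i + 1) - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum(((j + 1) - muy) ** 2 * py[j] for j in range(ng)))

    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i, j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i, j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    autoc = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    feats["glcm_Autocorrelation"] = autoc
    feats["glcm_JointAverage"] = mux
    for power, name in ((4, "ClusterProminence"), (3, "ClusterShade"), (2, "ClusterTendency")):
        feats[f"glcm_{name}"] = sum(
            ((i + 1) + (j + 1) - mux - muy) ** power * p[i, j]
            for i in range(ng)
            for j in range(ng)
        )
    feats["glcm_Contrast"] = sum(
        (i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    feats["glcm_Correlation"] = (
        (autoc - mux * muy) / (sigx * sigy) if sigx * sigy > 0 else 1.0
    )
    da = sum(k * v for k, v in pdiff.items())
    feats["glcm_DifferenceAverage"] = da
    feats["glcm_DifferenceEntropy"] = ent(pdiff.values())
    feats["glcm_DifferenceVariance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    feats["glcm_JointEnergy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    hxy = ent(p.ravel())
    feats["glcm_JointEntropy"] = hxy
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    hx, hy = ent(px), ent(py)
    feats["glcm_Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    feats["glcm_Imc2"] = (
        math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))) if ng > 1 else 0.0
    )
    feats["glcm_Idm"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    feats["glcm_Idmn"] = sum(
        p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
    )
    feats["glcm_Id"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    feats["glcm_Idn"] = sum(
        p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    feats["glcm_InverseVariance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    if ng > 1:
        q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                tot = 0.0
                for kk in range(ng):
                    if px[i] > 0 and py[kk] > 0:
                        tot += p[i, kk] * p[j, kk] / (px[i] * py[kk])
                q[i, j] = tot
        eig = sorted(np.real(np.linalg.eigvals(q)))
        feats["glcm_MCC"] = math.sqrt(max(0.0, eig[-2])) if len(eig) > 1 else 1.0
    else:
        feats["glcm_MCC"] = 1.0
    feats["glcm_MaximumProbability"] = float(p.max())
    feats["glcm_SumAverage"] = sum(k * v for k, v in psum.items())
    feats["glcm_SumEntropy"] = ent(psum.values())
    feats["glcm_SumSquares"] = sum(
        ((i + 1) - mux) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    return feats


# ---------------------------------------------------------------------------
# GLDM

def gldm_features_oracle(lv, mask, ng, neighborhood):
    counts = {}
    for p in zip(*np.nonzero(mask)):
        dep = 0
        for d in neighborhood:
            q = tuple(p[i] + d[i] for i in range(3))
            if _in(mask.shape, q) and mask[q] and lv[q] == lv[p]:
                dep += 1
        key = (lv[p], dep + 1)  # dependence size includes the center voxel
        counts[key] = counts.get(key, 0) + 1
    nd = max(j for _, j in counts)
    mat = np.zeros((ng, nd))
    for (i, j), c in counts.items():
        mat[i - 1, j - 1] = c
    nz = mat.sum()
    feats = {}
    mu_i = sum((i + 1) * mat[i, :].sum() / nz for i in range(ng))
    mu_j = sum((j + 1) * mat[:, j].sum() / nz for j in range(nd))
    acc = {
        "gldm_SmallDependenceEmphasis": 0.0,
        "gldm_LargeDependenceEmphasis": 0.0,
        "gldm_GrayLevelVariance": 0.0,
        "gldm_DependenceVariance": 0.0,
        "gldm_DependenceEntropy": 0.0,
        "gldm_LowGrayLevelEmphasis": 0.0,
        "gldm_HighGrayLevelEmphasis": 0.0,
        "gldm_SmallDependenceLowGrayLevelEmphasis": 0.0,
        "gldm_SmallDependenceHighGrayLevelEmphasis": 0.0,
        "gldm_LargeDependenceLowGrayLevelEmphasis": 0.0,
        "gldm_LargeDependenceHighGrayLevelEmphasis": 0.0,
    }
    for i in range(ng):
        for j in range(nd):
            pp = mat[i, j] / nz
            if pp == 0:
                continue
            iv, jv = i + 1, j + 1
            acc["gldm_SmallDependenceEmphasis"] += pp / jv**2
            acc["gldm_LargeDependenceEmphasis"] += pp * jv**2
            acc["gldm_GrayLevelVariance"] += pp * (iv - mu_i) ** 2
            acc["gldm_DependenceVariance"] += pp * (jv - mu_j) ** 2
            acc["gldm_DependenceEntropy"] -= pp * math.log2(pp)
            acc["gldm_LowGrayLevelEmphasis"] += pp / iv**2
            acc["gldm_HighGrayLevelEmphasis"] += pp * iv**2
            acc["gldm_SmallDependenceLowGrayLevelEmphasis"] += pp / (iv**2 * jv**2)
            acc["gldm_SmallDependenceHighGrayLevelEmphasis"] += pp * iv**2 / jv**2
            acc["gldm_LargeDependenceLowGrayLevelEmphasis"] += pp * jv**2 / iv**2
            acc["gldm_LargeDependenceHighGrayLevelEmphasis"] += pp * iv**2 * jv**2
    feats.update(acc)
    feats["gldm_GrayLevelNonUniformity"] = sum(
        mat[i, :].sum() ** 2 for i in range(ng)
    ) / nz
    feats["gldm_DependenceNonUniformity"] = sum(
        mat[:, j].sum() ** 2 for j in range(nd)
    ) / nz
    feats["gldm_DependenceNonUniformityNormalized"] = (
        feats["gldm_DependenceNonUniformity"] / nz
    )
    return feats


# ---------------------------------------------------------------------------
# GLRLM / GLSZM shared formulas

def _rl_features_oracle(mat, np_voxels, names):
    nr = mat.sum()
    ng, nl = mat.shape
    mu_i = sum((i + 1) * mat[i, :].sum() / nr for i in range(ng))
    mu_l = sum((l + 1) * mat[:, l].sum() / nr for l in range(nl))
    f = dict.fromkeys(names.values(), 0.0)
    for i in range(ng):
        for l in range(nl):
            pp = mat[i, l] / nr
            if pp == 0:
                continue
            iv, lt = i + 1, l + 1
            f[names["short"]] += pp / lt**2
            f[names["long"]] += pp * lt**2
            f[names["glv"]] += pp * (iv - mu_i) ** 2
            f[names["sv"]] += pp * (lt - mu_l) ** 2
            f[names["ent"]] -= pp * math.log2(pp)
            f[names["lgl"]] += pp / iv**2
            f[names["hgl"]] += pp * iv**2
            f[names["slgl"]] += pp / (iv**2 * lt**2)
            f[names["shgl"]] += pp * iv**2 / lt**2
            f[names["llgl"]] += pp * lt**2 / iv**2
            f[names["lhgl"]] += pp * iv**2 * lt**2
    f[names["gln"]] = sum(mat[i, :].sum() ** 2 for i in range(ng)) / nr
    f[names["glnn"]] = f[names["gln"]] / nr
    f[names["rln"]] = sum(mat[:, l].sum() ** 2 for l in range(nl)) / nr
    f[names["rlnn"]] = f[names["rln"]] / nr
    f[names["pct"]] = nr / np_voxels
    return f


def glrlm_matrix_oracle(lv, mask, ng, angle):
    """Enumerate maximal runs by walking every line in direction ``angle``."""
    runs = []
    visited = set()
    for p in zip(*np.nonzero(mask)):
        prev = tuple(p[i] - angle[i] for i in range(3))
        if _in(mask.shape, prev) and mask[prev] and lv[prev] == lv[p]:
            continue  # not a run start
        length = 1
        cur = tuple(p[i] + angle[i] for i in range(3))
        while _in(mask.shape, cur) and mask[cur] and lv[cur] == lv[p]:
            length += 1
            cur = tuple(cur[i] + angle[i] for i in range(3))
        runs.append((lv[p], length))
        visited.add(p)
    nl = max(l for _, l in runs)
    mat = np.zeros((ng, nl))
    for g, l in runs:
        mat[g - 1, l - 1] += 1
    return mat


def glrlm_features_oracle(lv, mask, ng, angles, names):
    np_voxels = int(mask.sum())
    per = [
        _rl_features_oracle(glrlm_matrix_oracle(lv, mask, ng, a), np_voxels, names)
        for a in angles
    ]
    return {k: float(np.mean([d[k] for d in per])) for k in per[0]}


def glszm_features_oracle(lv, mask, ng, neighborhood, names):
    """Zones by explicit flood fill over equal-level connected voxels."""
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        g = lv[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in neighborhood:
                q = tuple(p[i] + d[i] for i in range(3))
                if _in(mask.shape, q) and mask[q] and not seen[q] and lv[q] == g:
                    seen[q] = True
                    stack.append(q)
        zones.append((g, size))
    ns = max(s for _, s in zones)
    mat = np.zeros((ng, ns))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return _rl_features_oracle(mat, int(mask.sum()), names)


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features_oracle(lv, mask, ng, neighborhood):
    s = dict.fromkeys(range(1, ng + 1), 0.0)
    n = dict.fromkeys(range(1, ng + 1), 0)
    total = 0
    for p in zip(*np.nonzero(mask)):
        nb = []
        for d in neighborhood:
            q = tuple(p[i] + d[i] for i in range(3))
            if _in(mask.shape, q) and mask[q]:
                nb.append(lv[q])
        if not nb:
            continue
        total += 1
        n[lv[p]] += 1
        s[lv[p]] += abs(lv[p] - sum(nb) / len(nb))
    pi = {i: n[i] / total for i in n if n[i] > 0}
    ngp = len(pi)
    sum_ps = sum(pi[i] * s[i] for i in pi)
    coarseness = min(1.0 / sum_ps if sum_ps > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (
            sum(pi[i] * pi[j] * (i - j) ** 2 for i in pi for j in pi)
            / (ngp * (ngp - 1))
            * sum(s[i] for i in pi)
            / total
        )
        denom = sum(abs(i * pi[i] - j * pi[j]) for i in pi for j in pi)
        busyness = sum_ps / denom if denom > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (pi[i] * s[i] + pi[j] * s[j]) / (pi[i] + pi[j])
                for i in pi
                for j in pi
            )
            / total
        )
        stot = sum(s[i] for i in pi)
        strength = (
            sum((pi[i] + pi[j]) * (i - j) ** 2 for i in pi for j in pi) / stot
            if stot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_Coarseness": coarseness,
        "ngtdm_Contrast": contrast,
        "ngtdm_Busyness": busyness,
        "ngtdm_Complexity": complexity,
        "ngtdm_Strength": strength,
    }
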