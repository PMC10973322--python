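"""Gray-level texture matrices and their features, computed from scratch.

Five matrix families over the discretized ROI:

* GLCM   - co-occurrence of level pairs at a voxel offset (24 features),
  symmetric and normalized per direction, feature values averaged over the
  13 unique 3D directions;
* GLDM   - dependence counts: for each voxel, the number of neighbors in
  the 26-neighborhood with an identical level (similarity tolerance 0);
  the tabulated dependence size includes the center voxel, so sizes start
  at 1 (14 features);
* GLRLM  - run lengths of constant level along each direction, averaged
  over directions (16 features);
* GLSZM  - sizes of 26-connected constant-level zones (16 features);
* NGTDM  - absolute difference between a voxel's level and the mean level
  of its in-mask neighbors, accumulated per level (5 features).

Degenerate single-level matrices yield the documented limits instead of
raising: GLCM Correlation and MCC are 1, Imc1/Imc2 are 0, NGTDM Contrast is
0 and Coarseness saturates at 1e6.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretization import DiscretizationParams, discretize

__all__ = [
    "GLCM_FEATURES",
    "GLDM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]

_COARSENESS_MAX = 1e6

GLCM_FEATURES = [f"glcm_{n}" for n in [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]]

GLDM_FEATURES = [f"gldm_{n}" for n in [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]]

GLRLM_FEATURES = [f"glrlm_{n}" for n in [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]]

GLSZM_FEATURES = [f"glszm_{n}" for n in [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]]

NGTDM_FEATURES = [f"ngtdm_{n}" for n in [
    "Coarseness", "Contrast", "Busyness", "Complexity", "Strength",
]]


def _offset_slices(shape, d):
    """Aligned views such that arr[src] and arr[dst] pair voxel v with v+d."""
    src, dst = [], []
    for n, o in zip(shape, d):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _prep(volume, mask, disc: DiscretizationParams | None):
    disc = disc or DiscretizationParams()
    hu = volume.hu if hasattr(volume, "hu") else np.asarray(volume)
    mask = np.asarray(mask.mask if hasattr(mask, "mask") else mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    # crop to the mask bounding box; all matrix families are translation
    # invariant, and neighborhoods never cross the mask
    sl = tuple(
        slice(int(idx.min()), int(idx.max()) + 1) for idx in np.nonzero(mask)
    )
    hu, mask = hu[sl], mask[sl]
    levels, ng = discretize(hu, mask, disc.bin_width)
    return levels, mask, ng, disc


# ---------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels, mask, ng, angle):
    """Symmetric, normalized co-occurrence matrix for one direction."""
    src, dst = _offset_slices(levels.shape, angle)
    valid = mask[src] & mask[dst]
    if not valid.any():
        return None
    i = levels[src][valid] - 1
    j = levels[dst][valid] - 1
    c = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
    c = c + c.T
    return c / c.sum()


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    # diagonal and cross-diagonal marginals
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    autoc = float((ii * jj * p).sum())
    joint_avg = mux
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sigx * sigy > 0:
        corr = (autoc - mux * muy) / (sigx * sigy)
    else:
        corr = 1.0
    diff_avg = float((k_diff * p_diff).sum())
    diff_ent = ent(p_diff)
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    joint_energy = float((p**2).sum())
    hxy = ent(p.ravel())
    with np.errstate(divide="ignore", invalid="ignore"):
        outer = np.outer(px, py)
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-(outer[outer > 0] * np.log2(outer[outer > 0])).sum())
    hx, hy = ent(px), ent(py)
    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if ng > 1 else 0.0

    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    idmn = float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum())
    id_ = float((p / (1.0 + np.abs(ii - jj))).sum())
    idn = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    off = ii != jj
    inv_var = float((p[off] / (ii[off] - jj[off]) ** 2).sum())

    if ng > 1:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        w = np.where(py > 0, 1.0 / np.where(py > 0, py, 1.0), 0.0)
        a = p * w[None, :]  # p(i,k)/py(k)
        q = a @ p.T  # sum_k p(i,k)/py(k) * p(j,k)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(px[:, None] > 0, q / np.where(px[:, None] > 0, px[:, None], 1.0), 0.0)
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if eig.size > 1 else 1.0
    else:
        mcc = 1.0

    sum_avg = float((k_sum * p_sum).sum())
    sum_ent = ent(p_sum)
    sum_squares = float(((ii - mux) ** 2 * p).sum())

    return {
        "glcm_Autocorrelation": autoc,
        "glcm_JointAverage": joint_avg,
        "glcm_ClusterProminence": float(((ii + jj - mux - muy) ** 4 * p).sum()),
        "glcm_ClusterShade": float(((ii + jj - mux - muy) ** 3 * p).sum()),
        "glcm_ClusterTendency": float(((ii + jj - mux - muy) ** 2 * p).sum()),
        "glcm_Contrast": contrast,
        "glcm_Correlation": float(corr),
        "glcm_DifferenceAverage": diff_avg,
        "glcm_DifferenceEntropy": diff_ent,
        "glcm_DifferenceVariance": diff_var,
        "glcm_JointEnergy": joint_energy,
        "glcm_JointEntropy": hxy,
        "glcm_Imc1": float(imc1),
        "glcm_Imc2": imc2,
        "glcm_Idm": idm,
        "glcm_Idmn": idmn,
        "glcm_Id": id_,
        "glcm_Idn": idn,
        "glcm_InverseVariance": inv_var,
        "glcm_MCC": mcc,
        "glcm_MaximumProbability": float(p.max()),
        "glcm_SumAverage": sum_avg,
        "glcm_SumEntropy": sum_ent,
        "glcm_SumSquares": sum_squares,
    }


def glcm_features(volume, mask, disc: DiscretizationParams | None = None) -> dict[str, float]:
    levels, m, ng, disc = _prep(volume, mask, disc)
    if m.sum() < 2:
        raise ValueError("GLCM requires at least 2 in-mask voxels")
    per_angle = []
    for a in disc.angles:
        p = glcm_matrix(levels, m, ng, a)
        if p is not None:
            per_angle.append(_glcm_single(p))
    if not per_angle:
        raise ValueError("no voxel pairs found for any direction")
    return {k: float(np.mean([d[k] for d in per_angle])) for k in GLCM_FEATURES}


# ---------------------------------------------------------------------------
# GLDM

def gldm_matrix(levels, mask, ng, neighborhood):
    """P(i, j): voxels of level i whose dependence size is j (center included)."""
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in neighborhood:
        src, dst = _offset_slices(levels.shape, d)
        eq = (levels[src] == levels[dst]) & mask[src] & mask[dst]
        view = dep[src]
        view[eq] += 1
    sizes = dep[mask] + 1  # center voxel counts toward its own dependence
    lv = levels[mask]
    nd = int(sizes.max())
    mat = np.bincount((lv - 1) * nd + (sizes - 1), minlength=ng * nd)
    return mat.reshape(ng, nd).astype(float)


def gldm_features(volume, mask, disc: DiscretizationParams | None = None) -> dict[str, float]:
    levels, m, ng, disc = _prep(volume, mask, disc)
    mat = gldm_matrix(levels, m, ng, disc.neighborhood)
    nz = mat.sum()
    p = mat / nz
    i = np.arange(1, mat.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, mat.shape[1] + 1)[None, :].astype(float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(1, mat.shape[0] + 1) * pi).sum())
    mu_j = float((np.arange(1, mat.shape[1] + 1) * pj).sum())
    pn = p[p > 0]
    return {
        "gldm_SmallDependenceEmphasis": float((p / j**2).sum()),
        "gldm_LargeDependenceEmphasis": float((p * j**2).sum()),
        "gldm_GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "gldm_DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "gldm_DependenceNonUniformityNormalized": float((mat.sum(axis=0) ** 2).sum() / nz**2),
        "gldm_GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "gldm_DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "gldm_DependenceEntropy": float(-(pn * np.log2(pn)).sum()),
        "gldm_LowGrayLevelEmphasis": float((p / i**2).sum()),
        "gldm_HighGrayLevelEmphasis": float((p * i**2).sum()),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "gldm_SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "gldm_LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels, mask, ng, angle):
    """Run-length matrix R(i, l) for one direction."""
    shape = levels.shape
    # a run starts where the predecessor along -angle is absent or different
    src, dst = _offset_slices(shape, angle)
    cont = np.zeros(shape, dtype=bool)  # voxel continues the run of v-angle
    cont[dst] = (levels[src] == levels[dst]) & mask[src] & mask[dst]
    starts = mask & ~cont

    coords = np.argwhere(starts)
    lv = levels[starts]
    lengths = np.ones(coords.shape[0], dtype=np.int64)
    d = np.asarray(angle)
    cur = coords + d
    active = np.arange(coords.shape[0])
    while active.size:
        c = cur[active]
        inb = np.all((c >= 0) & (c < np.asarray(shape)), axis=1)
        ok = np.zeros(active.size, dtype=bool)
        if inb.any():
            ci = c[inb]
            flat = (ci[:, 0], ci[:, 1], ci[:, 2])
            ok[inb] = mask[flat] & (levels[flat] == lv[active[inb]])
        lengths[active[ok]] += 1
        active = active[ok]
        cur[active] += d

    nl = int(lengths.max()) if lengths.size else 1
    mat = np.bincount((lv - 1) * nl + (lengths - 1), minlength=ng * nl)
    return mat.reshape(ng, nl).astype(float)


def _rl_style_features(mat, np_voxels, prefix, size_name_map):
    """Shared feature formulas of run-length and size-zone matrices."""
    nr = mat.sum()
    p = mat / nr
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    l = np.arange(1, nl + 1)[None, :].astype(float)
    pi = mat.sum(axis=1)
    pl = mat.sum(axis=0)
    mu_i = float(((np.arange(1, ng + 1)) * pi / nr).sum())
    mu_l = float(((np.arange(1, nl + 1)) * pl / nr).sum())
    pn = p[p > 0]
    base = {
        size_name_map["short"]: float((p / l**2).sum()),
        size_name_map["long"]: float((p * l**2).sum()),
        size_name_map["gln"]: float((pi**2).sum() / nr),
        size_name_map["glnn"]: float((pi**2).sum() / nr**2),
        size_name_map["rln"]: float((pl**2).sum() / nr),
        size_name_map["rlnn"]: float((pl**2).sum() / nr**2),
        size_name_map["pct"]: float(nr / np_voxels),
        size_name_map["glv"]: float((p * (i - mu_i) ** 2).sum()),
        size_name_map["sv"]: float((p * (l - mu_l) ** 2).sum()),
        size_name_map["ent"]: float(-(pn * np.log2(pn)).sum()),
        size_name_map["lgl"]: float((p / i**2).sum()),
        size_name_map["hgl"]: float((p * i**2).sum()),
        size_name_map["slgl"]: float((p / (i**2 * l**2)).sum()),
        size_name_map["shgl"]: float((p * i**2 / l**2).sum()),
        size_name_map["llgl"]: float((p * l**2 / i**2).sum()),
        size_name_map["lhgl"]: float((p * i**2 * l**2).sum()),
    }
    return base


_GLRLM_MAP = {
    "short": "glrlm_ShortRunEmphasis", "long": "glrlm_LongRunEmphasis",
    "gln": "glrlm_GrayLevelNonUniformity",
    "glnn": "glrlm_GrayLevelNonUniformityNormalized",
    "rln": "glrlm_RunLengthNonUniformity",
    "rlnn": "glrlm_RunLengthNonUniformityNormalized",
    "pct": "glrlm_RunPercentage", "glv": "glrlm_GrayLevelVariance",
    "sv": "glrlm_RunVariance", "ent": "glrlm_RunEntropy",
    "lgl": "glrlm_LowGrayLevelRunEmphasis",
    "hgl": "glrlm_HighGrayLevelRunEmphasis",
    "slgl": "glrlm_ShortRunLowGrayLevelEmphasis",
    "shgl": "glrlm_ShortRunHighGrayLevelEmphasis",
    "llgl": "glrlm_LongRunLowGrayLevelEmphasis",
    "lhgl": "glrlm_LongRunHighGrayLevelEmphasis",
}

_GLSZM_MAP = {
    "short": "glszm_SmallAreaEmphasis", "long": "glszm_LargeAreaEmphasis",
    "gln": "glszm_GrayLevelNonUniformity",
    "glnn": "glszm_GrayLevelNonUniformityNormalized",
    "rln": "glszm_SizeZoneNonUniformity",
    "rlnn": "glszm_SizeZoneNonUniformityNormalized",
    "pct": "glszm_ZonePercentage", "glv": "glszm_GrayLevelVariance",
    "sv": "glszm_ZoneVariance", "ent": "glszm_ZoneEntropy",
    "lgl": "glszm_LowGrayLevelZoneEmphasis",
    "hgl": "glszm_HighGrayLevelZoneEmphasis",
    "slgl": "glszm_SmallAreaLowGrayLevelEmphasis",
    "shgl": "glszm_SmallAreaHighGrayLevelEmphasis",
    "llgl": "glszm_LargeAreaLowGrayLevelEmphasis",
    "lhgl": "glszm_LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(volume, mask, disc: DiscretizationParams | None = None) -> dict[str, float]:
    levels, m, ng, disc = _prep(volume, mask, disc)
    np_voxels = int(m.sum())
    per_angle = []
    for a in disc.angles:
        mat = glrlm_matrix(levels, m, ng, a)
        per_angle.append(_rl_style_features(mat, np_voxels, "glrlm", _GLRLM_MAP))
    return {k: float(np.mean([d[k] for d in per_angle])) for k in GLRLM_FEATURES}


# ---------------------------------------------------------------------------
# GLSZM

def glszm_matrix(levels, mask, ng, mode="3d"):
    """Zone-size matrix over connected constant-level zones."""
    if mode == "3d":
        struct = np.ones((3, 3, 3), dtype=bool)
    else:  # in-plane 8-connectivity only
        struct = np.zeros((3, 3, 3), dtype=bool)
        struct[:, :, 1] = True
    pairs: dict[tuple[int, int], int] = {}
    max_size = 1
    for g in range(1, ng + 1):
        sel = (levels == g) & mask
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=struct)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            if s > 0:
                pairs[(g, int(s))] = pairs.get((g, int(s)), 0) + 1
                max_size = max(max_size, int(s))
    mat = np.zeros((ng, max_size), dtype=float)
    for (g, s), c in pairs.items():
        mat[g - 1, s - 1] = c
    return mat


def glszm_features(volume, mask, disc: DiscretizationParams | None = None) -> dict[str, float]:
    levels, m, ng, disc = _prep(volume, mask, disc)
    mat = glszm_matrix(levels, m, ng, disc.mode)
    return _rl_style_features(mat, int(m.sum()), "glszm", _GLSZM_MAP)


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features(volume, mask, disc: DiscretizationParams | None = None) -> dict[str, float]:
    levels, m, ng, disc = _prep(volume, mask, disc)
    if disc.mode == "3d":
        kernel = np.ones((3, 3, 3))
        kernel[1, 1, 1] = 0.0
    else:
        kernel = np.zeros((3, 3, 3))
        kernel[:, :, 1] = 1.0
        kernel[1, 1, 1] = 0.0

    lv = levels.astype(float) * m
    nb_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(m.astype(float), kernel, mode="constant", cval=0.0)
    valid = m & (nb_cnt > 0.5)

    n_valid = int(valid.sum())
    s = np.zeros(ng + 1)
    n_i = np.zeros(ng + 1)
    if n_valid:
        diffs = np.abs(levels[valid] - nb_sum[valid] / nb_cnt[valid])
        lv_valid = levels[valid]
        s = np.bincount(lv_valid, weights=diffs, minlength=ng + 1)
        n_i = np.bincount(lv_valid, minlength=ng + 1).astype(float)

    i_idx = np.nonzero(n_i)[0]
    p = n_i / max(n_valid, 1)
    ngp = i_idx.size

    sum_ps = float((p[i_idx] * s[i_idx]).sum())
    coarseness = 1.0 / sum_ps if sum_ps > 0 else _COARSENESS_MAX
    coarseness = min(coarseness, _COARSENESS_MAX)

    if ngp > 1 and n_valid:
        ii, jj = np.meshgrid(i_idx, i_idx, indexing="ij")
        pij = p[ii] * p[jj]
        contrast = float((pij * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1))
        contrast *= float(s[i_idx].sum()) / n_valid
        denom_busy = float(np.abs(ii * p[ii] - jj * p[jj]).sum())
        busyness = sum_ps / denom_busy if denom_busy > 0 else 0.0
        complexity = float(
            (np.abs(ii - jj) * (p[ii] * s[ii] + p[jj] * s[jj]) / (p[ii] + p[jj])).sum()
        ) / n_valid
        s_total = float(s[i_idx].sum())
        strength = (
            float(((p[ii] + p[jj]) * (ii - jj) ** 2).sum()) / s_total if s_total > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "ngtdm_Coarseness": float(coarseness),
        "ngtdm_Contrast": float(contrast),
        "ngtdm_Busyness": float(busyness),
        "ngtdm_Complexity": float(complexity),
        "ngtdm_Strength": float(strength),
    }
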