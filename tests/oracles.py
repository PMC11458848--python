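"""Independent brute-force oracles for the texture families, ICC and AUC.

Everything here is written as plain nested loops over voxels / matrix cells,
deliberately sharing no code with the package implementation: matrices are
assembled voxel by voxel and features evaluated cell by cell from their
definitions.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]

ALL_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _inside(shape, z, y, x):
    return 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]


def _entropy(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


# ----------------------------------------------------------------- GLCM --


def naive_glcm_matrix(levels, mask, direction):
    """Symmetric normalized co-occurrence matrix over present gray levels."""
    present = sorted({int(levels[idx]) for idx in zip(*np.nonzero(mask))})
    index = {g: i for i, g in enumerate(present)}
    m = len(present)
    counts = np.zeros((m, m))
    dz, dy, dx = direction
    for z, y, x in zip(*np.nonzero(mask)):
        z2, y2, x2 = z + dz, y + dy, x + dx
        if _inside(mask.shape, z2, y2, x2) and mask[z2, y2, x2]:
            i, j = index[int(levels[z, y, x])], index[int(levels[z2, y2, x2])]
            counts[i, j] += 1
            counts[j, i] += 1
    total = counts.sum()
    P = counts / total if total > 0 else counts
    return P, present


def naive_glcm_features(levels, mask, direction):
    P, g = naive_glcm_matrix(levels, mask, direction)
    m = len(g)
    if P.sum() == 0:
        P = np.eye(m) / m
    px = [sum(P[i][j] for j in range(m)) for i in range(m)]
    mu = sum(px[i] * g[i] for i in range(m))
    sigma2 = sum(px[i] * (g[i] - mu) ** 2 for i in range(m))

    pd = {}
    ps = {}
    for i in range(m):
        for j in range(m):
            pd[abs(g[i] - g[j])] = pd.get(abs(g[i] - g[j]), 0.0) + P[i][j]
            ps[g[i] + g[j]] = ps.get(g[i] + g[j], 0.0) + P[i][j]
    da = sum(k * v for k, v in pd.items())
    hxy = _entropy([P[i][j] for i in range(m) for j in range(m)])
    hx = _entropy(px)
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * px[j])
        for i in range(m)
        for j in range(m)
        if P[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = _entropy([px[i] * px[j] for i in range(m) for j in range(m)])

    f = {}
    f["Autocorrelation"] = sum(P[i][j] * g[i] * g[j] for i in range(m) for j in range(m))
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
        f[name] = sum(
            P[i][j] * (g[i] + g[j] - 2 * mu) ** power for i in range(m) for j in range(m)
        )
    f["Contrast"] = sum(P[i][j] * (g[i] - g[j]) ** 2 for i in range(m) for j in range(m))
    f["Correlation"] = (f["Autocorrelation"] - mu * mu) / sigma2 if sigma2 > 0 else 1.0
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = _entropy(list(pd.values()))
    f["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in pd.items())
    f["Id"] = sum(P[i][j] / (1 + abs(g[i] - g[j])) for i in range(m) for j in range(m))
    f["Idm"] = sum(P[i][j] / (1 + (g[i] - g[j]) ** 2) for i in range(m) for j in range(m))
    f["Idmn"] = sum(
        P[i][j] / (1 + ((g[i] - g[j]) / m) ** 2) for i in range(m) for j in range(m)
    )
    f["Idn"] = sum(P[i][j] / (1 + abs(g[i] - g[j]) / m) for i in range(m) for j in range(m))
    if m == 1 or hx == 0:
        f["Imc1"] = 0.0
        f["Imc2"] = 0.0
    else:
        f["Imc1"] = (hxy - hxy1) / hx
        f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["InverseVariance"] = sum(
        P[i][j] / (g[i] - g[j]) ** 2 for i in range(m) for j in range(m) if g[i] != g[j]
    )
    f["JointAverage"] = mu
    f["JointEnergy"] = sum(P[i][j] ** 2 for i in range(m) for j in range(m))
    f["JointEntropy"] = hxy
    if m == 1:
        f["MCC"] = 1.0
    else:
        Q = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                for k in range(m):
                    if px[i] > 0 and px[k] > 0:
                        Q[i][j] += P[i][k] * P[j][k] / (px[i] * px[k])
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        f["MCC"] = math.sqrt(max(0.0, ev[-2]))
    f["MaximumProbability"] = max(P[i][j] for i in range(m) for j in range(m))
    f["SumAverage"] = sum(k * v for k, v in ps.items())
    f["SumEntropy"] = _entropy(list(ps.values()))
    f["SumSquares"] = sum(P[i][j] * (g[i] - mu) ** 2 for i in range(m) for j in range(m))
    return f


def naive_glcm_averaged(levels, mask):
    per_dir = []
    for d in OFFSETS_13:
        P, _ = naive_glcm_matrix(levels, mask, d)
        if P.sum() > 0:
            per_dir.append(naive_glcm_features(levels, mask, d))
    if not per_dir:
        per_dir = [naive_glcm_features(levels, mask, OFFSETS_13[0])]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLRLM --


def naive_runs(levels, mask, direction):
    """Enumerate maximal runs by walking each line voxel by voxel."""
    dz, dy, dx = direction
    runs = []
    visited = set()
    for z, y, x in sorted(zip(*np.nonzero(mask))):
        if (z, y, x) in visited:
            continue
        # walk backwards to the start of the run
        sz, sy, sx = z, y, x
        while (
            _inside(mask.shape, sz - dz, sy - dy, sx - dx)
            and mask[sz - dz, sy - dy, sx - dx]
            and levels[sz - dz, sy - dy, sx - dx] == levels[z, y, x]
        ):
            sz, sy, sx = sz - dz, sy - dy, sx - dx
        # walk forwards, collecting the run
        length = 0
        cz, cy, cx = sz, sy, sx
        while (
            _inside(mask.shape, cz, cy, cx)
            and mask[cz, cy, cx]
            and levels[cz, cy, cx] == levels[z, y, x]
        ):
            visited.add((cz, cy, cx))
            length += 1
            cz, cy, cx = cz + dz, cy + dy, cx + dx
        runs.append((int(levels[z, y, x]), length))
    return runs


def naive_rlm_style_features(pairs, n_voxels, kind):
    """The 16 run-length-style features from (gray, size) pairs.

    ``kind`` switches the family-specific names (run vs zone).
    """
    nr = len(pairs)
    grays = [g for g, _ in pairs]
    sizes = [s for _, s in pairs]
    by_gray = {}
    by_size = {}
    joint = {}
    for g, s in pairs:
        by_gray[g] = by_gray.get(g, 0) + 1
        by_size[s] = by_size.get(s, 0) + 1
        joint[(g, s)] = joint.get((g, s), 0) + 1
    mu_g = sum(grays) / nr
    mu_s = sum(sizes) / nr
    sre = sum(1.0 / s**2 for s in sizes) / nr
    lre = sum(float(s) ** 2 for s in sizes) / nr
    gln = sum(v**2 for v in by_gray.values()) / nr
    rln = sum(v**2 for v in by_size.values()) / nr
    out = {
        "GrayLevelNonUniformity": gln,
        "GrayLevelNonUniformityNormalized": gln / nr,
        "GrayLevelVariance": sum((g - mu_g) ** 2 for g in grays) / nr,
        "RunPercentage": nr / n_voxels,
        "RunVariance": sum((s - mu_s) ** 2 for s in sizes) / nr,
        "RunEntropy": _entropy([v / nr for v in joint.values()]),
        "RunLengthNonUniformity": rln,
        "RunLengthNonUniformityNormalized": rln / nr,
        "ShortRunEmphasis": sre,
        "LongRunEmphasis": lre,
        "LowGrayLevelRunEmphasis": sum(1.0 / g**2 for g in grays) / nr,
        "HighGrayLevelRunEmphasis": sum(float(g) ** 2 for g in grays) / nr,
        "ShortRunLowGrayLevelEmphasis": sum(1.0 / (g**2 * s**2) for g, s in pairs) / nr,
        "ShortRunHighGrayLevelEmphasis": sum(g**2 / s**2 for g, s in pairs) / nr,
        "LongRunLowGrayLevelEmphasis": sum(s**2 / g**2 for g, s in pairs) / nr,
        "LongRunHighGrayLevelEmphasis": sum(float(g * s) ** 2 for g, s in pairs) / nr,
    }
    if kind == "zone":
        rename = {
            "RunPercentage": "ZonePercentage",
            "RunVariance": "ZoneVariance",
            "RunEntropy": "ZoneEntropy",
            "RunLengthNonUniformity": "SizeZoneNonUniformity",
            "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
            "ShortRunEmphasis": "SmallAreaEmphasis",
            "LongRunEmphasis": "LargeAreaEmphasis",
            "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
            "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
            "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
            "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
            "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
            "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
        }
        out = {rename.get(k, k): v for k, v in out.items()}
    return out


def naive_glrlm_features(levels, mask):
    n_voxels = int(mask.sum())
    per_dir = []
    for d in OFFSETS_13:
        pairs = naive_runs(levels, mask, d)
        per_dir.append(naive_rlm_style_features(pairs, n_voxels, "run"))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLSZM --


def naive_zones(levels, mask):
    """Flood-fill 26-connected equal-level zones."""
    zones = []
    visited = np.zeros(mask.shape, dtype=bool)
    for z, y, x in sorted(zip(*np.nonzero(mask))):
        if visited[z, y, x]:
            continue
        level = levels[z, y, x]
        stack = [(z, y, x)]
        visited[z, y, x] = True
        size = 0
        while stack:
            cz, cy, cx = stack.pop()
            size += 1
            for dz, dy, dx in ALL_26:
                nz, ny, nx = cz + dz, cy + dy, cx + dx
                if (
                    _inside(mask.shape, nz, ny, nx)
                    and mask[nz, ny, nx]
                    and not visited[nz, ny, nx]
                    and levels[nz, ny, nx] == level
                ):
                    visited[nz, ny, nx] = True
                    stack.append((nz, ny, nx))
        zones.append((int(level), size))
    return zones


def naive_glszm_features(levels, mask):
    return naive_rlm_style_features(naive_zones(levels, mask), int(mask.sum()), "zone")


# ----------------------------------------------------------------- GLDM --


def naive_gldm_pairs(levels, mask, alpha=0):
    pairs = []
    for z, y, x in zip(*np.nonzero(mask)):
        dep = 1
        for dz, dy, dx in ALL_26:
            nz, ny, nx = z + dz, y + dy, x + dx
            if (
                _inside(mask.shape, nz, ny, nx)
                and mask[nz, ny, nx]
                and abs(int(levels[nz, ny, nx]) - int(levels[z, y, x])) <= alpha
            ):
                dep += 1
        pairs.append((int(levels[z, y, x]), dep))
    return pairs


def naive_gldm_features(levels, mask, alpha=0):
    pairs = naive_gldm_pairs(levels, mask, alpha)
    run_style = naive_rlm_style_features(pairs, len(pairs), "run")
    rename = {
        "RunVariance": "DependenceVariance",
        "RunEntropy": "DependenceEntropy",
        "RunLengthNonUniformity": "DependenceNonUniformity",
        "RunLengthNonUniformityNormalized": "DependenceNonUniformityNormalized",
        "ShortRunEmphasis": "SmallDependenceEmphasis",
        "LongRunEmphasis": "LargeDependenceEmphasis",
        "LowGrayLevelRunEmphasis": "LowGrayLevelEmphasis",
        "HighGrayLevelRunEmphasis": "HighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis": "SmallDependenceLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis": "SmallDependenceHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis": "LargeDependenceLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis": "LargeDependenceHighGrayLevelEmphasis",
    }
    out = {rename.get(k, k): v for k, v in run_style.items()}
    # GLDM has no percentage/GLNN features; drop the extraneous ones
    out.pop("RunPercentage", None)
    out.pop("GrayLevelNonUniformityNormalized", None)
    return out


# ---------------------------------------------------------------- NGTDM --


def naive_ngtdm_features(levels, mask):
    entries = []  # (gray, |g - neighbourhood average|)
    for z, y, x in zip(*np.nonzero(mask)):
        neigh = []
        for dz, dy, dx in ALL_26:
            nz, ny, nx = z + dz, y + dy, x + dx
            if _inside(mask.shape, nz, ny, nx) and mask[nz, ny, nx]:
                neigh.append(int(levels[nz, ny, nx]))
        if neigh:
            entries.append((int(levels[z, y, x]), abs(levels[z, y, x] - sum(neigh) / len(neigh))))
    if not entries:
        return {"Busyness": 0.0, "Coarseness": 1e6, "Complexity": 0.0,
                "Contrast": 0.0, "Strength": 0.0}
    nvp = len(entries)
    grays = sorted({g for g, _ in entries})
    n = {g: sum(1 for gg, _ in entries if gg == g) for g in grays}
    s = {g: sum(d for gg, d in entries if gg == g) for g in grays}
    p = {g: n[g] / nvp for g in grays}
    ngp = len(grays)

    denom = sum(p[g] * s[g] for g in grays)
    coarseness = min(1.0 / denom, 1e6) if denom > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(p[a] * p[b] * (a - b) ** 2 for a in grays for b in grays)
            / (ngp * (ngp - 1))
            * sum(s.values())
            / nvp
        )
        busy_den = sum(abs(a * p[a] - b * p[b]) for a in grays for b in grays)
        busyness = denom / busy_den if busy_den > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    complexity = (
        sum(
            abs(a - b) * (p[a] * s[a] + p[b] * s[b]) / (p[a] + p[b])
            for a in grays
            for b in grays
        )
        / nvp
    )
    s_sum = sum(s.values())
    strength = (
        sum((p[a] + p[b]) * (a - b) ** 2 for a in grays for b in grays) / s_sum
        if s_sum > 0
        else 0.0
    )
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


# ------------------------------------------------------------- ICC / AUC --


def naive_icc_one_way(matrix):
    """One-way ANOVA ICC from explicit sums of squares."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_between = 0.0
    ss_within = 0.0
    for i in range(n):
        mean_i = sum(x[i]) / k
        ss_between += k * (mean_i - grand) ** 2
        for j in range(k):
            ss_within += (x[i, j] - mean_i) ** 2
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    if msb + (k - 1) * msw == 0:
        return 1.0
    return (msb - msw) / (msb + (k - 1) * msw)


def naive_rank_auc(labels, scores):
    """Plain rank AUC with 0.5 for score ties."""
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_concordance(times, events, scores):
    """Harrell's C by explicit pair enumeration."""
    num = 0.0
    den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i] or times[i] >= times[j]:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den
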