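"""Independent brute-force oracle implementations used only by tests.

Everything here is written by plain enumeration (explicit Python loops,
breadth-first flood fills, exhaustive scans) so that it shares no code
path with the vectorised implementations it checks.  Only intended for
tiny grids (<= 5x5x5) and toy inputs.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

DIRS13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NBR26 = [(dx, dy, dz)
         for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
         if (dx, dy, dz) != (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= p[a] < shape[a] for a in range(3))


# ---------------------------------------------------------------------------
# matrices by enumeration
# ---------------------------------------------------------------------------

def glcm_by_enumeration(levels, mask, n_levels):
    mat = np.zeros((n_levels, n_levels))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for d in DIRS13:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inside(shape, q) and mask[q]:
                        mat[levels[x, y, z] - 1, levels[q] - 1] += 1
                        mat[levels[q] - 1, levels[x, y, z] - 1] += 1
    return mat


def glrlm_by_enumeration(levels, mask, n_levels):
    shape = levels.shape
    mat = np.zeros((n_levels, max(shape)))
    for d in DIRS13:
        seen = set()
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask[x, y, z] or (x, y, z) in seen:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inside(shape, prev) and mask[prev] \
                            and levels[prev] == levels[x, y, z]:
                        continue  # not a run start
                    g = levels[x, y, z]
                    run = [(x, y, z)]
                    cur = (x + d[0], y + d[1], z + d[2])
                    while _inside(shape, cur) and mask[cur] and levels[cur] == g:
                        run.append(cur)
                        cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                    for p in run:
                        seen.add(p)
                    mat[g - 1, len(run) - 1] += 1
    return mat


def zones_by_flood_fill(levels, mask):
    """26-connected equal-level zones, via explicit BFS."""
    shape = levels.shape
    visited = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z] or visited[x, y, z]:
                    continue
                g = levels[x, y, z]
                q = deque([(x, y, z)])
                visited[x, y, z] = True
                members = []
                while q:
                    p = q.popleft()
                    members.append(p)
                    for d in NBR26:
                        nb = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _inside(shape, nb) and mask[nb] \
                                and not visited[nb] and levels[nb] == g:
                            visited[nb] = True
                            q.append(nb)
                zones.append((int(g), members))
    return zones


def glszm_by_enumeration(levels, mask, n_levels):
    zones = zones_by_flood_fill(levels, mask)
    max_size = max((len(m) for _, m in zones), default=1)
    mat = np.zeros((n_levels, max_size))
    for g, members in zones:
        mat[g - 1, len(members) - 1] += 1
    return mat


def border_distance_by_scan(mask):
    """City-block distance from each ROI voxel to the nearest out-of-ROI
    voxel or image edge, plus one (border voxels have distance 1)."""
    shape = mask.shape
    outside = [(x, y, z)
               for x in range(-1, shape[0] + 1)
               for y in range(-1, shape[1] + 1)
               for z in range(-1, shape[2] + 1)
               if not _inside(shape, (x, y, z)) or not mask[x, y, z]]
    dist = np.zeros(shape, dtype=int)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if mask[x, y, z]:
                    dist[x, y, z] = min(abs(x - o[0]) + abs(y - o[1])
                                        + abs(z - o[2]) for o in outside)
    return dist


def gldzm_by_enumeration(levels, mask, n_levels):
    zones = zones_by_flood_fill(levels, mask)
    dist = border_distance_by_scan(mask)
    max_d = int(dist[mask].max()) if mask.any() else 1
    mat = np.zeros((n_levels, max_d))
    for g, members in zones:
        d = min(dist[p] for p in members)
        mat[g - 1, d - 1] += 1
    return mat


def ngtdm_by_enumeration(levels, mask, n_levels):
    """Returns (n_i, s_i) arrays of the neighbourhood grey-tone difference."""
    shape = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                nb = [levels[x + d[0], y + d[1], z + d[2]]
                      for d in NBR26
                      if _inside(shape, (x + d[0], y + d[1], z + d[2]))
                      and mask[x + d[0], y + d[1], z + d[2]]]
                if not nb:
                    continue
                g = levels[x, y, z]
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(nb) / len(nb))
    return n_i, s_i


def rl_features_by_enumeration(mat, n_voxels, perc_denominator):
    """The 16 shared run/zone-style features, by explicit summation."""
    ns = mat.sum()
    out = {}
    acc = {k: 0.0 for k in ("short", "long", "lg", "hg", "sl", "sh", "ll", "lh")}
    mu_i = mu_j = 0.0
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            c = mat[i, j]
            if c == 0:
                continue
            gi, dj = i + 1, j + 1
            acc["short"] += c / dj**2
            acc["long"] += c * dj**2
            acc["lg"] += c / gi**2
            acc["hg"] += c * gi**2
            acc["sl"] += c / (gi**2 * dj**2)
            acc["sh"] += c * gi**2 / dj**2
            acc["ll"] += c * dj**2 / gi**2
            acc["lh"] += c * gi**2 * dj**2
            mu_i += gi * c / ns
            mu_j += dj * c / ns
    gl_var = j_var = entr = 0.0
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            c = mat[i, j]
            if c == 0:
                continue
            p = c / ns
            gl_var += (i + 1 - mu_i) ** 2 * p
            j_var += (j + 1 - mu_j) ** 2 * p
            entr -= p * math.log2(p)
    si = [mat[i, :].sum() for i in range(mat.shape[0])]
    sj = [mat[:, j].sum() for j in range(mat.shape[1])]
    out.update({
        "short": acc["short"] / ns, "long": acc["long"] / ns,
        "lg": acc["lg"] / ns, "hg": acc["hg"] / ns,
        "sl": acc["sl"] / ns, "sh": acc["sh"] / ns,
        "ll": acc["ll"] / ns, "lh": acc["lh"] / ns,
        "glnu": sum(v**2 for v in si) / ns,
        "glnu_norm": sum(v**2 for v in si) / ns**2,
        "jnu": sum(v**2 for v in sj) / ns,
        "jnu_norm": sum(v**2 for v in sj) / ns**2,
        "perc": ns / perc_denominator,
        "gl_var": gl_var, "j_var": j_var, "entr": entr,
    })
    return out


# ---------------------------------------------------------------------------
# first-order oracles
# ---------------------------------------------------------------------------

def ivh_ix_by_scan(values, frac):
    """Minimum intensity of the ceil(frac * n) most intense voxels."""
    v = sorted(values, reverse=True)
    k = max(int(math.ceil(frac * len(v))), 1)
    return min(v[:k])


def peak_by_counting(data, roi_mask, spacing, radius_mm):
    """Global intensity peak by explicit sphere counting per ROI voxel."""
    shape = data.shape
    best = -np.inf
    rv = [int(math.floor(radius_mm / s)) for s in spacing]
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not roi_mask[x, y, z]:
                    continue
                total, count = 0.0, 0
                for dx in range(-rv[0], rv[0] + 1):
                    for dy in range(-rv[1], rv[1] + 1):
                        for dz in range(-rv[2], rv[2] + 1):
                            if math.sqrt((dx * spacing[0]) ** 2
                                         + (dy * spacing[1]) ** 2
                                         + (dz * spacing[2]) ** 2) \
                                    > radius_mm + 1e-9:
                                continue
                            p = (x + dx, y + dy, z + dz)
                            if _inside(shape, p):
                                total += data[p]
                                count += 1
                best = max(best, total / count)
    return best


def breslow_nll_by_enumeration(eta, times, events):
    """Negative Breslow partial log-likelihood per event, by double loop."""
    eta = list(eta)
    total, d = 0.0, 0
    for i in range(len(eta)):
        if not events[i]:
            continue
        d += 1
        risk = sum(math.exp(eta[j]) for j in range(len(eta))
                   if times[j] >= times[i])
        total += eta[i] - math.log(risk)
    return -total / d


def harrell_c_by_pairs(scores, times, events):
    """Concordance by exhaustive comparable-pair enumeration (risk scores:
    higher score should mean shorter survival)."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be the earlier, observed event
            if not events[i] or times[i] >= times[j]:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def auc_by_pairs(scores, labels):
    num = den = 0.0
    for i in range(len(scores)):
        for j in range(len(scores)):
            if labels[i] == 1 and labels[j] == 0:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den
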