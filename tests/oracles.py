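"""Independent brute-force oracles used to validate the package's fast paths.

Everything here is deliberately naive (double loops, flood fill, literal
formulas) and shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np

FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def boundary_by_scan(mask: np.ndarray) -> np.ndarray:
    """Per-voxel 6-neighbour scan: boundary = any face neighbour outside."""
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for x, y, z in np.argwhere(mask):
        for dx, dy, dz in FACE_OFFSETS:
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                out[x, y, z] = True
                break
            if not mask[nx, ny, nz]:
                out[x, y, z] = True
                break
    return out


def _offsets_for_connectivity(connectivity: int):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(mask: np.ndarray, connectivity: int = 26):
    """Iterative flood fill; returns (labels, sizes list)."""
    offs = _offsets_for_connectivity(connectivity)
    labels = np.zeros(mask.shape, dtype=int)
    sizes = []
    next_label = 0
    shape = mask.shape
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        next_label += 1
        stack = [start]
        labels[start] = next_label
        size = 0
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in offs:
                n = (x + dx, y + dy, z + dz)
                if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1]
                        and 0 <= n[2] < shape[2] and mask[n] and not labels[n]):
                    labels[n] = next_label
                    stack.append(n)
        sizes.append(size)
    return labels, sizes


def assd_bruteforce(ref_boundary: np.ndarray, seg_boundary: np.ndarray,
                    spacing) -> float:
    """All-pairs average symmetric surface distance from boundary masks."""
    sp = np.asarray(spacing, dtype=float)
    p_ref = np.argwhere(ref_boundary) * sp
    p_seg = np.argwhere(seg_boundary) * sp
    # O(n^2): every pairwise distance is formed explicitly, one row at a time
    d_sr = [np.sqrt(((x - p_ref) ** 2).sum(axis=1)).min() for x in p_seg]
    d_rs = [np.sqrt(((x - p_seg) ** 2).sum(axis=1)).min() for x in p_ref]
    return (sum(d_sr) + sum(d_rs)) / (len(p_seg) + len(p_ref))


def confusion_by_enumeration(ref: np.ndarray, seg: np.ndarray, domain: np.ndarray):
    tp = fp = fn = tn = 0
    for idx in map(tuple, np.argwhere(domain)):
        r, s = bool(ref[idx]), bool(seg[idx])
        if r and s:
            tp += 1
        elif s:
            fp += 1
        elif r:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def parzen_double_sum(queries: np.ndarray, points: np.ndarray, h) -> np.ndarray:
    hx, hy = h
    out = []
    for q in queries:
        total = 0.0
        for p in points:
            total += np.exp(-((q[0] - p[0]) ** 2 / (2 * hx ** 2)
                              + (q[1] - p[1]) ** 2 / (2 * hy ** 2)))
        out.append(total / (len(points) * 2 * np.pi * hx * hy))
    return np.asarray(out)


def pearson_textbook(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return float(num / den)


def gmm_em_posteriors(y: np.ndarray, means, covs, priors, n_iter: int):
    """Plain Gaussian-mixture EM; returns posteriors after the final E-step
    computed with the parameters of the (n_iter-1)-th M-step."""
    means = [np.array(m, dtype=float) for m in means]
    covs = [np.array(c, dtype=float) for c in covs]
    priors = np.array(priors, dtype=float)
    K = len(means)
    post = None
    for _ in range(n_iter):
        # E-step
        dens = np.empty((len(y), K))
        for k in range(K):
            d = y - means[k]
            inv = np.linalg.inv(covs[k])
            det = np.linalg.det(covs[k])
            maha = np.einsum("ij,jk,ik->i", d, inv, d)
            dens[:, k] = priors[k] * np.exp(-0.5 * maha) / np.sqrt(
                (2 * np.pi) ** y.shape[1] * det)
        post = dens / dens.sum(axis=1, keepdims=True)
        # M-step
        nk = post.sum(axis=0)
        priors = nk / nk.sum()
        for k in range(K):
            means[k] = (post[:, k, None] * y).sum(axis=0) / nk[k]
            d = y - means[k]
            covs[k] = (post[:, k, None, None]
                       * (d[:, :, None] * d[:, None, :])).sum(axis=0) / nk[k]
    return post, means, covs, priors


def maxmin_strength_threshold(affinities, seeds: np.ndarray, mask: np.ndarray):
    """Exact max-min path strength by threshold connectivity.

    strength(v) = the largest affinity level t such that v reaches a seed
    through face edges all of affinity >= t — evaluated by flood fill at
    every distinct affinity value.  Equals the max-over-paths of the
    min-affinity along the path, by definition of the bottleneck.
    """
    shape = seeds.shape
    levels = sorted({float(a) for arr in affinities for a in arr.ravel()} | {1.0},
                    reverse=True)
    strength = np.zeros(shape)
    strength[seeds] = 1.0
    done = seeds.copy()
    for t in levels:
        if t <= 0:
            break
        # flood fill from seeds through edges with affinity >= t
        reach = seeds.copy()
        frontier = list(map(tuple, np.argwhere(seeds)))
        while frontier:
            x, y, z = frontier.pop()
            for axis, d in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
                n = [x, y, z]
                n[axis] += d
                if not (0 <= n[axis] < shape[axis]):
                    continue
                n = tuple(n)
                if reach[n] or not mask[n]:
                    continue
                edge = list((x, y, z))
                if d < 0:
                    edge[axis] -= 1
                if edge[axis] < 0 or edge[axis] >= shape[axis] - 1:
                    continue
                if affinities[axis][tuple(edge)] >= t:
                    reach[n] = True
                    frontier.append(n)
        newly = reach & ~done
        strength[newly] = t
        done |= newly
    return strength


def maxmin_strength_paths(affinities, seeds: np.ndarray, mask: np.ndarray):
    """Literal enumeration of all simple paths (tiny grids only)."""
    shape = seeds.shape
    coords = [tuple(c) for c in np.argwhere(mask)]
    strength = {c: 0.0 for c in coords}
    for c in map(tuple, np.argwhere(seeds)):
        strength[c] = 1.0

    def edge_aff(a, b):
        diff = [b[i] - a[i] for i in range(3)]
        axis = next(i for i in range(3) if diff[i] != 0)
        e = list(a)
        if diff[axis] < 0:
            e[axis] -= 1
        return float(affinities[axis][tuple(e)])

    def neighbors(c):
        for axis, d in ((0, 1), (0, -1), (1, 1), (1, -1), (2, 1), (2, -1)):
            n = list(c)
            n[axis] += d
            n = tuple(n)
            if all(0 <= n[i] < shape[i] for i in range(3)) and mask[n]:
                yield n

    def dfs(node, min_aff, visited):
        if min_aff > strength[node]:
            strength[node] = min_aff
        for n in neighbors(node):
            if n in visited:
                continue
            dfs(n, min(min_aff, edge_aff(node, n)), visited | {n})

    for s in map(tuple, np.argwhere(seeds)):
        dfs(s, 1.0, {s})
    out = np.zeros(shape)
    for c, v in strength.items():
        out[c] = v
    return out
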