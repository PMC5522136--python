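"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit Python loops / enumeration,
deliberately sharing no code with the package's vectorised paths.
"""

from itertools import combinations, product

import numpy as np

OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _in(shape, v):
    return all(0 <= v[k] < shape[k] for k in range(3))


def bf_glcm(levels, offset, n_levels):
    """Co-occurrence counts by explicit pair enumeration (symmetric)."""
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for v in product(*(range(s) for s in shape)):
        w = tuple(v[k] + offset[k] for k in range(3))
        if not _in(shape, w):
            continue
        i, j = levels[v], levels[w]
        if i >= 0 and j >= 0:
            counts[i, j] += 1
            counts[j, i] += 1
    return counts


def bf_glrlm(levels, offset, n_levels):
    """Run-length counts by walking each line voxel by voxel."""
    shape = levels.shape
    runs = []
    for v in product(*(range(s) for s in shape)):
        if levels[v] < 0:
            continue
        prev = tuple(v[k] - offset[k] for k in range(3))
        if _in(shape, prev) and levels[prev] == levels[v]:
            continue  # not a run start
        length = 1
        cur = v
        while True:
            nxt = tuple(cur[k] + offset[k] for k in range(3))
            if _in(shape, nxt) and levels[nxt] == levels[cur]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((levels[v], length))
    max_len = max((l for _, l in runs), default=1)
    counts = np.zeros((n_levels, max_len + 1), dtype=np.int64)
    for lev, length in runs:
        counts[lev, length] += 1
    return counts


def bf_glzlm(levels, n_levels):
    """Zone counts by breadth-first flood fill over 26-neighborhoods."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for v in product(*(range(s) for s in shape)):
        if levels[v] < 0 or seen[v]:
            continue
        lev = levels[v]
        stack = [v]
        seen[v] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                w = tuple(cur[k] + off[k] for k in range(3))
                if _in(shape, w) and not seen[w] and levels[w] == lev:
                    seen[w] = True
                    stack.append(w)
        zones.append((lev, size))
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((n_levels, max_size + 1), dtype=np.int64)
    for lev, size in zones:
        counts[lev, size] += 1
    return counts


def _bf_directions():
    dirs = []
    for d in OFFSETS_26:
        if tuple(-c for c in d) not in dirs:
            dirs.append(d)
    return dirs


def bf_texture_features(levels, n_levels):
    """All six texture indices from the brute-force matrices, explicit sums."""
    dirs = _bf_directions()
    hom, ent, sre, lre = [], [], [], []
    for off in dirs:
        c = bf_glcm(levels, off, n_levels)
        tot = c.sum()
        if tot > 0:
            h = e = 0.0
            for i in range(n_levels):
                for j in range(n_levels):
                    p = c[i, j] / tot
                    if p > 0:
                        h += p / (1 + abs(i - j))
                        e -= p * np.log2(p)
            hom.append(h)
            ent.append(e)
        r = bf_glrlm(levels, off, n_levels)
        rtot = r.sum()
        if rtot > 0:
            s = l = 0.0
            for i in range(n_levels):
                for length in range(1, r.shape[1]):
                    p = r[i, length] / rtot
                    s += p / length**2
                    l += p * length**2
            sre.append(s)
            lre.append(l)
    z = bf_glzlm(levels, n_levels)
    ztot = z.sum()
    lgze = hgze = 0.0
    for i in range(1, n_levels):
        for size in range(1, z.shape[1]):
            p = z[i, size] / ztot
            lgze += p / i**2
            hgze += p * i**2
    return {
        "Homogeneity": float(np.mean(hom)),
        "Entropy": float(np.mean(ent)),
        "SRE": float(np.mean(sre)),
        "LRE": float(np.mean(lre)),
        "LGZE": lgze,
        "HGZE": hgze,
    }


def bf_auc(scores, labels):
    """AUC by exhaustive concordant/discordant/tied pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    c = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                c += 1.0
            elif p == n:
                c += 0.5
    return c / (len(pos) * len(neg))


def bf_wilcoxon_exact(x, y):
    """Exact two-sided rank-sum p-value by enumerating label assignments.

    Valid for tie-free pooled samples; uses the symmetric two-tailed rule
    P(U <= u_low) + P(U >= n1*n0 - u_low).
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    m = n1 * len(y)

    # U = #(x > y) pairs
    def u_of(subset):
        rest = [v for v in pooled if v not in subset]
        return sum(1 for a in subset for b in rest if a > b)

    u_obs = u_of(set(x))
    lo = min(u_obs, m - u_obs)
    count = 0
    total = 0
    for subset in combinations(pooled, n1):
        u = u_of(set(subset))
        total += 1
        if u <= lo or u >= m - lo:
            count += 1
    return count / total


def bf_delong(scores_a, scores_b, labels):
    """DeLong p-value with explicit placement-value loops."""
    labels = np.asarray(labels).astype(bool)

    def components(scores):
        pos = np.asarray(scores, float)[labels]
        neg = np.asarray(scores, float)[~labels]
        m, n = len(pos), len(neg)
        v10 = np.empty(m)
        v01 = np.empty(n)
        for i, p in enumerate(pos):
            v10[i] = sum(1.0 if p > q else 0.5 if p == q else 0.0 for q in neg) / n
        for j, q in enumerate(neg):
            v01[j] = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos) / m
        return v10, v01, v10.mean()

    v10a, v01a, auc_a = components(scores_a)
    v10b, v01b, auc_b = components(scores_b)
    m, n = len(v10a), len(v01a)

    def cov(u, v):
        return ((u - u.mean()) * (v - v.mean())).sum() / (len(u) - 1)

    var = (
        cov(v10a, v10a) / m + cov(v01a, v01a) / n
        + cov(v10b, v10b) / m + cov(v01b, v01b) / n
        - 2 * (cov(v10a, v10b) / m + cov(v01a, v01b) / n)
    )
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    from scipy.stats import norm

    return float(2 * norm.sf(abs(diff) / np.sqrt(var)))
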