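"""Independent brute-force oracles shared by the unit and acceptance
suites. These deliberately use naive enumeration (dict counting,
explicit walks) and never call the implementation under test."""

import numpy as np

from sarcomics.radiomics import DIRECTIONS_13


def brute_glcm(disc, mask, distance, directions=DIRECTIONS_13):
    """Exhaustive symmetric pair counting for the co-occurrence matrix."""
    pairs = {}
    idx = np.argwhere(mask)
    vox = {tuple(p) for p in idx}
    for p in idx:
        for d in directions:
            q = tuple(p + np.array(d) * distance)
            if q in vox:
                a, b = disc[tuple(p)], disc[q]
                pairs[(a, b)] = pairs.get((a, b), 0) + 1
                pairs[(b, a)] = pairs.get((b, a), 0) + 1
    total = sum(pairs.values())
    return {k: v / total for k, v in pairs.items()} if total else {}


def brute_glcm_stats(P):
    levels = sorted({i for i, _ in P} | {j for _, j in P})
    pi = {i: sum(v for (a, _), v in P.items() if a == i) for i in levels}
    mu = sum(i * pi[i] for i in levels)
    var = sum(pi[i] * (i - mu) ** 2 for i in levels)
    out = {
        "contrast": sum(v * (i - j) ** 2 for (i, j), v in P.items()),
        "energy": sum(v ** 2 for v in P.values()),
        "entropy": -sum(v * np.log2(v) for v in P.values() if v > 0),
        "homogeneity": sum(v / (1 + abs(i - j)) for (i, j), v in P.items()),
        "dissimilarity": sum(v * abs(i - j) for (i, j), v in P.items()),
        "idm": sum(v / (1 + (i - j) ** 2) for (i, j), v in P.items()),
    }
    if var > 0:
        out["correlation"] = sum(v * (i - mu) * (j - mu)
                                 for (i, j), v in P.items()) / var
    else:
        out["correlation"] = 1.0
    return out


def brute_runs(disc, mask, directions=DIRECTIONS_13):
    """Walk every lattice line in each direction and collect
    (gray level, run length) pairs."""
    runs = []
    idx = np.argwhere(mask)
    vox = {tuple(p): disc[tuple(p)] for p in idx}
    for d in directions:
        d = np.array(d)
        for p in idx:
            prev = tuple(p - d)
            if prev in vox and vox[prev] == vox[tuple(p)]:
                continue  # not a run start
            g = vox[tuple(p)]
            length = 1
            q = p + d
            while tuple(q) in vox and vox[tuple(q)] == g:
                length += 1
                q = q + d
            runs.append((g, length))
    return runs


def brute_zones(disc, mask):
    """(gray level, zone size) pairs by explicit 26-connected flood fill."""
    idx = [tuple(p) for p in np.argwhere(mask)]
    vox = {p: disc[p] for p in idx}
    seen = set()
    zones = []
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
               for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    for p in idx:
        if p in seen:
            continue
        g = vox[p]
        stack = [p]
        seen.add(p)
        size = 0
        while stack:
            q = stack.pop()
            size += 1
            for off in offsets:
                r = (q[0] + off[0], q[1] + off[1], q[2] + off[2])
                if r in vox and r not in seen and vox[r] == g:
                    seen.add(r)
                    stack.append(r)
        zones.append((g, size))
    return zones


def rl_features_from_pairs(pairs, n_vox, prefix):
    """The 11 run/zone-length formulas computed independently."""
    g = np.array([p[0] for p in pairs], float)
    l = np.array([p[1] for p in pairs], float)
    n_r = len(pairs)
    g_marg = {gi: np.sum(g == gi) for gi in np.unique(g)}
    l_marg = {li: np.sum(l == li) for li in np.unique(l)}
    return {
        f"{prefix}_sre": np.mean(1 / l ** 2),
        f"{prefix}_lre": np.mean(l ** 2),
        f"{prefix}_gln": sum(v ** 2 for v in g_marg.values()) / n_r,
        f"{prefix}_rln": sum(v ** 2 for v in l_marg.values()) / n_r,
        f"{prefix}_rp": n_r / n_vox,
        f"{prefix}_lgre": np.mean(1 / g ** 2),
        f"{prefix}_hgre": np.mean(g ** 2),
        f"{prefix}_srlge": np.mean(1 / (g ** 2 * l ** 2)),
        f"{prefix}_srhge": np.mean(g ** 2 / l ** 2),
        f"{prefix}_lrlge": np.mean(l ** 2 / g ** 2),
        f"{prefix}_lrhge": np.mean(g ** 2 * l ** 2),
    }
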