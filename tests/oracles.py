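"""Independent brute-force oracles used to cross-check the implementations.

Deliberately written with plain loops and their own candidate constructions so
they share no code path with the library.
"""

import itertools
import math

import numpy as np

EPS = 1e-9


def oracle_depth(points, index, n_grid=500):
    """Brute-force Tukey depth: scan every pair-normal plane through the point
    plus a dense polar-angle direction grid."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    x = points[index]
    diffs = [points[j] - x for j in range(n) if j != index
             and np.linalg.norm(points[j] - x) > EPS]
    directions = list(diffs)
    for a in range(len(diffs)):
        for b in range(a + 1, len(diffs)):
            c = np.cross(diffs[a], diffs[b])
            nc = np.linalg.norm(c)
            if nc > EPS:
                directions.append(c)
                # tilted variants that push the generating pair just off the
                # boundary plane, one way then the other
                v = diffs[a] / np.linalg.norm(diffs[a]) + diffs[b] / np.linalg.norm(diffs[b])
                nv = np.linalg.norm(v)
                if nv > EPS:
                    directions.append(c / nc + 1e-7 * v / nv)
                    directions.append(c / nc - 1e-7 * v / nv)
    # dense quasi-uniform grid from polar angles (independent of the
    # implementation's candidate construction)
    for i in range(n_grid):
        theta = math.acos(max(-1.0, min(1.0, 1.0 - 2.0 * (i + 0.5) / n_grid)))
        phi = 3.883222 * i
        directions.append(
            np.array(
                [math.sin(theta) * math.cos(phi),
                 math.sin(theta) * math.sin(phi),
                 math.cos(theta)]
            )
        )
    best = n
    rel = points - x
    for u in directions:
        norm = np.linalg.norm(u)
        if norm < EPS:
            continue
        s = rel @ (u / norm)
        below = int(np.sum(s < -EPS))
        above = int(np.sum(s > EPS))
        on = n - below - above
        best = min(best, min(below, above) + on)
    return best / n


def exhaustive_ranksum_p(x, y, alternative):
    """Exact rank-sum p-value by enumerating every assignment of pooled ranks."""
    nx = len(x)
    pooled = sorted(list(x) + list(y))
    ranks = {}
    for v in sorted(set(pooled)):
        idx = [i + 1 for i, p in enumerate(pooled) if p == v]
        ranks[v] = sum(idx) / len(idx)
    obs = sum(ranks[v] for v in x)
    items = [ranks[v] for v in pooled]
    count = total = 0
    mean = nx * (len(pooled) + 1) / 2.0
    for combo in itertools.combinations(range(len(pooled)), nx):
        w = sum(items[i] for i in combo)
        total += 1
        if alternative == "less" and w <= obs + 1e-9:
            count += 1
        elif alternative == "greater" and w >= obs - 1e-9:
            count += 1
        elif alternative == "two-sided" and abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def brute_force_hse(structure, radius, mode):
    """Half-sphere exposure by direct per-pair dot-product enumeration."""
    chains = {}
    for res in structure:
        if res.atom("CA") is not None:
            chains.setdefault(res.chain_id, []).append(res)
    out = {}
    all_res = [r for rs in chains.values() for r in rs]
    for cid, rs in chains.items():
        for i, res in enumerate(rs):
            ca = res.atom("CA").coord
            u = None
            parts = []
            if i > 0:
                parts.append(ca - rs[i - 1].atom("CA").coord)
            if i + 1 < len(rs):
                parts.append(ca - rs[i + 1].atom("CA").coord)
            if parts:
                u = sum(parts)
            if mode == "B" and res.atom("CB") is not None:
                u = res.atom("CB").coord - ca
            up = down = 0
            for other in all_res:
                if other is res:
                    continue
                d = other.atom("CA").coord - ca
                if np.linalg.norm(d) <= radius:
                    if u is not None and float(np.dot(d, u)) > 0.0:
                        up += 1
                    else:
                        down += 1
            out[res.key] = (up, down)
    return out
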