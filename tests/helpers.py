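"""Independent brute-force oracles used to validate the accelerated paths.

Everything here is written from the definitions (O(n²) scans, exhaustive
enumeration, plain loops) and shares no code with the implementation.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_interaction_matrix(xy: np.ndarray, labels: np.ndarray) -> dict:
    """Mean nearest-neighbour distance per ordered type pair, O(n²)."""
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    types = sorted(set(labels))
    out = {}
    for a in types:
        ia = np.flatnonzero(labels == a)
        for b in types:
            ib = np.flatnonzero(labels == b)
            if a == b and len(ia) < 2:
                out[(a, b)] = np.nan
                continue
            out[(a, b)] = float(d[np.ix_(ia, ib)].min(axis=1).mean())
    return out


def brute_top2_contacts(
    xy: np.ndarray, labels: np.ndarray, cell_ids: np.ndarray
) -> dict:
    """Top-2 neighbour contact counts with (distance, cell_id) tie-break."""
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    out: dict = {}
    for i in range(n):
        cand = sorted(
            ((d[i, j], cell_ids[j], j) for j in range(n) if j != i),
            key=lambda t: (t[0], t[1]),
        )
        for _, _, j in cand[:2]:
            key = (labels[i], labels[j])
            out[key] = out.get(key, 0) + 1
    return out


def _point_segment_distance(p, a, b) -> float:
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    t = np.dot(p - a, ab) / np.dot(ab, ab)
    t = min(1.0, max(0.0, t))
    return float(np.linalg.norm(p - (a + t * ab)))


def brute_signed_distance(point, vertices: np.ndarray) -> float:
    """Signed boundary distance from edge scan + crossing-number test."""
    vertices = np.asarray(vertices, dtype=float)
    n = len(vertices)
    dmin = min(
        _point_segment_distance(point, vertices[i], vertices[(i + 1) % n])
        for i in range(n)
    )
    x, y = point
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return -dmin if inside or dmin == 0 else dmin


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration (no ties assumed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    obs = ranks[: len(x)].sum()
    stats = np.array(
        [sum(ranks[list(c)]) for c in combinations(range(len(pooled)), len(x))]
    )
    p = 2 * min((stats <= obs).mean(), (stats >= obs).mean())
    return min(p, 1.0)


def brute_enrichment_score(
    ranked_genes, rank_weights, members
) -> float:
    """Weighted-KS enrichment score as a plain running-sum loop."""
    members = set(members)
    hits = [g in members for g in ranked_genes]
    total_hit_w = sum(w for g, w in zip(ranked_genes, rank_weights) if g in members)
    n_miss = len(ranked_genes) - sum(hits)
    running = 0.0
    best = 0.0
    for g, w, h in zip(ranked_genes, rank_weights, hits):
        if h:
            running += w / total_hit_w
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best
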