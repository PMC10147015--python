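"""Brute-force geometric references for validation.

These deliberately naive routines exist only to cross-check the
production implementations (Qhull-based hulls, closed-form Sholl
crossing counts) in tests and the acceptance script.  They are small-n
and slow by design and share no code with the paths they validate.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_hull(points: np.ndarray, tol: float = 1e-9) -> tuple[float, float]:
    """Convex hull (volume, area) by supporting-plane enumeration.

    Every point triplet is tested as a supporting plane (all remaining
    points on one side, on-plane allowed); unique supporting planes are
    collected, the points on each plane form one facet whose polygon is
    ordered angularly, and volume is accumulated from signed pyramid
    volumes to the centroid.  Handles facets with more than three
    coplanar vertices (e.g. cube faces).  Intended for n <= ~12.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 4:
        raise ValueError("need at least 4 points")
    centroid = pts.mean(axis=0)
    planes = []  # (unit normal pointing outward, offset)
    for i, j, k in combinations(range(n), 3):
        normal = np.cross(pts[j] - pts[i], pts[k] - pts[i])
        norm = np.linalg.norm(normal)
        if norm < tol:
            continue
        normal = normal / norm
        d = np.dot(pts - pts[i], normal)
        if np.all(d >= -tol):
            # points on the positive side: flip so the normal points outward
            normal, d = -normal, -d
        if not np.all(d <= tol):
            continue
        offset = float(np.dot(normal, pts[i]))
        key = (round(normal[0], 7), round(normal[1], 7), round(normal[2], 7), round(offset, 7))
        planes.append((key, normal, offset))
    seen = set()
    area = 0.0
    volume = 0.0
    for key, normal, offset in planes:
        if key in seen:
            continue
        seen.add(key)
        on_plane = pts[np.abs(pts @ normal - offset) <= tol]
        # order facet vertices angularly around their centroid
        c = on_plane.mean(axis=0)
        ref = on_plane[0] - c
        ref /= np.linalg.norm(ref)
        other = np.cross(normal, ref)
        ang = np.arctan2((on_plane - c) @ other, (on_plane - c) @ ref)
        ordered = on_plane[np.argsort(ang)]
        # fan triangulation
        for a in range(1, len(ordered) - 1):
            tri = np.array([ordered[0], ordered[a], ordered[a + 1]])
            cross = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            tri_area = 0.5 * np.linalg.norm(cross)
            area += tri_area
            height = float(np.dot(normal, tri[0] - centroid))
            volume += tri_area * height / 3.0
    return float(volume), float(area)


def dunn_z_brute(values_a, values_b, pooled_all) -> float:
    """Dunn z-statistic recomputed from first principles.

    ``pooled_all`` is the full concatenation across *all* groups (the
    ranking frame); values_a/values_b are the two groups compared.
    Mid-ranks and the tie correction are computed by hand.
    """
    pooled = np.asarray(pooled_all, dtype=float)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1

    def mean_rank(vals):
        vals = np.asarray(vals, dtype=float)
        return np.mean([ranks[np.flatnonzero(pooled == v)[0]] for v in vals]), len(vals)

    # careful mean rank: map each observation to the rank of an equal value
    # (mid-ranks make all equal values share one rank, so lookup is safe)
    ra, na = mean_rank(values_a)
    rb, nb = mean_rank(values_b)
    n_tot = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie = float((counts**3 - counts).sum() / (12.0 * (n_tot - 1)))
    var = (n_tot * (n_tot + 1) / 12.0 - tie) * (1.0 / na + 1.0 / nb)
    if var <= 0:
        return 0.0
    return float((ra - rb) / np.sqrt(var))


def ecdf_ks_d(x, y) -> float:
    """Maximum ECDF gap between two samples, by direct evaluation."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    grid = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(x, grid, side="right") / len(x)
    fy = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.max(np.abs(fx - fy)))
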