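"""Independent brute-force reference implementations.

Everything here is written with plain loops, sets and BFS so it shares no
code path with the package: each function recomputes an operation from its
definition and is used to cross-check the vectorised / library-backed
implementations on small random instances.
"""

from __future__ import annotations

import math
from collections import deque


def brute_usable_intervals(labels):
    """Interval i (beat i-1 -> beat i) is usable iff both endpoint beats are normal."""
    n = len(labels)
    usable = []
    for i in range(n):
        ok = labels[i] == "normal"
        if i > 0 and labels[i - 1] != "normal":
            ok = False
        usable.append(ok)
    return usable


def brute_pairs(rr, labels):
    usable = brute_usable_intervals(labels)
    out = []
    for i in range(len(rr) - 1):
        if usable[i] and usable[i + 1]:
            out.append((rr[i], rr[i + 1]))
    return out


def brute_correct_isolated(rr, labels):
    rr = list(rr)
    labels = list(labels)
    n = len(rr)
    for i in range(1, n - 1):
        if labels[i] != "normal" and labels[i - 1] == "normal" and labels[i + 1] == "normal":
            rr[i] = (rr[i - 1] + rr[i + 1]) / 2.0
            labels[i] = "normal"
    return rr, labels


def brute_bin(v, w, origin=0.0):
    return math.floor((v - origin) / w)


def brute_raster(xs, ys, w, origin=0.0):
    """Set of occupied (x_bin, y_bin) cells."""
    return {(brute_bin(x, w, origin), brute_bin(y, w, origin))
            for x, y in zip(xs, ys)}


def _neighbors(r, c, connectivity):
    if connectivity == 8:
        deltas = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        deltas = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for dr, dc in deltas:
        yield r + dr, c + dc


def brute_components(cells, connectivity=8):
    """Connected components of a set of (r, c) cells via BFS."""
    cells = set(cells)
    seen = set()
    comps = []
    for start in sorted(cells):
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        seen.add(start)
        while queue:
            r, c = queue.popleft()
            comp.add((r, c))
            for nb in _neighbors(r, c, connectivity):
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def brute_area_open(grid, min_pixels=4, connectivity=8):
    """Boolean 2D list -> boolean 2D list with small components removed."""
    rows, cols = len(grid), len(grid[0])
    cells = {(r, c) for r in range(rows) for c in range(cols) if grid[r][c]}
    keep = set()
    for comp in brute_components(cells, connectivity):
        if len(comp) >= min_pixels:
            keep |= comp
    return [[(r, c) in keep for c in range(cols)] for r in range(rows)]


def brute_fill_holes(grid, fg_connectivity=8):
    """Fill background not reachable from the border (complementary connectivity)."""
    rows, cols = len(grid), len(grid[0])
    bg_conn = 4 if fg_connectivity == 8 else 8
    background = {(r, c) for r in range(rows) for c in range(cols) if not grid[r][c]}
    border = {cell for cell in background
              if cell[0] in (0, rows - 1) or cell[1] in (0, cols - 1)}
    reach = set(border)
    queue = deque(border)
    while queue:
        r, c = queue.popleft()
        for nb in _neighbors(r, c, bg_conn):
            if nb in background and nb not in reach:
                reach.add(nb)
                queue.append(nb)
    return [[grid[r][c] or (r, c) not in reach for c in range(cols)]
            for r in range(rows)]


def brute_ve(grid, w):
    """Per-occupied-column vertical extent in ms: {col: (max-min+1)*w}."""
    rows, cols = len(grid), len(grid[0])
    out = {}
    for c in range(cols):
        occupied = [r for r in range(rows) if grid[r][c]]
        if occupied:
            out[c] = (max(occupied) - min(occupied) + 1) * w
    return out


def brute_features2d(grid, w, origin=0.0, x0=0):
    """L, HVE, A, P from a boolean grid whose column c is global bin x0+c."""
    ve = brute_ve(grid, w)
    cols = sorted(ve)
    c_min, c_max = cols[0], cols[-1]
    L = (c_max + 1 - c_min) * w
    hve = max(ve.values())
    best = min(c for c in cols if ve[c] == hve)
    rr_star = origin + (x0 + best + 0.5) * w
    left = origin + (x0 + c_min) * w
    area = sum(row.count(True) for row in
               [[bool(v) for v in r] for r in grid]) * w * w
    P = max(0.0, min(100.0, 100.0 * (rr_star - left) / L))
    return {"L": L, "HVE": hve, "A": area, "P": P, "rr_star": rr_star}


def brute_peaks(counts, threshold_frac=0.5):
    """Regional-maximum plateaus >= threshold, merged, with centroids.

    Returns a sorted list of (x_centroid_col, y_centroid_row, height) in
    array coordinates (col, row), plateau centroid = mean of member cells.
    """
    rows, cols = len(counts), len(counts[0])
    maxval = max(max(row) for row in counts)
    threshold = threshold_frac * maxval
    nonzero = {(r, c) for r in range(rows) for c in range(cols) if counts[r][c] > 0}
    peaks = []
    seen = set()
    for start in sorted(nonzero):
        if start in seen:
            continue
        h = counts[start[0]][start[1]]
        # plateau = connected cells of equal value (8-neighborhood)
        plateau = set()
        queue = deque([start])
        plateau.add(start)
        while queue:
            r, c = queue.popleft()
            for nr, nc in _neighbors(r, c, 8):
                if 0 <= nr < rows and 0 <= nc < cols:
                    if counts[nr][nc] == h and (nr, nc) not in plateau:
                        plateau.add((nr, nc))
                        queue.append((nr, nc))
        seen |= plateau
        # regional max: strictly greater than every outside neighbor
        is_max = True
        for r, c in plateau:
            for nr, nc in _neighbors(r, c, 8):
                if 0 <= nr < rows and 0 <= nc < cols and (nr, nc) not in plateau:
                    if counts[nr][nc] >= h:
                        is_max = False
        if is_max and h >= threshold:
            cx = sum(c for _, c in plateau) / len(plateau)
            cy = sum(r for r, _ in plateau) / len(plateau)
            peaks.append((cx, cy, h))
    return sorted(peaks)


def brute_inertia(counts, w, origin=0.0, x0=0, y0=0):
    """Longhand barycenter and RMS radii over unit masses at occupied bins."""
    pts = []
    for r, row in enumerate(counts):
        for c, v in enumerate(row):
            if v > 0:
                x = origin + (x0 + c + 0.5) * w
                y = origin + (y0 + r + 0.5) * w
                pts.append((x, y, float(v)))
    n = len(pts)
    gx = sum(p[0] for p in pts) / n
    gy = sum(p[1] for p in pts) / n
    gz = sum(p[2] for p in pts) / n
    rx = math.sqrt(sum((p[0] - gx) ** 2 for p in pts) / n)
    ry = math.sqrt(sum((p[1] - gy) ** 2 for p in pts) / n)
    rz = math.sqrt(sum((p[2] - gz) ** 2 for p in pts) / n)
    return (gx, gy, gz), (rx, ry, rz)
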