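"""Independent brute-force oracles used by the acceptance script.

Each routine recomputes a quantity by a method unrelated to the
package's implementation path: extended-precision normal equations for
OLS, a shrinking likelihood grid for the logistic MLE, hull
rasterisation for extent-of-occurrence cells, direct set arithmetic for
two-site turnover, and exhaustive set-partition enumeration for
modularity.
"""

from __future__ import annotations

import numpy as np


def ols_oracle(x, y):
    """Simple-regression normal equations in extended precision."""
    x = np.asarray(x, np.longdouble)
    y = np.asarray(y, np.longdouble)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)


def grid_mle_oracle(y, x, span=8.0, passes=6, width=41):
    """Brute-force Bernoulli likelihood maximiser on a shrinking 2-D grid."""
    def ll(b0, b1):
        eta = b0 + b1 * x
        return np.sum(y * eta - np.logaddexp(0.0, eta))

    c0, c1, half = 0.0, 0.0, span
    for _ in range(passes):
        b0s = np.linspace(c0 - half, c0 + half, width)
        b1s = np.linspace(c1 - half, c1 + half, width)
        vals = np.array([[ll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        c0, c1 = b0s[i], b1s[j]
        half *= 2.2 / (width - 1)
    return c0, c1


def two_site_closed_form(P):
    """Pairwise Jaccard turnover from direct set arithmetic."""
    a = int((P[0] & P[1]).sum())
    b12 = int((P[0] & ~P[1]).sum())
    b21 = int((P[1] & ~P[0]).sum())
    m = min(b12, b21)
    return 2 * m / (a + 2 * m) if (a + 2 * m) else 0.0


def _segment_cells(p0, p1, grid):
    """Cells crossed by a segment, by exact grid-line traversal.

    Splits the segment at every crossing of a cell boundary and maps
    the midpoint of each piece to its cell, so arbitrarily thin corner
    clips are detected.
    """
    (x0, y0), (x1, y1) = p0, p1
    ts = {0.0, 1.0}
    for (a0, a1, o) in ((x0, x1, grid.origin[0]), (y0, y1, grid.origin[1])):
        if a1 != a0:
            k0 = int(np.floor((min(a0, a1) - o) / grid.cell_side_m))
            k1 = int(np.ceil((max(a0, a1) - o) / grid.cell_side_m))
            for k in range(k0, k1 + 1):
                t = (o + k * grid.cell_side_m - a0) / (a1 - a0)
                if 0.0 < t < 1.0:
                    ts.add(t)
    ts_sorted = sorted(ts)
    cells = set()
    for ta, tb in zip(ts_sorted[:-1], ts_sorted[1:]):
        tm = (ta + tb) / 2.0
        cells.add(grid.cell_of(x0 + tm * (x1 - x0), y0 + tm * (y1 - y0)))
    return cells


def raster_oracle_cells(points, grid, raster_m=1000.0):
    """Grid cells touched by the hull, found by rasterising the hull.

    Interior points on a 1 km lattice, plus hull vertices, plus the
    cells crossed by each hull edge found by exact grid-line traversal
    (a fixed sampling pitch would miss corner slivers thinner than the
    pitch).
    """
    from matplotlib.path import Path as MplPath
    from scipy.spatial import ConvexHull, QhullError

    points = np.atleast_2d(np.asarray(points, float))
    if len(points) == 1:
        return frozenset([grid.cell_of(*points[0])])
    cells = {grid.cell_of(x, y) for x, y in points}
    try:
        hull = ConvexHull(points)
        verts = points[hull.vertices]
        edges = list(zip(verts, np.roll(verts, -1, axis=0)))
        minx, miny = points.min(axis=0) - raster_m
        maxx, maxy = points.max(axis=0) + raster_m
        xs = np.arange(minx, maxx, raster_m)
        ys = np.arange(miny, maxy, raster_m)
        xx, yy = np.meshgrid(xs, ys)
        lattice = np.column_stack([xx.ravel(), yy.ravel()])
        inside = lattice[MplPath(verts).contains_points(lattice)]
        cells.update(grid.cell_of(x, y) for x, y in inside)
    except QhullError:  # collinear: spanning segment only
        order = np.lexsort(points.T)
        edges = [(points[order[0]], points[order[-1]])]
    for p0, p1 in edges:
        cells.update(_segment_cells(p0, p1, grid))
    return frozenset(cells)


def _partitions(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1:]
        yield part + [{first}]


def best_modularity_oracle(g):
    """Exhaustive enumeration of all set partitions."""
    import networkx as nx

    return max(nx.community.modularity(g, p, weight=None)
               for p in _partitions(list(g.nodes)))
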