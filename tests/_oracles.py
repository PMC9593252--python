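"""Independent brute-force oracles used to pin the fast implementations.

These are deliberately written as O(n^2) python/numpy loops with no shared
code with the package internals.
"""

import numpy as np


def _dist(p, q, window=None, periodic=False):
    d = np.abs(np.asarray(p) - np.asarray(q))
    if periodic:
        sizes = np.array([window.width, window.height])
        d = np.minimum(d, sizes - d)
    return float(np.hypot(d[0], d[1]))


def _weight(p, q, window, mode):
    if mode != "translation":
        return 1.0
    dx, dy = abs(p[0] - q[0]), abs(p[1] - q[1])
    return window.area_nm2 / ((window.width - dx) * (window.height - dy))


def brute_pcf(points, window, edges, mode="periodic"):
    """Univariate binned g(r) by explicit double loop over ordered pairs."""
    n = len(points)
    nb = len(edges) - 1
    acc = np.zeros(nb)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = _dist(points[i], points[j], window, periodic=(mode == "periodic"))
            for k in range(nb):
                if edges[k] <= d < edges[k + 1]:
                    acc[k] += _weight(points[i], points[j], window, mode)
    annulus = np.pi * (np.asarray(edges[1:]) ** 2 - np.asarray(edges[:-1]) ** 2)
    return acc * window.area_nm2 / (n * (n - 1) * annulus)


def brute_bpcf(pa, pb, window, edges, mode="periodic"):
    """Bivariate binned g12(r) by explicit double loop over cross pairs."""
    nb = len(edges) - 1
    acc = np.zeros(nb)
    for p in pa:
        for q in pb:
            d = _dist(p, q, window, periodic=(mode == "periodic"))
            for k in range(nb):
                if edges[k] <= d < edges[k + 1]:
                    acc[k] += _weight(p, q, window, mode)
    annulus = np.pi * (np.asarray(edges[1:]) ** 2 - np.asarray(edges[:-1]) ** 2)
    return acc * window.area_nm2 / (len(pa) * len(pb) * annulus)


def brute_single_linkage(points, d_th):
    """Cluster partition by explicit union-find over all point pairs."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(np.asarray(points[i]) - points[j])) <= d_th:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    return np.asarray(roots)


def partitions_equal(labels_a, labels_b):
    """True iff two labelings induce the same partition."""
    seen = {}
    for la, lb in zip(labels_a, labels_b):
        if la in seen:
            if seen[la] != lb:
                return False
        else:
            seen[la] = lb
    return len(set(seen.values())) == len(seen)
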