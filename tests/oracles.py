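"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles (definitions and
exhaustive enumeration), deliberately sharing no code path with the
package implementation it checks.
"""

import itertools

import numpy as np


def brute_ispc(phix, phiy):
    """|mean unit vector of phase differences| by explicit summation."""
    s = 0j
    for a, b in zip(phix, phiy):
        s += complex(np.cos(a - b), np.sin(a - b))
    return abs(s / len(phix))


def brute_pli(zx, zy):
    """|mean sign of the imaginary cross-spectrum| by explicit summation."""
    total = 0.0
    for a, b in zip(zx, zy):
        im = (a * np.conj(b)).imag
        total += int(im > 0) - int(im < 0)
    return abs(total / len(zx))


def brute_rank(x):
    """Average ranks (1-based) with tie averaging, from the definition."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(px, py):
    """Pearson correlation of brute-force ranks."""
    rx, ry = brute_rank(px), brute_rank(py)
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def all_graphs(n):
    """All 2^(n(n-1)/2) labelled simple graphs on n nodes, as adjacency."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        a = np.zeros((n, n), dtype=int)
        for (i, j), b in zip(pairs, bits):
            a[i, j] = a[j, i] = b
        yield a


def brute_density(a):
    n = len(a)
    return a.sum() / (n * (n - 1)) if n > 1 else 0.0


def brute_clustering(a):
    """Mean local clustering from triangle counts among neighbours."""
    n = len(a)
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals)) if vals else 0.0


def brute_transitivity(a):
    """3 * triangles / open-or-closed triads, by enumeration."""
    n = len(a)
    closed = 0
    triads = 0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        for u, v in itertools.combinations(nbrs, 2):
            triads += 1
            closed += a[u, v]
    return closed / triads if triads else 0.0


def brute_components(a):
    """Connected components via depth-first search."""
    n = len(a)
    seen = set()
    comps = []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in range(n) if a[u, v] and v not in comp)
        seen |= comp
        comps.append(comp)
    return comps


def brute_path_length(a):
    """(mean geodesic over reachable pairs, unreachable pair count) via
    Floyd-Warshall."""
    n = len(a)
    INF = float("inf")
    d = [[0 if i == j else (1 if a[i, j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    total, reach, unreach = 0.0, 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            if d[i][j] < INF:
                total += d[i][j]
                reach += 1
            else:
                unreach += 1
    return (total / reach if reach else 0.0), unreach
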