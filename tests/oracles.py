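"""Independent brute-force implementations used only as test oracles.

These deliberately share no code with the package: zones are enumerated
with a hand-written union-find, runs with an explicit per-line walk, and
matrix features with naive double loops.
"""

import numpy as np


def unionfind_zones(levels: np.ndarray, connectivity: int = 26):
    """(level, size) multiset via union-find over same-level neighbors."""
    shape = levels.shape
    idx = {p: i for i, p in enumerate(np.ndindex(shape))}
    parent = list(range(len(idx)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    if connectivity == 26:
        offsets = [o for o in np.ndindex(3, 3, 3)
                   if o != (1, 1, 1)]
        offsets = [(o[0] - 1, o[1] - 1, o[2] - 1) for o in offsets]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        for o in offsets:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            if all(0 <= q[d] < shape[d] for d in range(3)) \
                    and levels[q] == levels[p]:
                union(idx[p], idx[q])
    sizes: dict[int, int] = {}
    roots: dict[int, int] = {}
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        r = find(idx[p])
        sizes[r] = sizes.get(r, 0) + 1
        roots[r] = int(levels[p])
    return sorted((roots[r], s) for r, s in sizes.items())


def scan_runs(levels: np.ndarray, direction):
    """(level, length) multiset of maximal runs along one direction,
    enumerated by walking every line explicitly."""
    shape = levels.shape
    d = direction
    starts = []
    for p in np.ndindex(shape):
        q = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
        inside = all(0 <= q[k] < shape[k] for k in range(3))
        if not inside:
            starts.append(p)
    runs = []
    for s in starts:
        line = []
        p = s
        while all(0 <= p[k] < shape[k] for k in range(3)):
            line.append(int(levels[p]))
            p = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
        i = 0
        while i < len(line):
            if line[i] == 0:
                i += 1
                continue
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs.append((line[i], j - i))
            i = j
    return sorted(runs)


def glszm_feature_oracle(counts: np.ndarray, name: str) -> float:
    """Naive double-loop evaluation of a size-zone feature."""
    ns = counts.sum()
    acc = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            s = counts[i, j]
            lvl, size = i + 1, j + 1
            if name == "SZE":
                acc += s / size**2
            elif name == "SZLGE":
                acc += s / (lvl**2 * size**2)
            elif name == "HGRE":
                acc += s * lvl**2
            else:
                raise ValueError(name)
    return acc / ns
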