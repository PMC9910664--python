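"""Independent brute-force oracles for the operator tests.

These deliberately avoid scipy/skimage so they form an independent path:
pure-Python BFS component labelling and naive largest-inscribed-sphere
thickness, both feasible only on tiny inputs.
"""

from collections import deque
from itertools import product

import numpy as np


def neighbor_offsets(ndim: int, full: bool) -> list[tuple[int, ...]]:
    """26/8-connectivity offsets (full) or 6/4 (faces only)."""
    offs = []
    for off in product((-1, 0, 1), repeat=ndim):
        if all(o == 0 for o in off):
            continue
        if not full and sum(abs(o) for o in off) != 1:
            continue
        offs.append(off)
    return offs


def bfs_label(data: np.ndarray, full_connectivity: bool = True) -> list[list[tuple]]:
    """Connected components as lists of index tuples, by BFS flood fill."""
    data = np.asarray(data, dtype=bool)
    offs = neighbor_offsets(data.ndim, full_connectivity)
    seen = np.zeros(data.shape, dtype=bool)
    comps = []
    for idx in np.ndindex(data.shape):
        if not data[idx] or seen[idx]:
            continue
        comp = []
        q = deque([idx])
        seen[idx] = True
        while q:
            cur = q.popleft()
            comp.append(cur)
            for off in offs:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(n < 0 or n >= s for n, s in zip(nb, data.shape)):
                    continue
                if data[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        comps.append(comp)
    return comps


def bfs_keep_largest(data: np.ndarray, full_connectivity: bool = True) -> np.ndarray:
    """Sweep despeckle oracle: largest component, lexicographic tie-break."""
    comps = bfs_label(data, full_connectivity)
    if not comps:
        raise ValueError("no objects")
    best = max(comps, key=lambda c: (len(c), tuple(-m for m in min(c))))
    out = np.zeros(data.shape, dtype=bool)
    for idx in best:
        out[idx] = True
    return out


def brute_local_thickness(data: np.ndarray) -> np.ndarray:
    """Naive largest-inscribed-sphere thickness map, in voxels.

    Mirrors the implemented convention -- inscribed radius = Euclidean
    distance to the nearest background voxel (array border exempt),
    quantised to the nearest integer; the sphere of diameter 2r - 1 covers
    voxels within r - 0.5 of its centre; each voxel keeps the largest
    covering sphere -- but computes it by O(n^2) pairwise distances with no
    scipy, so it is an independent computational path.  Tiny inputs only.
    """
    data = np.asarray(data, dtype=bool)
    fg = np.argwhere(data)
    bg = np.argwhere(~data)
    if len(bg) == 0:
        raise ValueError("no background")
    d = np.sqrt(((fg[:, None, :] - bg[None, :, :]) ** 2).sum(-1).min(axis=1))
    r = np.round(d).astype(int)
    th = np.zeros(data.shape)
    order = np.argsort(r)[::-1]
    for i in order:
        c, ri = fg[i], r[i]
        cover = np.sqrt(((fg - c) ** 2).sum(axis=1)) <= ri - 0.5
        for v in fg[cover]:
            t = tuple(v)
            if th[t] == 0:
                th[t] = 2 * ri - 1
    return th


def truth_table_bitwise(a: bool, b: bool, op: str) -> bool:
    return {
        "AND": a and b,
        "OR": a or b,
        "SUB": a and not b,
        "XOR": a != b,
        "NOT_A": not a,
    }[op]
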