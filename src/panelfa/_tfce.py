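"""Union-find TFCE kernel.

The enhanced value of voxel v is the discrete integral

    TFCE(v) = sum_{k=1..n_steps} e(h_k, v)^E * h_k^H * dh,

over thresholds h_k = h_max * k / n_steps, where e(h, v) is the spatial
support of the connected suprathreshold (stat >= h) component containing
v: its voxel count times the voxel volume in TFCE mode, or its mass
sum(stat - h) times the voxel volume in cluster-mass mode.

Thresholds are processed descending with an incremental union-find so
each voxel is inserted once and components only ever merge; this is exact
(identical to relabelling the suprathreshold set at every height) and
fast enough to sit inside a permutation loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def build_adjacency(mask: np.ndarray, connectivity: int = 26):
    """CSR neighbour lists over the voxels inside ``mask``.

    Returns ``(indptr, indices)`` with neighbour voxel indices in the
    masked (flattened) ordering; built once per mask and reused across
    maps and permutations.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(mask, dtype=bool)
    st = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    offs = np.argwhere(st) - 1
    offs = offs[np.any(offs != 0, axis=1)]
    idx_vol = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    idx_vol[mask] = np.arange(len(coords))
    return _adjacency_kernel(coords.astype(np.int64), idx_vol,
                             offs.astype(np.int64),
                             np.asarray(mask.shape, dtype=np.int64))


@njit(cache=True)
def _adjacency_kernel(coords, idx_vol, offs, shape):
    n = coords.shape[0]
    k = offs.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    buf = np.empty(n * k, dtype=np.int64)
    pos = 0
    for i in range(n):
        x, y, z = coords[i, 0], coords[i, 1], coords[i, 2]
        for o in range(k):
            a = x + offs[o, 0]
            b = y + offs[o, 1]
            c = z + offs[o, 2]
            if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= c < shape[2]:
                j = idx_vol[a, b, c]
                if j >= 0:
                    buf[pos] = j
                    pos += 1
        indptr[i + 1] = pos
    return indptr, buf[:pos].copy()


@njit(cache=True)
def _find(parent, v):
    r = v
    while parent[r] != r:
        r = parent[r]
    while parent[v] != r:          # path compression
        nxt = parent[v]
        parent[v] = r
        v = nxt
    return r


@njit(cache=True)
def tfce_flat(stat, indptr, indices, n_steps, E, H, voxel_volume, mass_mode):
    """Enhance a non-negative masked-flat statistic vector."""
    n = stat.shape[0]
    out = np.zeros(n)
    hmax = 0.0
    for i in range(n):
        if stat[i] > hmax:
            hmax = stat[i]
    if hmax <= 0.0:
        return out
    dh = hmax / n_steps
    order = np.argsort(-stat)
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    ssum = np.zeros(n)
    ptr = 0
    for k in range(n_steps, 0, -1):
        h = hmax * (k / n_steps)
        while ptr < n and stat[order[ptr]] >= h:
            v = order[ptr]
            ptr += 1
            parent[v] = v
            size[v] = 1
            ssum[v] = stat[v]
            for e in range(indptr[v], indptr[v + 1]):
                w = indices[e]
                if parent[w] >= 0:
                    rv = _find(parent, v)
                    rw = _find(parent, w)
                    if rv != rw:
                        if size[rv] < size[rw]:
                            rv, rw = rw, rv
                        parent[rw] = rv
                        size[rv] += size[rw]
                        ssum[rv] += ssum[rw]
        inc_h = h ** H * dh
        for p in range(ptr):
            v = order[p]
            r = _find(parent, v)
            if mass_mode:
                support = (ssum[r] - size[r] * h) * voxel_volume
            else:
                support = size[r] * voxel_volume
            out[v] += support ** E * inc_h
    return out
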