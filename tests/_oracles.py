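"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (full sorts, explicit loops, BFS) and
shares no code with the package implementation it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def top_k_bruteforce(stat_map: np.ndarray, mask: np.ndarray, k: int) -> set[int]:
    """Flat indices of the k largest in-mask values; ties -> smaller index."""
    items = [(-float(stat_map.ravel()[i]), int(i)) for i in np.flatnonzero(mask.ravel())]
    items.sort()
    return {i for _, i in items[:k]}


def overlap_bruteforce(masks: list[np.ndarray]) -> np.ndarray:
    out = np.zeros(masks[0].shape, dtype=int)
    it = np.ndindex(*masks[0].shape)
    for idx in it:
        out[idx] = sum(1 for m in masks if m[idx])
    return out


def gaussian3d(shape, center, sigma_vox) -> np.ndarray:
    """Closed-form separable Gaussian (unit mass per axis kernel convention is
    not needed: used as an analytic field, values only)."""
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    out = np.ones(shape)
    for ax, (g, c, s) in enumerate(zip(grids, center, sigma_vox)):
        out = out * np.exp(-((g - c) ** 2) / (2.0 * s ** 2)) / (np.sqrt(2 * np.pi) * s)
    return out


def steepest_ascent_basins(field: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Label each supported voxel by the local maximum its 26-neighbour
    steepest-ascent path reaches; maxima are numbered by flat index order."""
    shape = field.shape
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
               if (i, j, k) != (0, 0, 0)]
    labels = np.zeros(shape, dtype=int)
    max_label = {}

    def ascend(idx):
        path = []
        cur = idx
        while True:
            if labels[cur] != 0:
                lab = labels[cur]
                break
            path.append(cur)
            best = cur
            best_val = field[cur]
            for o in offsets:
                n = tuple(np.add(cur, o))
                if all(0 <= n[a] < shape[a] for a in range(3)) and field[n] > best_val:
                    best, best_val = n, field[n]
            if best == cur:  # local maximum
                if cur not in max_label:
                    max_label[cur] = len(max_label) + 1
                lab = max_label[cur]
                break
            cur = best
        for p in path:
            labels[p] = lab
        return lab

    for idx in np.ndindex(*shape):
        if support[idx]:
            ascend(idx)
    labels[~support] = 0
    return labels


def max_cluster_size_6conn(binary: np.ndarray) -> int:
    """Largest 6-connected component size, by explicit BFS."""
    visited = np.zeros(binary.shape, dtype=bool)
    best = 0
    nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for idx in np.argwhere(binary):
        idx = tuple(idx)
        if visited[idx]:
            continue
        size = 0
        q = deque([idx])
        visited[idx] = True
        while q:
            cur = q.popleft()
            size += 1
            for o in nbrs:
                n = tuple(np.add(cur, o))
                if all(0 <= n[a] < binary.shape[a] for a in range(3)) \
                        and binary[n] and not visited[n]:
                    visited[n] = True
                    q.append(n)
        best = max(best, size)
    return best


def ball_voxels(center, radius, shape) -> set[tuple[int, int, int]]:
    """Voxel-centre ball membership by explicit distance check."""
    out = set()
    for idx in np.ndindex(*shape):
        if sum((a - c) ** 2 for a, c in zip(idx, center)) <= radius ** 2 + 1e-12:
            out.add(idx)
    return out


def weighted_mean_oracle(effects, variances):
    """Closed-form inverse-variance weighted mean per element."""
    w = [1.0 / v for v in variances]
    num = sum(e * wi for e, wi in zip(effects, w))
    den = sum(w)
    return num / den, 1.0 / den
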