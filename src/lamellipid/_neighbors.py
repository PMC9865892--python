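"""Periodic neighbor search used by RDF, hydrogen bonds and ion contacts.

A plain cell list over the orthorhombic box, falling back to chunked brute
force whenever any dimension admits fewer than 3 cells (where cell offsets
would alias) or the problem is small enough that brute force wins anyway.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .traj_model import minimum_image

__all__ = ["neighbor_pairs"]

_BRUTE_CHUNK = 512


def _brute_force(pos_a, pos_b, box, cutoff):
    out_a, out_b, out_d = [], [], []
    for start in range(0, len(pos_a), _BRUTE_CHUNK):
        chunk = pos_a[start : start + _BRUTE_CHUNK]
        d = minimum_image(chunk[:, None, :], pos_b[None, :, :], box)
        dist = np.linalg.norm(d, axis=-1)
        ia, ib = np.nonzero(dist <= cutoff)
        out_a.append(ia + start)
        out_b.append(ib)
        out_d.append(dist[ia, ib])
    return np.concatenate(out_a), np.concatenate(out_b), np.concatenate(out_d)


def neighbor_pairs(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    box: np.ndarray,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (i, j) with minimum-image |pos_b[j] - pos_a[i]| <= cutoff.

    Returns (idx_a, idx_b, distances).  Self-pairs are NOT removed; callers
    comparing a selection with itself must drop i == j themselves.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise GeometryError("box lengths must be positive")
    if cutoff <= 0:
        raise GeometryError("cutoff must be positive")
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 3)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 3)
    if len(pos_a) == 0 or len(pos_b) == 0:
        empty = np.empty(0, dtype=int)
        return empty, empty, np.empty(0)

    n_cells = np.maximum(np.floor(box / cutoff).astype(int), 1)
    if np.any(n_cells < 3) or len(pos_a) * len(pos_b) <= 250_000:
        return _brute_force(pos_a, pos_b, box, cutoff)

    frac_a = np.mod(pos_a, box) / box
    frac_b = np.mod(pos_b, box) / box
    cell_a = np.minimum((frac_a * n_cells).astype(int), n_cells - 1)
    cell_b = np.minimum((frac_b * n_cells).astype(int), n_cells - 1)

    def flat(cells):
        return (cells[:, 0] * n_cells[1] + cells[:, 1]) * n_cells[2] + cells[:, 2]

    key_b = flat(cell_b)
    order_b = np.argsort(key_b, kind="stable")
    sorted_key_b = key_b[order_b]

    cand_a, cand_b = [], []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                shifted = np.mod(cell_a + np.array([di, dj, dk]), n_cells)
                key_a = flat(shifted)
                lo = np.searchsorted(sorted_key_b, key_a, side="left")
                hi = np.searchsorted(sorted_key_b, key_a, side="right")
                counts = hi - lo
                total = counts.sum()
                if total == 0:
                    continue
                ia = np.repeat(np.arange(len(pos_a)), counts)
                ranges = np.concatenate(
                    [np.arange(l, h) for l, h in zip(lo, hi) if h > l]
                )
                cand_a.append(ia)
                cand_b.append(order_b[ranges])
    if not cand_a:
        empty = np.empty(0, dtype=int)
        return empty, empty, np.empty(0)
    ia = np.concatenate(cand_a)
    ib = np.concatenate(cand_b)
    dist = np.linalg.norm(minimum_image(pos_a[ia], pos_b[ib], box), axis=-1)
    mask = dist <= cutoff
    return ia[mask], ib[mask], dist[mask]
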