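"""3-D topology-preserving thinning to a one-voxel-thick medial skeleton.

Sequential thinning ordered by the Euclidean distance transform: border
voxels (those with a background face neighbor) are visited outermost-first,
and a voxel is deleted immediately (sequentially) iff it is a *simple
point* — deleting it changes neither the number of 26-connected foreground
components nor the number of 6-connected background components — and not a
curve endpoint (it has at least two foreground 26-neighbors).  Simplicity
is decided locally in the 3x3x3 neighborhood by the standard two-number
characterization: exactly one 26-connected foreground component in the
26-neighborhood, and exactly one 6-connected background component in the
18-neighborhood that touches a face neighbor.  Sequential deletion makes
topology preservation exact; the distance ordering peels the object in
shells, keeping the skeleton on the medial ridge.  Endpoint preservation
retains curve ends, so a solid cylinder thins to a voxel chain along its
axis and an isolated voxel is its own skeleton.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage


@njit(cache=True)
def _is_simple(nbhd):
    """Simple-point test on a 3x3x3 uint8 neighborhood (center foreground)."""
    # exactly one 26-connected foreground component among the 26 neighbors
    lab = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    ncomp = 0
    for start in range(27):
        if start == 13:
            continue
        si, sj, sk = start // 9, (start // 3) % 3, start % 3
        if nbhd[si, sj, sk] == 0 or lab[start] != 0:
            continue
        ncomp += 1
        if ncomp > 1:
            return False
        sp = 0
        stack[sp] = start
        sp += 1
        lab[start] = 1
        while sp > 0:
            sp -= 1
            cur = stack[sp]
            ci, cj, ck = cur // 9, (cur // 3) % 3, cur % 3
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    for dk in range(-1, 2):
                        ni, nj, nk = ci + di, cj + dj, ck + dk
                        if 0 <= ni < 3 and 0 <= nj < 3 and 0 <= nk < 3:
                            nidx = ni * 9 + nj * 3 + nk
                            if nidx != 13 and nbhd[ni, nj, nk] != 0 and lab[nidx] == 0:
                                lab[nidx] = 1
                                stack[sp] = nidx
                                sp += 1
    if ncomp != 1:
        return False

    # exactly one 6-connected background component within the 18-neighborhood
    # reachable from a face neighbor (corners excluded from the region)
    lab2 = np.zeros(27, np.uint8)
    ncomp2 = 0
    for f in range(6):
        fi = 1 + _FACE[f, 0]
        fj = 1 + _FACE[f, 1]
        fk = 1 + _FACE[f, 2]
        fidx = fi * 9 + fj * 3 + fk
        if nbhd[fi, fj, fk] != 0 or lab2[fidx] != 0:
            continue
        ncomp2 += 1
        if ncomp2 > 1:
            return False
        sp = 0
        stack[sp] = fidx
        sp += 1
        lab2[fidx] = 1
        while sp > 0:
            sp -= 1
            cur = stack[sp]
            ci, cj, ck = cur // 9, (cur // 3) % 3, cur % 3
            for f2 in range(6):
                ni = ci + _FACE[f2, 0]
                nj = cj + _FACE[f2, 1]
                nk = ck + _FACE[f2, 2]
                if 0 <= ni < 3 and 0 <= nj < 3 and 0 <= nk < 3:
                    # stay inside N18: at most two offsets differ from center
                    if abs(ni - 1) + abs(nj - 1) + abs(nk - 1) > 2:
                        continue
                    nidx = ni * 9 + nj * 3 + nk
                    if nidx != 13 and nbhd[ni, nj, nk] == 0 and lab2[nidx] == 0:
                        lab2[nidx] = 1
                        stack[sp] = nidx
                        sp += 1
    return ncomp2 == 1


_FACE = np.array(
    [[0, 0, -1], [0, 0, 1], [0, -1, 0], [0, 1, 0], [-1, 0, 0], [1, 0, 0]], dtype=np.int64
)


@njit(cache=True)
def _thin_pass(img, xs, ys, zs):
    """One sequential pass over candidate voxels (already distance-ordered).

    Deletes border voxels that are simple and not curve endpoints; returns
    the number of deletions."""
    nbhd = np.empty((3, 3, 3), np.uint8)
    deleted = 0
    for n in range(xs.size):
        x, y, z = xs[n], ys[n], zs[n]
        if img[x, y, z] == 0:
            continue
        if (
            img[x - 1, y, z] != 0
            and img[x + 1, y, z] != 0
            and img[x, y - 1, z] != 0
            and img[x, y + 1, z] != 0
            and img[x, y, z - 1] != 0
            and img[x, y, z + 1] != 0
        ):
            continue  # interior voxel, not on the border
        nfg = 0
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    nbhd[i, j, k] = img[x + i - 1, y + j - 1, z + k - 1]
                    if nbhd[i, j, k] != 0:
                        nfg += 1
        if nfg - 1 <= 1:  # curve endpoint (or isolated voxel): keep
            continue
        if _is_simple(nbhd):
            img[x, y, z] = 0
            deleted += 1
    return deleted


def skeletonize_3d(mask: np.ndarray) -> np.ndarray:
    """Medial skeleton of a 3-D binary mask (topology-preserving thinning)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    padded = np.pad(mask, 1).astype(np.uint8)
    # one global priority: peel in order of distance from the original surface
    edt = ndimage.distance_transform_edt(padded)
    while True:
        xs, ys, zs = np.nonzero(padded)
        order = np.argsort(edt[xs, ys, zs], kind="stable")
        if _thin_pass(padded, xs[order], ys[order], zs[order]) == 0:
            break
    return padded[1:-1, 1:-1, 1:-1].astype(bool)
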