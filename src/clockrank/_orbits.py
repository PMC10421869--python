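"""Compiled kernel for per-node graphlet-orbit counting.

Enumerates, for a target node v, every connected induced subgraph on 2-4
nodes containing v — exactly once each, via the classic rooted
extension-set discipline (grow the subset only through neighbors, exclude
nodes already adjacent to the current subset, and never revisit an earlier
sibling) — and classifies v's automorphism orbit in each subgraph from the
induced edge count and within-subgraph degrees.

Orbit ids follow the standard 15-orbit convention for 2-4-node graphlets:
0 edge; 1/2 path-P3 end/mid; 3 triangle; 4/5 path-P4 end/mid; 6/7 claw
leaf/center; 8 cycle-C4; 9/10/11 paw pendant/cycle-mid/apex; 12/13 diamond
degree-2/degree-3; 14 K4.
"""

import numpy as np
from numba import njit

N_ORBITS = 15


@njit(inline="always")
def _is_edge(indptr, indices, u, v):
    lo = indptr[u]
    hi = indptr[u + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        x = indices[mid]
        if x == v:
            return 1
        elif x < v:
            lo = mid + 1
        else:
            hi = mid
    return 0


@njit
def _count_node(indptr, indices, v, mark, ext1, ext2, ext3, counts):
    """Accumulate the 15 orbit counts of node v into ``counts`` (zeroed by
    the caller).  ``mark`` is an all-zero scratch array restored on exit."""
    deg_v = indptr[v + 1] - indptr[v]
    counts[0] = deg_v
    mark[v] = 1
    n1 = 0
    for ii in range(indptr[v], indptr[v + 1]):
        u = indices[ii]
        ext1[n1] = u
        n1 += 1
        mark[u] = 1
    for i1 in range(n1):
        a = ext1[i1]
        # extension set for S={v,a}: later level-1 siblings plus exclusive
        # neighbors of a (nodes not already in S or adjacent to S)
        n2 = 0
        for j in range(i1 + 1, n1):
            ext2[n2] = ext1[j]
            n2 += 1
        new2 = n2
        for ii in range(indptr[a], indptr[a + 1]):
            u = indices[ii]
            if mark[u] == 0:
                mark[u] = 2
                ext2[n2] = u
                n2 += 1
        for i2 in range(n2):
            b = ext2[i2]
            vb = _is_edge(indptr, indices, v, b)
            ab = _is_edge(indptr, indices, a, b)
            # classify S={v,a,b}; edge v-a is guaranteed
            if vb + ab == 2:
                counts[3] += 1
            elif vb == 1:
                counts[2] += 1  # v adjacent to both: P3 mid
            else:
                counts[1] += 1  # v-a-b path: P3 end
            n3 = 0
            for j in range(i2 + 1, n2):
                ext3[n3] = ext2[j]
                n3 += 1
            new3 = n3
            for ii in range(indptr[b], indptr[b + 1]):
                u = indices[ii]
                if mark[u] == 0:
                    mark[u] = 3
                    ext3[n3] = u
                    n3 += 1
            for i3 in range(n3):
                c = ext3[i3]
                vc = _is_edge(indptr, indices, v, c)
                ac = _is_edge(indptr, indices, a, c)
                bc = _is_edge(indptr, indices, b, c)
                e = 1 + vb + ab + vc + ac + bc
                dv = 1 + vb + vc
                if e == 6:
                    counts[14] += 1
                elif e == 5:
                    if dv == 3:
                        counts[13] += 1
                    else:
                        counts[12] += 1
                elif e == 4:
                    da = 1 + ab + ac
                    db = vb + ab + bc
                    dc = vc + ac + bc
                    if dv == 2 and da == 2 and db == 2 and dc == 2:
                        counts[8] += 1
                    elif dv == 1:
                        counts[9] += 1
                    elif dv == 3:
                        counts[11] += 1
                    else:
                        counts[10] += 1
                else:  # e == 3: tree — star (some degree 3) or path
                    da = 1 + ab + ac
                    db = vb + ab + bc
                    dc = vc + ac + bc
                    if dv == 3:
                        counts[7] += 1
                    elif da == 3 or db == 3 or dc == 3:
                        counts[6] += 1
                    elif dv == 2:
                        counts[5] += 1
                    else:
                        counts[4] += 1
            for j in range(new3, n3):
                mark[ext3[j]] = 0
        for j in range(new2, n2):
            mark[ext2[j]] = 0
    mark[v] = 0
    for j in range(n1):
        mark[ext1[j]] = 0


@njit
def orbit_counts(indptr, indices, targets):
    """Orbit-count matrix (len(targets) x 15) for the given node indices."""
    n = indptr.shape[0] - 1
    out = np.zeros((targets.shape[0], N_ORBITS), dtype=np.int64)
    mark = np.zeros(n, dtype=np.int8)
    ext1 = np.empty(n, dtype=np.int64)
    ext2 = np.empty(n, dtype=np.int64)
    ext3 = np.empty(n, dtype=np.int64)
    for t in range(targets.shape[0]):
        _count_node(indptr, indices, targets[t], mark, ext1, ext2, ext3, out[t])
    return out
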