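"""Naive persistent homology by full boundary-matrix reduction.

Independent oracle for the optimized cohomology engine: textbook column
reduction of the Z_p boundary matrix of the full Rips filtration.  Only
usable for tiny point sets (all simplices up to dim maxdim+1 are built).
"""

from itertools import combinations

import numpy as np


def naive_rips_barcode(D, maxdim=1, thresh=None, p=47):
    """Barcode [(dim, birth, death)] of the Rips filtration, brute force."""
    n = D.shape[0]
    if thresh is None:
        thresh = float(np.min(np.max(D, axis=1)))
    simplices = []  # (diam, dim, vertices)
    for d in range(maxdim + 2):
        for vs in combinations(range(n), d + 1):
            diam = max((D[a, b] for a, b in combinations(vs, 2)), default=0.0)
            if diam <= thresh:
                simplices.append((diam, d, vs))
    # filtration order: faces strictly before cofaces
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: i for i, s in enumerate(simplices)}

    # sparse columns: dict row -> coeff (mod p)
    columns = []
    for diam, d, vs in simplices:
        col = {}
        if d > 0:
            for t in range(d + 1):
                face = vs[:t] + vs[t + 1:]
                col[index[face]] = (-1) ** t % p
        columns.append(col)

    low_inv = {}  # low row -> column index
    pairs = []
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = max(col)
            if low not in low_inv:
                break
            k = low_inv[low]
            lam = (p - col[low]) * pow(columns[k][low], p - 2, p) % p
            for r, c in columns[k].items():
                col[r] = (col.get(r, 0) + lam * c) % p
                if col[r] == 0:
                    del col[r]
        if col:
            low = max(col)
            low_inv[low] = j
            pairs.append((low, j))

    paired = set()
    bars = []
    for i, j in pairs:
        paired.add(i)
        paired.add(j)
        dim = simplices[i][1]
        birth, death = simplices[i][0], simplices[j][0]
        if death > birth and dim <= maxdim:
            bars.append((dim, birth, death))
    for i, (diam, d, vs) in enumerate(simplices):
        if i not in paired and d <= maxdim:
            bars.append((d, diam, np.inf))
    bars.sort(key=lambda b: (b[0], -(b[2] - b[1]), b[1]))
    return bars
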