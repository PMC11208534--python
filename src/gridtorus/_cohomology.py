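"""Vietoris–Rips persistent cohomology over a prime field.

Low-level engine computing barcodes (dimensions 0..maxdim) and representative
1-cocycles from a dense distance matrix.  The implementation follows the
standard persistent-cohomology reduction: columns are coboundaries of
d-simplices processed in reverse filtration order, with the clearing
optimization and the emergent-pair shortcut, and the enclosing-radius
threshold so that no spurious essential classes appear above dimension 0.

Simplices are encoded in the combinatorial number system; the inner loops are
numba-compiled.  Public entry point: :func:`rips_cohomology`.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import Dict
from numba.core import types

__all__ = ["rips_cohomology"]


# ---------------------------------------------------------------- utilities


def _binom_table(n: int, kmax: int) -> np.ndarray:
    """Pascal triangle, binom[i, j] = C(i, j), int64."""
    b = np.zeros((n + 1, kmax + 1), dtype=np.int64)
    b[:, 0] = 1
    for i in range(1, n + 1):
        for j in range(1, kmax + 1):
            b[i, j] = b[i - 1, j - 1] + b[i - 1, j]
    return b


@njit(cache=False)
def _max_vertex(idx, k, upper, binom):
    """Largest v < upper with binom[v, k] <= idx (binary search)."""
    lo, hi = k - 1, upper
    # binom[lo,k]=0 <= idx always; find largest feasible
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if binom[mid, k] <= idx:
            lo = mid
        else:
            hi = mid
    return lo


@njit(cache=False)
def _simplex_vertices(idx, dim, n, binom, out):
    """Decode combinatorial index into dim+1 vertices, descending order."""
    v = n
    rem = idx
    for k in range(dim + 1, 0, -1):
        v = _max_vertex(rem, k, v, binom)
        out[dim + 1 - k] = v
        rem -= binom[v, k]
    return out


@njit(cache=False)
def _heap_less(d1, i1, d2, i2):
    # Priority for pivot extraction: smaller diameter first, ties broken by
    # larger combinatorial index (reverse filtration order).
    if d1 != d2:
        return d1 < d2
    return i1 > i2


@njit(cache=False)
def _heap_push(hd, hi, hc, size, d, i, c):
    j = size
    hd[j] = d
    hi[j] = i
    hc[j] = c
    while j > 0:
        par = (j - 1) >> 1
        if _heap_less(hd[j], hi[j], hd[par], hi[par]):
            hd[j], hd[par] = hd[par], hd[j]
            hi[j], hi[par] = hi[par], hi[j]
            hc[j], hc[par] = hc[par], hc[j]
            j = par
        else:
            break
    return size + 1


@njit(cache=False)
def _heap_pop(hd, hi, hc, size):
    last = size - 1
    hd[0], hd[last] = hd[last], hd[0]
    hi[0], hi[last] = hi[last], hi[0]
    hc[0], hc[last] = hc[last], hc[0]
    j = 0
    while True:
        l = 2 * j + 1
        r = l + 1
        best = j
        if l < last and _heap_less(hd[l], hi[l], hd[best], hi[best]):
            best = l
        if r < last and _heap_less(hd[r], hi[r], hd[best], hi[best]):
            best = r
        if best == j:
            break
        hd[j], hd[best] = hd[best], hd[j]
        hi[j], hi[best] = hi[best], hi[j]
        hc[j], hc[best] = hc[best], hc[j]
        j = best
    return last


@njit(cache=False)
def _union_find_dim0(n, edge_idx, edge_diam, order, binom):
    """Kruskal pass: 0-dim pairs and the cycle edges (columns for dim 1).

    Returns (deaths of finite H0 bars, number of infinite H0 bars,
    mask of cycle edges in `order`'s ordering).
    """
    parent = np.arange(n)
    deaths = np.empty(len(order), dtype=np.float64)
    ndeaths = 0
    is_cycle = np.zeros(len(order), dtype=np.bool_)
    for oi in range(len(order)):
        e = order[oi]
        # decode edge
        i = _max_vertex(edge_idx[e], 2, n, binom)
        j = edge_idx[e] - binom[i, 2]
        ri = i
        while parent[ri] != ri:
            parent[ri] = parent[parent[ri]]
            ri = parent[ri]
        rj = j
        while parent[rj] != rj:
            parent[rj] = parent[parent[rj]]
            rj = parent[rj]
        if ri == rj:
            is_cycle[oi] = True
        else:
            parent[ri] = rj
            deaths[ndeaths] = edge_diam[e]
            ndeaths += 1
    ncomp = 0
    for v in range(n):
        if parent[v] == v:
            ncomp += 1
    return deaths[:ndeaths], ncomp, is_cycle


@njit(cache=False)
def _reduce_dimension(
    D,
    n,
    dim,
    col_idx,
    col_diam,
    thresh,
    p,
    inv,
    binom,
    want_cocycles,
):
    """Reduce the coboundary matrix of `dim`-simplex columns.

    Columns must be sorted in reverse filtration order (decreasing diameter,
    increasing index among ties).  Returns persistence pairs, essential
    births, the pivot lookup (for clearing in dim+1), and, if requested,
    representative cocycles for every emitted pair.
    """
    ncols = col_idx.shape[0]
    signs = np.empty(dim + 3, dtype=np.int64)
    for t in range(dim + 3):
        signs[t] = 1 if t % 2 == 0 else p - 1

    pivot_lookup = Dict.empty(types.int64, types.int64)
    pivot_coeff = np.empty(ncols, dtype=np.int64)

    # stored reduction-matrix columns (V), flattened
    v_idx = np.empty(4 * ncols + 16, dtype=np.int64)
    v_coef = np.empty(4 * ncols + 16, dtype=np.int64)
    v_ptr = np.zeros(ncols + 1, dtype=np.int64)
    v_used = 0
    col_of_store = np.empty(ncols, dtype=np.int64)  # store slot -> column pos
    nstored = 0
    store_of_col = np.full(ncols, -1, dtype=np.int64)

    births = np.empty(ncols, dtype=np.float64)
    deaths = np.empty(ncols, dtype=np.float64)
    npairs = 0
    essential = np.empty(ncols, dtype=np.float64)
    ness = 0

    # cocycle output (dim-1 representatives)
    coc_idx = np.empty(16, dtype=np.int64)
    coc_coef = np.empty(16, dtype=np.int64)
    coc_ptr = np.zeros(ncols + 1, dtype=np.int64)
    coc_used = 0
    ncoc = 0

    # scratch
    verts = np.empty(dim + 1, dtype=np.int64)
    fverts = np.empty(dim + 1, dtype=np.int64)
    hcap = 1024
    hd = np.empty(hcap, dtype=np.float64)
    hi = np.empty(hcap, dtype=np.int64)
    hc = np.empty(hcap, dtype=np.int64)
    wv_cap = 256
    wv_idx = np.empty(wv_cap, dtype=np.int64)
    wv_coef = np.empty(wv_cap, dtype=np.int64)

    init_cap = 256
    init_d = np.empty(init_cap, dtype=np.float64)
    init_i = np.empty(init_cap, dtype=np.int64)
    init_c = np.empty(init_cap, dtype=np.int64)

    for cpos in range(ncols):
        sidx = col_idx[cpos]
        sdiam = col_diam[cpos]
        _simplex_vertices(sidx, dim, n, binom, verts)

        # working V column starts as the unit column
        wv_n = 1
        wv_idx[0] = sidx
        wv_coef[0] = 1
        hsize = 0

        # --- initialize coboundary, with emergent-pair shortcut -----------
        pivot_idx = np.int64(-1)
        pivot_diam = 0.0
        pivot_c = np.int64(0)
        emergent = False
        check_emergent = True
        ninit = 0

        idx_below = sidx
        idx_above = np.int64(0)
        v = np.int64(n - 1)
        k = np.int64(dim + 1)
        while v >= k:
            while v >= k and binom[v, k] <= idx_below:
                idx_below -= binom[v, k]
                idx_above += binom[v, k + 1]
                v -= 1
                k -= 1
            if v < k:
                break
            cof_diam = sdiam
            for t in range(dim + 1):
                dvw = D[v, verts[t]]
                if dvw > cof_diam:
                    cof_diam = dvw
            cof_idx = idx_above + binom[v, k + 1] + idx_below
            cof_c = signs[k]
            v -= 1
            if cof_diam <= thresh:
                if ninit >= init_cap:
                    init_cap *= 2
                    nd = np.empty(init_cap, dtype=np.float64)
                    ni = np.empty(init_cap, dtype=np.int64)
                    nc = np.empty(init_cap, dtype=np.int64)
                    nd[:ninit] = init_d[:ninit]
                    ni[:ninit] = init_i[:ninit]
                    nc[:ninit] = init_c[:ninit]
                    init_d, init_i, init_c = nd, ni, nc
                init_d[ninit] = cof_diam
                init_i[ninit] = cof_idx
                init_c[ninit] = cof_c
                ninit += 1
                if check_emergent and cof_diam == sdiam:
                    if cof_idx not in pivot_lookup:
                        pivot_idx = cof_idx
                        pivot_diam = cof_diam
                        pivot_c = cof_c
                        emergent = True
                        break
                    check_emergent = False

        if not emergent:
            if hcap < ninit + 16:
                while hcap < ninit + 16:
                    hcap *= 2
                hd = np.empty(hcap, dtype=np.float64)
                hi = np.empty(hcap, dtype=np.int64)
                hc = np.empty(hcap, dtype=np.int64)
            for t in range(ninit):
                hsize = _heap_push(hd, hi, hc, hsize, init_d[t], init_i[t], init_c[t])

        # --- reduction loop ----------------------------------------------
        while True:
            if not emergent:
                # extract pivot: combine equal entries mod p
                pivot_idx = np.int64(-1)
                while hsize > 0:
                    d0 = hd[0]
                    i0 = hi[0]
                    c0 = np.int64(0)
                    while hsize > 0 and hi[0] == i0:
                        c0 = (c0 + hc[0]) % p
                        hsize = _heap_pop(hd, hi, hc, hsize)
                    if c0 != 0:
                        pivot_idx = i0
                        pivot_diam = d0
                        pivot_c = c0
                        break
                if pivot_idx == -1:
                    essential[ness] = sdiam
                    ness += 1
                    break

            if pivot_idx in pivot_lookup:
                # (an emergent pivot is by construction unpaired, so the heap
                # is fully initialized whenever we reach this branch)
                other = pivot_lookup[pivot_idx]
                store = store_of_col[other]
                lam = ((p - pivot_c) * inv[pivot_coeff[other]]) % p
                # push pivot back (it must cancel against the addition)
                if hsize + 1 > hcap:
                    hcap *= 2
                    nd = np.empty(hcap, dtype=np.float64)
                    ni = np.empty(hcap, dtype=np.int64)
                    nc = np.empty(hcap, dtype=np.int64)
                    nd[:hsize] = hd[:hsize]
                    ni[:hsize] = hi[:hsize]
                    nc[:hsize] = hc[:hsize]
                    hd, hi, hc = nd, ni, nc
                hsize = _heap_push(hd, hi, hc, hsize, pivot_diam, pivot_idx, pivot_c)

                # add lam * column `other` (its stored V entries)
                for q in range(v_ptr[store], v_ptr[store + 1]):
                    fidx = v_idx[q]
                    fc = (v_coef[q] * lam) % p
                    if fc == 0:
                        continue
                    # append to working V
                    if wv_n >= wv_cap:
                        wv_cap *= 2
                        nidx = np.empty(wv_cap, dtype=np.int64)
                        ncoe = np.empty(wv_cap, dtype=np.int64)
                        nidx[:wv_n] = wv_idx[:wv_n]
                        ncoe[:wv_n] = wv_coef[:wv_n]
                        wv_idx, wv_coef = nidx, ncoe
                    wv_idx[wv_n] = fidx
                    wv_coef[wv_n] = fc
                    wv_n += 1
                    # push cofacets of fidx
                    _simplex_vertices(fidx, dim, n, binom, fverts)
                    fdiam = 0.0
                    for a in range(dim + 1):
                        for b in range(a + 1, dim + 1):
                            dab = D[fverts[a], fverts[b]]
                            if dab > fdiam:
                                fdiam = dab
                    ib = fidx
                    ia = np.int64(0)
                    vv = np.int64(n - 1)
                    kk = np.int64(dim + 1)
                    while vv >= kk:
                        while vv >= kk and binom[vv, kk] <= ib:
                            ib -= binom[vv, kk]
                            ia += binom[vv, kk + 1]
                            vv -= 1
                            kk -= 1
                        if vv < kk:
                            break
                        cdm = fdiam
                        for t in range(dim + 1):
                            dvw = D[vv, fverts[t]]
                            if dvw > cdm:
                                cdm = dvw
                        cix = ia + binom[vv, kk + 1] + ib
                        ccf = (signs[kk] * fc) % p
                        vv -= 1
                        if cdm <= thresh:
                            if hsize + 1 > hcap:
                                hcap *= 2
                                nd = np.empty(hcap, dtype=np.float64)
                                ni = np.empty(hcap, dtype=np.int64)
                                nc = np.empty(hcap, dtype=np.int64)
                                nd[:hsize] = hd[:hsize]
                                ni[:hsize] = hi[:hsize]
                                nc[:hsize] = hc[:hsize]
                                hd, hi, hc = nd, ni, nc
                            hsize = _heap_push(hd, hi, hc, hsize, cdm, cix, ccf)
                continue

            # new pivot: record pair, store V column
            pivot_lookup[pivot_idx] = cpos
            pivot_coeff[cpos] = pivot_c
            if v_used + wv_n > v_idx.shape[0]:
                newcap = v_idx.shape[0]
                while newcap < v_used + wv_n:
                    newcap *= 2
                nvi = np.empty(newcap, dtype=np.int64)
                nvc = np.empty(newcap, dtype=np.int64)
                nvi[:v_used] = v_idx[:v_used]
                nvc[:v_used] = v_coef[:v_used]
                v_idx, v_coef = nvi, nvc
            for q in range(wv_n):
                v_idx[v_used] = wv_idx[q]
                v_coef[v_used] = wv_coef[q]
                v_used += 1
            store_of_col[cpos] = nstored
            col_of_store[nstored] = cpos
            v_ptr[nstored + 1] = v_used
            nstored += 1

            if pivot_diam > sdiam:
                births[npairs] = sdiam
                deaths[npairs] = pivot_diam
                npairs += 1
                if want_cocycles:
                    if coc_used + wv_n > coc_idx.shape[0]:
                        newcap = coc_idx.shape[0]
                        while newcap < coc_used + wv_n:
                            newcap *= 2
                        nci = np.empty(newcap, dtype=np.int64)
                        ncc = np.empty(newcap, dtype=np.int64)
                        nci[:coc_used] = coc_idx[:coc_used]
                        ncc[:coc_used] = coc_coef[:coc_used]
                        coc_idx, coc_coef = nci, ncc
                    for q in range(wv_n):
                        coc_idx[coc_used] = wv_idx[q]
                        coc_coef[coc_used] = wv_coef[q]
                        coc_used += 1
                    ncoc += 1
                    coc_ptr[ncoc] = coc_used
            break

    return (
        births[:npairs],
        deaths[:npairs],
        essential[:ness],
        pivot_lookup,
        coc_idx[:coc_used],
        coc_coef[:coc_used],
        coc_ptr[: ncoc + 1],
    )


@njit(cache=False)
def _in_sorted(arr, x):
    lo, hi = 0, arr.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo < arr.shape[0] and arr[lo] == x


@njit(cache=False)
def _assemble_columns(D, n, dim, thresh, cleared, binom):
    """Enumerate `dim`-simplices with diameter <= thresh, skipping cleared
    ones (pivots of the previous dimension's reduction, sorted array)."""
    cap = 4096
    idxs = np.empty(cap, dtype=np.int64)
    diams = np.empty(cap, dtype=np.float64)
    count = 0
    if dim == 2:
        for k in range(2, n):
            for j in range(1, k):
                djk = D[j, k]
                base = binom[k, 3] + binom[j, 2]
                for i in range(j):
                    dm = djk
                    if D[i, j] > dm:
                        dm = D[i, j]
                    if D[i, k] > dm:
                        dm = D[i, k]
                    if dm <= thresh:
                        idx = base + i
                        if _in_sorted(cleared, idx):
                            continue
                        if count >= cap:
                            cap *= 2
                            ni = np.empty(cap, dtype=np.int64)
                            nd = np.empty(cap, dtype=np.float64)
                            ni[:count] = idxs[:count]
                            nd[:count] = diams[:count]
                            idxs, diams = ni, nd
                        idxs[count] = idx
                        diams[count] = dm
                        count += 1
        return idxs[:count], diams[:count]
    # generic dimension: decode every index (used only for dim >= 3)
    total = binom[n, dim + 1]
    verts = np.empty(dim + 1, dtype=np.int64)
    for idx in range(total):
        if _in_sorted(cleared, idx):
            continue
        _simplex_vertices(idx, dim, n, binom, verts)
        dm = 0.0
        for a in range(dim + 1):
            for b in range(a + 1, dim + 1):
                dab = D[verts[a], verts[b]]
                if dab > dm:
                    dm = dab
        if dm <= thresh:
            if count >= cap:
                cap *= 2
                ni = np.empty(cap, dtype=np.int64)
                nd = np.empty(cap, dtype=np.float64)
                ni[:count] = idxs[:count]
                nd[:count] = diams[:count]
                idxs, diams = ni, nd
            idxs[count] = idx
            diams[count] = dm
            count += 1
    return idxs[:count], diams[:count]


def rips_cohomology(D, maxdim=2, thresh=None, p=47, cocycles=True):
    """Persistent cohomology of the Vietoris–Rips filtration of ``D``.

    Parameters
    ----------
    D : (n, n) ndarray
        Dense symmetric distance matrix, zero diagonal, finite entries.
    maxdim : int
        Largest homological dimension computed (0..maxdim).
    thresh : float, optional
        Filtration cutoff.  Defaults to the enclosing radius
        ``min_i max_j D[i, j]``, beyond which the complex is a cone and no
        homology above dimension 0 survives.
    p : int
        Prime for the coefficient field Z_p.
    cocycles : bool
        Store representative cocycles for dimension-1 bars.

    Returns
    -------
    bars : list of (dim, birth, death) with ``death = inf`` for essential
        classes, sorted by dimension then decreasing lifetime.
    reps : dict mapping the position of a dimension-1 bar (its index among
        the returned dim-1 bars) to an ``(n_edges, 3)`` int/float structured
        view ``(i, j, coeff)`` of its representative cocycle.
    """
    D = np.ascontiguousarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if maxdim < 0:
        raise ValueError("maxdim must be nonnegative")
    if n == 0:
        return [], {}
    if n == 1:
        return [(0, 0.0, np.inf)], {}
    if thresh is None:
        thresh = float(np.min(np.max(D, axis=1)))
    binom = _binom_table(n, maxdim + 3)
    inv = np.zeros(p, dtype=np.int64)
    for c in range(1, p):
        inv[c] = pow(c, p - 2, p)

    # ---- edges & dimension 0
    iu, ju = np.triu_indices(n, k=1)
    ediam = D[iu, ju]
    eidx = binom[ju, 2] + iu  # vertices (j > i): index = C(j,2) + i
    keep = ediam <= thresh
    eidx, ediam = eidx[keep], ediam[keep]
    order = np.lexsort((eidx, ediam))  # filtration order: diam asc, idx asc
    deaths0, ncomp, is_cycle = _union_find_dim0(n, eidx, ediam, order, binom)

    by_dim = {d: [] for d in range(maxdim + 1)}
    coc_by_dim1 = []  # aligned with by_dim[1]
    for dth in deaths0:
        if dth > 0:
            by_dim[0].append((0.0, float(dth)))
    for _ in range(ncomp):
        by_dim[0].append((0.0, np.inf))

    if maxdim == 0:
        return _finalize(by_dim, coc_by_dim1, maxdim)

    # columns for dim 1: cycle edges, reverse filtration order
    cyc = order[is_cycle]
    col_idx = eidx[cyc]
    col_diam = ediam[cyc]
    rorder = np.lexsort((col_idx, -col_diam))
    col_idx = np.ascontiguousarray(col_idx[rorder])
    col_diam = np.ascontiguousarray(col_diam[rorder])

    vbuf = np.empty(2, dtype=np.int64)
    for dim in range(1, maxdim + 1):
        want_coc = cocycles and dim == 1
        (
            births,
            deaths,
            essential,
            pivot_lookup,
            coc_i,
            coc_c,
            coc_ptr,
        ) = _reduce_dimension(
            D, n, dim, col_idx, col_diam, thresh, p, inv, binom, want_coc
        )
        for t, (b, d) in enumerate(zip(births, deaths)):
            by_dim[dim].append((float(b), float(d)))
            if want_coc:
                lo, hi_ = coc_ptr[t], coc_ptr[t + 1]
                edges = np.empty((hi_ - lo, 3), dtype=np.float64)
                for q in range(lo, hi_):
                    _simplex_vertices(coc_i[q], 1, n, binom, vbuf)
                    c = coc_c[q]
                    if c > p // 2:  # lift to integers in (-p/2, p/2)
                        c -= p
                    edges[q - lo, 0] = vbuf[1]  # smaller vertex
                    edges[q - lo, 1] = vbuf[0]  # larger vertex
                    edges[q - lo, 2] = c
                coc_by_dim1.append(edges)
        for e in essential:
            by_dim[dim].append((float(e), np.inf))
            if want_coc:
                coc_by_dim1.append(None)
        if dim < maxdim:
            cleared = np.sort(np.array(list(pivot_lookup.keys()), dtype=np.int64))
            nxt_idx, nxt_diam = _assemble_columns(
                D, n, dim + 1, thresh, cleared, binom
            )
            ro = np.lexsort((nxt_idx, -nxt_diam))
            col_idx = np.ascontiguousarray(nxt_idx[ro])
            col_diam = np.ascontiguousarray(nxt_diam[ro])

    return _finalize(by_dim, coc_by_dim1, maxdim)


def _finalize(by_dim, coc_by_dim1, maxdim):
    """Sort bars by (dim, decreasing lifetime); reps keyed by (1, rank)."""
    bars = []
    reps = {}
    for d in range(maxdim + 1):
        idx_sorted = sorted(
            range(len(by_dim[d])), key=lambda t: -(by_dim[d][t][1] - by_dim[d][t][0])
        )
        for rank, t in enumerate(idx_sorted):
            b, dth = by_dim[d][t]
            bars.append((d, b, dth))
            if d == 1 and coc_by_dim1 and coc_by_dim1[t] is not None:
                reps[(1, rank)] = coc_by_dim1[t]
    return bars, reps
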