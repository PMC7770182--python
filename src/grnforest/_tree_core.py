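"""Low-level weighted regression-tree kernels.

Everything here is numba-jitted (with a transparent pure-Python fallback) and
operates on flat, preallocated arrays so a whole forest is grown without
touching the Python object layer. Trees are stored structure-of-arrays:
``features`` holds the split variable per node (-1 marks a leaf),
``thresholds`` the cut, ``lefts``/``rights`` the child slots, ``values`` the
weighted leaf mean, and ``nws``/``sqs`` the weighted count N_w and weighted
sum of squared deviations Sq_w of the samples allocated to the node.

Randomness is consumed in a fixed, documented order per node (split-mode
coin for VR-Trees, then candidate sampling, then cut draws) and each tree
seeds the generator from its own entry of a per-forest seed array, so
forests are reproducible across runs and platforms.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


METHOD_RF = 0
METHOD_RF_PAIRED = 1
METHOD_EXTRA = 2
METHOD_VR = 3


@njit(cache=True)
def _sort3(xs, ys, ws, lo, hi):
    """In-place ascending quicksort of xs[lo:hi], co-moving ys and ws.

    Iterative, median-of-three pivot, insertion sort below 16 elements; the
    larger partition is pushed first so the stack stays logarithmic.
    """
    stack = np.empty(128, np.int64)
    stack[0] = lo
    stack[1] = hi
    top = 2
    while top > 0:
        b = stack[top - 1]
        a = stack[top - 2]
        top -= 2
        while b - a > 16:
            mid = (a + b) // 2
            last = b - 1
            if xs[a] > xs[mid]:
                xs[a], xs[mid] = xs[mid], xs[a]
                ys[a], ys[mid] = ys[mid], ys[a]
                ws[a], ws[mid] = ws[mid], ws[a]
            if xs[a] > xs[last]:
                xs[a], xs[last] = xs[last], xs[a]
                ys[a], ys[last] = ys[last], ys[a]
                ws[a], ws[last] = ws[last], ws[a]
            if xs[mid] > xs[last]:
                xs[mid], xs[last] = xs[last], xs[mid]
                ys[mid], ys[last] = ys[last], ys[mid]
                ws[mid], ws[last] = ws[last], ws[mid]
            pivot = xs[mid]
            i = a
            j = last
            while i <= j:
                while xs[i] < pivot:
                    i += 1
                while xs[j] > pivot:
                    j -= 1
                if i <= j:
                    xs[i], xs[j] = xs[j], xs[i]
                    ys[i], ys[j] = ys[j], ys[i]
                    ws[i], ws[j] = ws[j], ws[i]
                    i += 1
                    j -= 1
            # iterate on the smaller side, push the larger
            if (j + 1 - a) >= (b - i):
                stack[top] = a
                stack[top + 1] = j + 1
                top += 2
                a = i
            else:
                stack[top] = i
                stack[top + 1] = b
                top += 2
                b = j + 1
        # insertion sort for the remaining short range
        for i in range(a + 1, b):
            xv = xs[i]
            yv = ys[i]
            wv = ws[i]
            j = i - 1
            while j >= a and xs[j] > xv:
                xs[j + 1] = xs[j]
                ys[j + 1] = ys[j]
                ws[j + 1] = ws[j]
                j -= 1
            xs[j + 1] = xv
            ys[j + 1] = yv
            ws[j + 1] = wv


@njit(cache=True)
def _sample_distinct(perm, m, k):
    """Partial Fisher-Yates into the workspace ``perm``; first k entries are
    the sample, returned sorted ascending (insertion sort, k is small)."""
    for t in range(m):
        perm[t] = t
    for t in range(k):
        r = t + np.random.randint(0, m - t)
        perm[t], perm[r] = perm[r], perm[t]
    for i in range(1, k):
        v = perm[i]
        j = i - 1
        while j >= 0 and perm[j] > v:
            perm[j + 1] = perm[j]
            j -= 1
        perm[j + 1] = v


@njit(cache=True)
def _det_scan(X, y, w, idx, lo, hi, cand, k_cand, sw, swy, swyy, sq_p, literal, xs, ys, ws):
    """Exhaustive scan over midpoint cuts of the candidate variables.

    Exact ties in gain are common at small nodes (any cut separating two
    rows has the same gain), so the winner among exactly-tied (variable,
    cut) pairs is reservoir-sampled from the tree's seeded stream: a
    deterministic lowest-index rule would systematically favour low-index
    columns, which breaks the even-chances premise of the shadow-feature
    relevance test. Results remain reproducible under the seed.
    """
    n = hi - lo
    best_gain = -1.0
    best_var = -1
    best_cut = 0.0
    n_tied = 1
    for ci in range(k_cand):
        v = cand[ci]
        xmin = X[idx[lo], v]
        xmax = xmin
        for j in range(n):
            k = idx[lo + j]
            xv = X[k, v]
            xs[j] = xv
            ys[j] = y[k]
            ws[j] = w[k]
            if xv < xmin:
                xmin = xv
            elif xv > xmax:
                xmax = xv
        if xmax <= xmin:
            continue
        _sort3(xs, ys, ws, 0, n)
        csw = 0.0
        cswy = 0.0
        cswyy = 0.0
        for jj in range(n - 1):
            yv = ys[jj]
            wv = ws[jj]
            csw += wv
            cswy += wv * yv
            cswyy += wv * yv * yv
            a = xs[jj]
            b = xs[jj + 1]
            if b <= a:
                continue
            sql = cswyy - cswy * cswy / csw
            if sql < 0.0:
                sql = 0.0
            rw = sw - csw
            rwy = swy - cswy
            rwyy = swyy - cswyy
            sqr = rwyy - rwy * rwy / rw
            if sqr < 0.0:
                sqr = 0.0
            if literal:
                gain = sw * sq_p - csw * sql - rw * sqr
            else:
                gain = sq_p - sql - sqr
            if gain > best_gain:
                best_gain = gain
                best_var = v
                best_cut = 0.5 * (a + b)
                n_tied = 1
            elif gain == best_gain and best_var >= 0:
                n_tied += 1
                if np.random.random() * n_tied < 1.0:
                    best_var = v
                    best_cut = 0.5 * (a + b)
    return best_gain, best_var, best_cut


@njit(cache=True)
def _cut_gain(X, y, w, idx, lo, hi, v, cut, sw, swy, swyy, sq_p, literal):
    """Gain of a given (variable, cut); -1 if a child would be empty."""
    n = hi - lo
    csw = 0.0
    cswy = 0.0
    cswyy = 0.0
    nl = 0
    for j in range(lo, hi):
        k = idx[j]
        if X[k, v] <= cut:
            csw += w[k]
            cswy += w[k] * y[k]
            cswyy += w[k] * y[k] * y[k]
            nl += 1
    if nl == 0 or nl == n:
        return -1.0
    sql = cswyy - cswy * cswy / csw
    if sql < 0.0:
        sql = 0.0
    rw = sw - csw
    rwy = swy - cswy
    rwyy = swyy - cswyy
    sqr = rwyy - rwy * rwy / rw
    if sqr < 0.0:
        sqr = 0.0
    if literal:
        return sw * sq_p - csw * sql - rw * sqr
    return sq_p - sql - sqr


@njit(cache=True)
def _build_tree(
    X,
    y,
    w,
    inbag_idx,
    method,
    n_test,
    h_max,
    min_node,
    vr_alpha,
    literal,
    features,
    thresholds,
    lefts,
    rights,
    values,
    nws,
    sqs,
    imp_row,
    idx,
    tmp,
    xs,
    ys,
    ws,
    perm,
    cand,
):
    n_total = inbag_idx.shape[0]
    M = X.shape[1]
    for j in range(n_total):
        idx[j] = inbag_idx[j]
    maxn = features.shape[0]
    stack_slot = np.empty(maxn, np.int64)
    stack_lo = np.empty(maxn, np.int64)
    stack_hi = np.empty(maxn, np.int64)
    stack_depth = np.empty(maxn, np.int64)
    stack_slot[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n_total
    stack_depth[0] = 0
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        slot = stack_slot[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        depth = stack_depth[top]
        n = hi - lo
        sw = 0.0
        swy = 0.0
        swyy = 0.0
        for j in range(lo, hi):
            k = idx[j]
            sw += w[k]
            swy += w[k] * y[k]
            swyy += w[k] * y[k] * y[k]
        mean = swy / sw
        sq = swyy - swy * swy / sw
        if sq < 0.0:
            sq = 0.0
        nws[slot] = sw
        sqs[slot] = sq
        values[slot] = mean
        features[slot] = -1
        lefts[slot] = -1
        rights[slot] = -1
        if n < min_node or depth >= h_max or sq <= swyy * 1e-13:
            continue
        best_gain = -1.0
        best_var = -1
        best_cut = 0.0
        if method == METHOD_VR:
            if vr_alpha >= 1.0:
                det = True
            else:
                det = np.random.random() < vr_alpha
        else:
            det = method != METHOD_EXTRA
        if method == METHOD_RF or (method == METHOD_VR and det):
            k_cand = n_test if n_test < M else M
            _sample_distinct(perm, M, k_cand)
            for t in range(k_cand):
                cand[t] = perm[t]
            best_gain, best_var, best_cut = _det_scan(
                X, y, w, idx, lo, hi, cand, k_cand, sw, swy, swyy, sq, literal, xs, ys, ws
            )
            if best_gain <= 0.0:
                continue
        elif method == METHOD_RF_PAIRED:
            n_orig = M // 2
            k2 = n_test // 2
            if k2 > n_orig:
                k2 = n_orig
            _sample_distinct(perm, n_orig, k2)
            for t in range(k2):
                cand[t] = perm[t]
                cand[k2 + t] = perm[t] + n_orig
            best_gain, best_var, best_cut = _det_scan(
                X, y, w, idx, lo, hi, cand, 2 * k2, sw, swy, swyy, sq, literal, xs, ys, ws
            )
            if best_gain <= 0.0:
                continue
        elif method == METHOD_EXTRA:
            k_cand = n_test if n_test < M else M
            _sample_distinct(perm, M, k_cand)
            n_tied = 1
            for ci in range(k_cand):
                v = perm[ci]
                xlo = X[idx[lo], v]
                xhi = xlo
                for j in range(lo + 1, hi):
                    xval = X[idx[j], v]
                    if xval < xlo:
                        xlo = xval
                    elif xval > xhi:
                        xhi = xval
                if xhi <= xlo:
                    continue
                cut = xlo + np.random.random() * (xhi - xlo)
                if cut >= xhi:
                    cut = 0.5 * (xlo + xhi)
                gain = _cut_gain(X, y, w, idx, lo, hi, v, cut, sw, swy, swyy, sq, literal)
                if gain > best_gain:
                    best_gain = gain
                    best_var = v
                    best_cut = cut
                    n_tied = 1
                elif gain == best_gain and best_var >= 0:
                    n_tied += 1
                    if np.random.random() * n_tied < 1.0:
                        best_var = v
                        best_cut = cut
            if best_var < 0:
                continue
        else:  # VR random branch: a uniformly random (variable, cut) pair
            found = False
            for _ in range(M):
                v = np.random.randint(0, M)
                xlo = X[idx[lo], v]
                xhi = xlo
                for j in range(lo + 1, hi):
                    xval = X[idx[j], v]
                    if xval < xlo:
                        xlo = xval
                    elif xval > xhi:
                        xhi = xval
                if xhi <= xlo:
                    continue
                cut = xlo + np.random.random() * (xhi - xlo)
                if cut >= xhi:
                    cut = 0.5 * (xlo + xhi)
                gain = _cut_gain(X, y, w, idx, lo, hi, v, cut, sw, swy, swyy, sq, literal)
                if gain >= 0.0:
                    best_gain = gain
                    best_var = v
                    best_cut = cut
                    found = True
                break
            if not found:
                continue
        # stable in-place partition of idx[lo:hi]
        nl = 0
        for j in range(lo, hi):
            if X[idx[j], best_var] <= best_cut:
                tmp[nl] = idx[j]
                nl += 1
        if nl == 0 or nl == n:
            continue  # numerically degenerate cut; keep as leaf
        nr = nl
        for j in range(lo, hi):
            if X[idx[j], best_var] > best_cut:
                tmp[nr] = idx[j]
                nr += 1
        for j in range(n):
            idx[lo + j] = tmp[j]
        left_slot = n_nodes
        right_slot = n_nodes + 1
        n_nodes += 2
        features[slot] = best_var
        thresholds[slot] = best_cut
        lefts[slot] = left_slot
        rights[slot] = right_slot
        imp_row[best_var] += best_gain
        stack_slot[top] = right_slot
        stack_lo[top] = lo + nl
        stack_hi[top] = hi
        stack_depth[top] = depth + 1
        top += 1
        stack_slot[top] = left_slot
        stack_lo[top] = lo
        stack_hi[top] = lo + nl
        stack_depth[top] = depth + 1
        top += 1
    return n_nodes


@njit(cache=True)
def build_forest(
    X,
    y,
    w,
    n_tree,
    seeds,
    method,
    n_test,
    h_max,
    min_node,
    vr_alpha,
    literal,
    bootstrap,
):
    """Grow ``n_tree`` trees; returns the packed node arrays plus bookkeeping.

    Per-measurement weights enter the split criterion, node statistics and
    importance only; bootstrap sampling is uniform with replacement over rows
    (weights travel with the drawn rows).
    """
    n, M = X.shape
    maxn = 2 * n + 1
    features = np.full((n_tree, maxn), -1, np.int64)
    thresholds = np.zeros((n_tree, maxn))
    lefts = np.full((n_tree, maxn), -1, np.int64)
    rights = np.full((n_tree, maxn), -1, np.int64)
    values = np.zeros((n_tree, maxn))
    nws = np.zeros((n_tree, maxn))
    sqs = np.zeros((n_tree, maxn))
    n_nodes = np.zeros(n_tree, np.int64)
    imp = np.zeros((n_tree, M))
    inbag = np.zeros((n_tree, n), np.int64)
    # shared workspaces, reused across trees
    idx = np.empty(n, np.int64)
    tmp = np.empty(n, np.int64)
    xs = np.empty(n)
    ys = np.empty(n)
    ws_buf = np.empty(n)
    perm = np.empty(M, np.int64)
    cand = np.empty(M, np.int64)
    for i in range(n_tree):
        np.random.seed(seeds[i])
        if bootstrap:
            bidx = np.random.randint(0, n, n)
        else:
            bidx = np.arange(n)
        for j in range(n):
            inbag[i, bidx[j]] += 1
        n_nodes[i] = _build_tree(
            X,
            y,
            w,
            bidx,
            method,
            n_test,
            h_max,
            min_node,
            vr_alpha,
            literal,
            features[i],
            thresholds[i],
            lefts[i],
            rights[i],
            values[i],
            nws[i],
            sqs[i],
            imp[i],
            idx,
            tmp,
            xs,
            ys,
            ws_buf,
            perm,
            cand,
        )
    return features, thresholds, lefts, rights, values, nws, sqs, n_nodes, imp, inbag


@njit(cache=True)
def forest_predict(features, thresholds, lefts, rights, values, X):
    """Plain ensemble prediction: mean over all trees of the leaf means."""
    n_tree = features.shape[0]
    nq = X.shape[0]
    out = np.zeros(nq)
    for i in range(n_tree):
        for q in range(nq):
            node = 0
            while features[i, node] >= 0:
                if X[q, features[i, node]] <= thresholds[i, node]:
                    node = lefts[i, node]
                else:
                    node = rights[i, node]
            out[q] += values[i, node]
    return out / n_tree


@njit(cache=True)
def forest_oob_predict(features, thresholds, lefts, rights, values, inbag, X):
    """Out-of-bag prediction over the training matrix.

    Rows that are in-bag for every tree fall back to the all-tree mean and
    are flagged in the returned boolean array.
    """
    n_tree = features.shape[0]
    nq = X.shape[0]
    out = np.zeros(nq)
    cnt = np.zeros(nq, np.int64)
    allmean = np.zeros(nq)
    for i in range(n_tree):
        for q in range(nq):
            node = 0
            while features[i, node] >= 0:
                if X[q, features[i, node]] <= thresholds[i, node]:
                    node = lefts[i, node]
                else:
                    node = rights[i, node]
            allmean[q] += values[i, node]
            if inbag[i, q] == 0:
                out[q] += values[i, node]
                cnt[q] += 1
    fallback = np.zeros(nq, np.bool_)
    for q in range(nq):
        if cnt[q] > 0:
            out[q] /= cnt[q]
        else:
            out[q] = allmean[q] / n_tree
            fallback[q] = True
    return out, fallback
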