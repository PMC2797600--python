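"""Numba inner loops of the partition sampler.

One chain's state and caches are a tuple of flat arrays (see
``sampler.ChainState``).  Per non-null module the cache holds sufficient
statistics from which the collapsed (tempered) expression block and the
Dirichlet-multinomial marker block are evaluated in O(K^3) / O(K C):

- ``Gd, sumy, sumy2, sumsq``: gene count and per-gene row sum aggregates;
- ``colsum[d, i]``: per-individual column sum over the module's genes;
- ``rsum, rsumsq, rc``: aggregates of the sampled individual effects
  (``rc = sum_i colsum[d, i] r[d, i]``);
- ``vcol[d, k], rtyp[d, k], n_k[d, k]``: per-type totals;
- ``combo[d, i], ccounts[d, k, c], Cmod, Mcnt, slT``: genotype-combination
  codes and count tables over the module's markers;
- ``tb[d], mb[d]``: cached tempered expression / marker block values;
- ``nulls``: summed null-gene and null-marker marginals.

All kernels leave the tempered target invariant; the inverse temperature
``beta`` multiplies collapsed likelihood and indicator-prior terms, while
the gene/type-effect integrals use the exact tempered form (see
``marginals.expression_block_tempered``) so that the augmented draws of
the continuous parameters remain exactly conjugate at every temperature.
"""

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)


# ----------------------------------------------------------------- basics


@njit(cache=True)
def _lgamma(x):
    return math.lgamma(x)


@njit(cache=True)
def _tb_eval(G, K, n_k, u_sum, u_sq, zz, v, s2, s2g, s2t, beta):
    """Tempered collapsed expression block from sufficient statistics.

    Slots with n_k == 0 are skipped (an unoccupied type has no effect)."""
    if G == 0:
        return 0.0
    kocc = 0
    for k in range(K):
        if n_k[k] > 0:
            kocc += 1
    nk = np.empty(kocc)
    vv = np.empty(kocc)
    j = 0
    for k in range(K):
        if n_k[k] > 0:
            nk[j] = n_k[k]
            vv[j] = v[k]
            j += 1
    N = 0.0
    for k in range(kocc):
        N += nk[k]
    n = G * N
    d = G + kocc
    s_a = s2 / s2g
    s_t = s2 / s2t
    a = N + s_a
    S = np.empty((kocc, kocc))
    for i in range(kocc):
        for j2 in range(kocc):
            S[i, j2] = -(G / a) * nk[i] * nk[j2]
        S[i, i] += G * nk[i] + s_t
    w = np.empty(kocc)
    for k in range(kocc):
        w[k] = vv[k] - (u_sum / a) * nk[k]
    L = np.linalg.cholesky(S)
    logdetS = 0.0
    for k in range(kocc):
        logdetS += 2.0 * math.log(L[k, k])
    # solve S x = w via forward/back substitution
    y = np.empty(kocc)
    for i in range(kocc):
        acc = w[i]
        for j2 in range(i):
            acc -= L[i, j2] * y[j2]
        y[i] = acc / L[i, i]
    x = np.empty(kocc)
    for i in range(kocc - 1, -1, -1):
        acc = y[i]
        for j2 in range(i + 1, kocc):
            acc -= L[j2, i] * x[j2]
        x[i] = acc / L[i, i]
    wSw = 0.0
    for k in range(kocc):
        wSw += w[k] * x[k]
    q = u_sq / a + wSw
    logdetP = G * math.log(a) + logdetS
    return (
        -0.5
        * beta
        * (
            (n + d) * LOG2PI
            + n * math.log(s2)
            + G * math.log(s2g)
            + kocc * math.log(s2t)
            + (zz - q) / s2
        )
        + 0.5 * d * (LOG2PI + math.log(s2))
        - 0.5 * d * math.log(beta)
        - 0.5 * logdetP
    )


@njit(cache=True)
def _dm_table(ccounts_d, K, C, gamma):
    """Dirichlet-multinomial log marginal summed over types."""
    tot = 0.0
    for k in range(K):
        n = 0
        s = 0.0
        for c in range(C):
            cnt = ccounts_d[k, c]
            n += cnt
            s += _lgamma(gamma + cnt)
        tot += _lgamma(C * gamma) - _lgamma(C * gamma + n) + s - C * _lgamma(gamma)
    return tot


@njit(cache=True)
def _alloc_ll(n_arr, slots, delta):
    """Collapsed Dirichlet-multinomial marginal of the type allocation
    (mixture weights over occupied types integrated out)."""
    K = 0
    N = 0.0
    s = 0.0
    for k in range(slots):
        if n_arr[k] > 0:
            K += 1
            N += n_arr[k]
            s += _lgamma(delta + n_arr[k])
    if K == 0:
        return 0.0
    return _lgamma(K * delta) - _lgamma(K * delta + N) + s - K * _lgamma(delta)


@njit(cache=True)
def _gamma_sample(rng, shape):
    """Marsaglia-Tsang gamma(shape, 1) via the chain's Generator."""
    boost = 1.0
    if shape < 1.0:
        boost = rng.random() ** (1.0 / shape)
        shape += 1.0
    d = shape - 1.0 / 3.0
    c = 1.0 / math.sqrt(9.0 * d)
    while True:
        x = rng.standard_normal()
        t = 1.0 + c * x
        if t <= 0.0:
            continue
        v = t * t * t
        u = rng.random()
        if math.log(u) < 0.5 * x * x + d - d * v + d * math.log(v):
            return boost * d * v


@njit(cache=True)
def _categorical(rng, logw):
    """Sample an index from unnormalized log weights."""
    m = logw[0]
    for i in range(1, logw.shape[0]):
        if logw[i] > m:
            m = logw[i]
    tot = 0.0
    for i in range(logw.shape[0]):
        tot += math.exp(logw[i] - m)
    u = rng.random() * tot
    acc = 0.0
    for i in range(logw.shape[0]):
        acc += math.exp(logw[i] - m)
        if u <= acc:
            return i
    return logw.shape[0] - 1


# --------------------------------------------------------- cache (re)build


@njit(cache=True)
def _u_stats(sumy_d, sumy2_d, Gd_d, rsum_d):
    us = sumy_d - Gd_d * rsum_d
    uq = sumy2_d - 2.0 * rsum_d * sumy_d + Gd_d * rsum_d * rsum_d
    return us, uq


@njit(cache=True)
def _tb_module(idx, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc, vcol, rtyp, n_k, K, var, beta):
    G = Gd[idx]
    if G == 0:
        return 0.0
    us, uq = _u_stats(sumy[idx], sumy2[idx], G, rsum[idx])
    zz = sumsq[idx] - 2.0 * rc[idx] + G * rsumsq[idx]
    kk = K[idx]
    v = np.empty(kk)
    for k in range(kk):
        v[k] = vcol[idx, k] - G * rtyp[idx, k]
    return _tb_eval(
        G, kk, n_k[idx, :kk], us, uq, zz, v,
        var[idx, 0], var[idx, 1], var[idx, 2], beta,
    )


@njit(cache=True)
def _rebuild_marker_side(idx, marker_ind, X, T, logT, types_row, Kd, combo_row, cc_mat, gamma):
    """Rebuild combo codes and count table for module idx (0-based).
    Returns (C, Mcnt, slT, mb)."""
    M, N = X.shape
    C = 1
    mcnt = 0
    slt = 0.0
    for i in range(N):
        combo_row[i] = 0
    for m in range(M):
        if marker_ind[m] == idx + 1:
            mcnt += 1
            slt += logT[m]
            t = T[m]
            C *= t
            for i in range(N):
                combo_row[i] = combo_row[i] * t + X[m, i]
    cc_mat[:, :] = 0
    for i in range(N):
        cc_mat[types_row[i] - 1, combo_row[i]] += 1
    mb = _dm_table(cc_mat, Kd, C, gamma) if mcnt > 0 else 0.0
    return C, mcnt, slt, mb


@njit(cache=True)
def _rebuild_all(
    Y, rowsum, rowsumsq, X, T, logT, nullg, nullm,
    gene_ind, marker_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb, nulls,
    gamma, beta,
):
    D = types.shape[0]
    G, N = Y.shape
    M = X.shape[0]
    colsum[:, :] = 0.0
    Gd[:] = 0
    sumy[:] = 0.0
    sumy2[:] = 0.0
    sumsq[:] = 0.0
    vcol[:, :] = 0.0
    rtyp[:, :] = 0.0
    n_k[:, :] = 0
    nulls[0] = 0.0
    nulls[1] = 0.0
    for g in range(G):
        d = gene_ind[g]
        if d == 0:
            nulls[0] += nullg[g]
        else:
            idx = d - 1
            Gd[idx] += 1
            sumy[idx] += rowsum[g]
            sumy2[idx] += rowsum[g] * rowsum[g]
            sumsq[idx] += rowsumsq[g]
            for i in range(N):
                colsum[idx, i] += Y[g, i]
    for m in range(M):
        if marker_ind[m] == 0:
            nulls[1] += nullm[m]
    for idx in range(D):
        rs = 0.0
        rss = 0.0
        rcv = 0.0
        for i in range(N):
            ri = r[idx, i]
            rs += ri
            rss += ri * ri
            rcv += colsum[idx, i] * ri
            k = types[idx, i] - 1
            n_k[idx, k] += 1
            vcol[idx, k] += colsum[idx, i]
            rtyp[idx, k] += ri
        rsum[idx] = rs
        rsumsq[idx] = rss
        rc[idx] = rcv
        C, mc, slt, mbv = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types[idx], K[idx], combo[idx], ccounts[idx], gamma
        )
        Cmod[idx] = C
        Mcnt[idx] = mc
        slT[idx] = slt
        mb[idx] = mbv
        tb[idx] = _tb_module(idx, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                             vcol, rtyp, n_k, K, var, beta)


# ------------------------------------------------------------- log target


@njit(cache=True)
def _chain_logpost(
    gene_ind, marker_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb, nulls,
    gamma, delta, a0, b0, ar, br, lamK, lamM, lamG, beta,
):
    """Tempered log target of the current state (recomputes the expression
    blocks at the requested beta; beta = 1 is the exact log posterior)."""
    D, N = types.shape
    total = beta * (nulls[0] + nulls[1])
    for idx in range(D):
        total += _tb_module(idx, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                            vcol, rtyp, n_k, K, var, beta)
        total += beta * mb[idx]
        total += beta * _alloc_ll(n_k[idx], n_k.shape[1], delta)
        total -= beta * (lamK * (K[idx] - 1.0) + lamM * K[idx] * slT[idx] + lamG * Gd[idx])
        for j in range(4):
            x = var[idx, j]
            aa = a0 if j < 3 else ar
            bb = b0 if j < 3 else br
            total += aa * math.log(bb) - _lgamma(aa) - (aa + 1.0) * math.log(x) - bb / x
        s2r = var[idx, 3]
        total += -0.5 * N * (LOG2PI + math.log(s2r)) - 0.5 * rsumsq[idx] / s2r
    return total


# ------------------------------------------------------------- gene sweep


@njit(cache=True)
def _gene_candidate_tb(
    g, idx, Y, rowsum, rowsumsq, r, types, K,
    Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc, vcol, rtyp, n_k, var, beta,
):
    """Tempered block value of module idx with gene g added."""
    N = Y.shape[1]
    kk = K[idx]
    ts = np.zeros(kk)
    ygr = 0.0
    for i in range(N):
        yi = Y[g, i]
        ts[types[idx, i] - 1] += yi
        ygr += yi * r[idx, i]
    G2 = Gd[idx] + 1
    sy = sumy[idx] + rowsum[g]
    sy2 = sumy2[idx] + rowsum[g] * rowsum[g]
    us = sy - G2 * rsum[idx]
    uq = sy2 - 2.0 * rsum[idx] * sy + G2 * rsum[idx] * rsum[idx]
    zz = (sumsq[idx] + rowsumsq[g]) - 2.0 * (rc[idx] + ygr) + G2 * rsumsq[idx]
    v = np.empty(kk)
    for k in range(kk):
        v[k] = (vcol[idx, k] + ts[k]) - G2 * rtyp[idx, k]
    return _tb_eval(G2, kk, n_k[idx, :kk], us, uq, zz, v,
                    var[idx, 0], var[idx, 1], var[idx, 2], beta)


@njit(cache=True)
def _remove_gene(g, idx, Y, rowsum, rowsumsq, r, types,
                 colsum, Gd, sumy, sumy2, sumsq, rc, vcol):
    N = Y.shape[1]
    Gd[idx] -= 1
    sumy[idx] -= rowsum[g]
    sumy2[idx] -= rowsum[g] * rowsum[g]
    sumsq[idx] -= rowsumsq[g]
    acc = 0.0
    for i in range(N):
        yi = Y[g, i]
        colsum[idx, i] -= yi
        acc += yi * r[idx, i]
        vcol[idx, types[idx, i] - 1] -= yi
    rc[idx] -= acc


@njit(cache=True)
def _add_gene(g, idx, Y, rowsum, rowsumsq, r, types,
              colsum, Gd, sumy, sumy2, sumsq, rc, vcol):
    N = Y.shape[1]
    Gd[idx] += 1
    sumy[idx] += rowsum[g]
    sumy2[idx] += rowsum[g] * rowsum[g]
    sumsq[idx] += rowsumsq[g]
    acc = 0.0
    for i in range(N):
        yi = Y[g, i]
        colsum[idx, i] += yi
        acc += yi * r[idx, i]
        vcol[idx, types[idx, i] - 1] += yi
    rc[idx] += acc


@njit(cache=True)
def _gene_sweep(
    rng, Y, rowsum, rowsumsq, nullg,
    gene_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, tb, nulls,
    lamG, beta,
):
    G, N = Y.shape
    D = types.shape[0]
    logw = np.empty(D + 1)
    for g in range(G):
        d0 = gene_ind[g]
        if d0 > 0:
            idx0 = d0 - 1
            _remove_gene(g, idx0, Y, rowsum, rowsumsq, r, types,
                         colsum, Gd, sumy, sumy2, sumsq, rc, vcol)
            tb[idx0] = _tb_module(idx0, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                                  vcol, rtyp, n_k, K, var, beta)
        else:
            nulls[0] -= nullg[g]
        logw[0] = beta * nullg[g]
        cand_tb = np.empty(D)
        for idx in range(D):
            cand_tb[idx] = _gene_candidate_tb(
                g, idx, Y, rowsum, rowsumsq, r, types, K,
                Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc, vcol, rtyp, n_k, var, beta,
            )
            logw[idx + 1] = cand_tb[idx] - tb[idx] - beta * lamG
        c = _categorical(rng, logw)
        gene_ind[g] = c
        if c == 0:
            nulls[0] += nullg[g]
        else:
            idx = c - 1
            _add_gene(g, idx, Y, rowsum, rowsumsq, r, types,
                      colsum, Gd, sumy, sumy2, sumsq, rc, vcol)
            tb[idx] = cand_tb[idx]


# ----------------------------------------------------------- marker sweep


@njit(cache=True)
def _marker_move_delta(m, d0, d1, marker_ind, X, T, logT, nullm, types, K, slT,
                       ccounts, combo, Cmod, Mcnt, mb, gamma, lamM, N, maxC,
                       combo_s, cc_s, combo_s2, cc_s2):
    """Delta of the tempered marker-side target for moving marker m from d0
    to d1, with proposed caches in the scratch arrays.  Caller toggles
    marker_ind."""
    delta = 0.0
    C_a = Mc_a = 0
    sl_a = mb_a = 0.0
    C_b = Mc_b = 0
    sl_b = mb_b = 0.0
    if d0 > 0:
        C_a, Mc_a, sl_a, mb_a = _rebuild_marker_side(
            d0 - 1, marker_ind, X, T, logT, types[d0 - 1], K[d0 - 1], combo_s, cc_s, gamma
        )
        delta += mb_a - mb[d0 - 1]
        delta += lamM * K[d0 - 1] * logT[m]
    else:
        delta -= nullm[m]
    if d1 > 0:
        C_b, Mc_b, sl_b, mb_b = _rebuild_marker_side(
            d1 - 1, marker_ind, X, T, logT, types[d1 - 1], K[d1 - 1], combo_s2, cc_s2, gamma
        )
        delta += mb_b - mb[d1 - 1]
        delta -= lamM * K[d1 - 1] * logT[m]
    else:
        delta += nullm[m]
    return delta, C_a, Mc_a, sl_a, mb_a, C_b, Mc_b, sl_b, mb_b


@njit(cache=True)
def _marker_excl_ok(m, idx, marker_ind, excl, skip):
    M = marker_ind.shape[0]
    for m2 in range(M):
        if m2 != skip and marker_ind[m2] == idx + 1 and excl[m, m2]:
            return False
    return True


@njit(cache=True)
def _commit_marker(d, C, Mc, sl, mbv, combo_s, cc_s, combo, Cmod, Mcnt, slT, mb, ccounts):
    idx = d - 1
    Cmod[idx] = C
    Mcnt[idx] = Mc
    slT[idx] = sl
    mb[idx] = mbv
    combo[idx, :] = combo_s
    ccounts[idx, :, :] = cc_s


@njit(cache=True)
def _marker_sweep(
    rng, X, T, logT, nullm, excl,
    marker_ind, types, K, slT,
    combo, Cmod, Mcnt, ccounts, mb, nulls,
    gamma, lamM, maxMarkers, beta,
):
    M, N = X.shape
    D = types.shape[0]
    maxC = ccounts.shape[2]
    maxK = ccounts.shape[1]
    combo_s = np.zeros(N, dtype=np.int64)
    cc_s = np.zeros((maxK, maxC), dtype=np.int64)
    combo_s2 = np.zeros(N, dtype=np.int64)
    cc_s2 = np.zeros((maxK, maxC), dtype=np.int64)
    for m in range(M):
        d0 = marker_ind[m]
        j = int(rng.random() * D)
        if j >= D:
            j = D - 1
        d1 = j if j < d0 else j + 1
        if d1 > 0:
            if Mcnt[d1 - 1] >= maxMarkers:
                continue
            if not _marker_excl_ok(m, d1 - 1, marker_ind, excl, m):
                continue
        marker_ind[m] = d1
        delta, C_a, Mc_a, sl_a, mb_a, C_b, Mc_b, sl_b, mb_b = _marker_move_delta(
            m, d0, d1, marker_ind, X, T, logT, nullm, types, K, slT,
            ccounts, combo, Cmod, Mcnt, mb, gamma, lamM, N, maxC,
            combo_s, cc_s, combo_s2, cc_s2,
        )
        if math.log(rng.random()) < beta * delta:
            if d0 > 0:
                _commit_marker(d0, C_a, Mc_a, sl_a, mb_a, combo_s, cc_s,
                               combo, Cmod, Mcnt, slT, mb, ccounts)
            else:
                nulls[1] -= nullm[m]
            if d1 > 0:
                _commit_marker(d1, C_b, Mc_b, sl_b, mb_b, combo_s2, cc_s2,
                               combo, Cmod, Mcnt, slT, mb, ccounts)
            else:
                nulls[1] += nullm[m]
        else:
            marker_ind[m] = d0
    # one swap proposal per module: exchange an in-module and a null marker
    for idx in range(D):
        if Mcnt[idx] == 0:
            continue
        n_null = 0
        for m in range(M):
            if marker_ind[m] == 0:
                n_null += 1
        if n_null == 0:
            continue
        j1 = int(rng.random() * Mcnt[idx])
        j2 = int(rng.random() * n_null)
        m1 = -1
        m2 = -1
        c1 = 0
        c2 = 0
        for m in range(M):
            if marker_ind[m] == idx + 1:
                if c1 == j1:
                    m1 = m
                c1 += 1
            elif marker_ind[m] == 0:
                if c2 == j2:
                    m2 = m
                c2 += 1
        if not _marker_excl_ok(m2, idx, marker_ind, excl, m1):
            continue
        marker_ind[m1] = 0
        marker_ind[m2] = idx + 1
        C_b, Mc_b, sl_b, mb_b = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types[idx], K[idx], combo_s, cc_s, gamma
        )
        delta = (mb_b - mb[idx]) + nullm[m1] - nullm[m2] \
            + lamM * K[idx] * (logT[m1] - logT[m2])
        if math.log(rng.random()) < beta * delta:
            _commit_marker(idx + 1, C_b, Mc_b, sl_b, mb_b, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            nulls[1] += nullm[m1] - nullm[m2]
        else:
            marker_ind[m1] = idx + 1
            marker_ind[m2] = 0


# ------------------------------------------------------- individual sweep


@njit(cache=True)
def _indiv_sweep(
    rng, idx, Y,
    types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb,
    gamma, delta, lamK, lamM, beta, maxK,
):
    N = Y.shape[1]
    G = Gd[idx]
    us, uq = _u_stats(sumy[idx], sumy2[idx], G, rsum[idx])
    zz = sumsq[idx] - 2.0 * rc[idx] + G * rsumsq[idx]
    C = Cmod[idx]
    has_mk = Mcnt[idx] > 0
    for i in range(N):
        kk = K[idx]
        k0 = types[idx, i] - 1
        csi = colsum[idx, i]
        ri = r[idx, i]
        cb = combo[idx, i]
        n_k[idx, k0] -= 1
        vcol[idx, k0] -= csi
        rtyp[idx, k0] -= ri
        if has_mk:
            ccounts[idx, k0, cb] -= 1
        emptied = n_k[idx, k0] == 0
        base_occ = kk - 1 if emptied else kk
        # full conditional over set partitions: join an existing type or
        # open a fresh singleton type (unless i's own type just emptied,
        # in which case re-occupying it already is the singleton option)
        fresh = 1 if (not emptied and kk < maxK) else 0
        ncand = kk + fresh
        logw = np.empty(ncand)
        v2 = np.empty(ncand)
        n2 = np.empty(ncand)
        for k in range(ncand):
            for k2 in range(kk):
                n2[k2] = n_k[idx, k2]
                v2[k2] = vcol[idx, k2] - G * rtyp[idx, k2]
            if fresh == 1:
                n2[kk] = 0.0
                v2[kk] = 0.0
            n2[k] += 1
            v2[k] += csi - G * ri
            tbv = _tb_eval(G, ncand, n2, us, uq, zz, v2,
                           var[idx, 0], var[idx, 1], var[idx, 2], beta)
            if k < kk:
                occ = base_occ + 1 if (n_k[idx, k] == 0) else base_occ
                pred = 0.0
                if has_mk:
                    pred = math.log(gamma + ccounts[idx, k, cb]) - math.log(C * gamma + n_k[idx, k])
            else:
                occ = base_occ + 1
                pred = -math.log(1.0 * C) if has_mk else 0.0
            prior = -(lamK * (occ - 1.0) + lamM * occ * slT[idx])
            alloc = _alloc_ll(n2, ncand, delta)
            logw[k] = tbv + beta * (pred + prior + alloc)
        ks = _categorical(rng, logw)
        if ks == kk:
            K[idx] = kk + 1
            n_k[idx, kk] = 0
            vcol[idx, kk] = 0.0
            rtyp[idx, kk] = 0.0
            ccounts[idx, kk, :] = 0
        types[idx, i] = ks + 1
        n_k[idx, ks] += 1
        vcol[idx, ks] += csi
        rtyp[idx, ks] += ri
        if has_mk:
            ccounts[idx, ks, cb] += 1
        if emptied and ks != k0:
            # compact: move last label into the empty slot
            last = kk - 1
            if k0 != last:
                for i2 in range(N):
                    if types[idx, i2] == last + 1:
                        types[idx, i2] = k0 + 1
                n_k[idx, k0] = n_k[idx, last]
                vcol[idx, k0] = vcol[idx, last]
                rtyp[idx, k0] = rtyp[idx, last]
                ccounts[idx, k0, :] = ccounts[idx, last, :]
            n_k[idx, last] = 0
            vcol[idx, last] = 0.0
            rtyp[idx, last] = 0.0
            ccounts[idx, last, :] = 0
            K[idx] = kk - 1
    tb[idx] = _tb_module(idx, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                         vcol, rtyp, n_k, K, var, beta)
    if has_mk:
        mb[idx] = _dm_table(ccounts[idx], K[idx], C, gamma)


# ----------------------------------------------------------- split / merge


SPLIT_MARKER_FRAC = 0.4  # split proposals guided by a random marker's genotype
SPLIT_EXPR_FRAC = 0.3  # split proposals cutting the type along module expression


@njit(cache=True)
def _sorted_members(types_row, k, key):
    """Members of type k sorted by (key, index); deterministic."""
    N = types_row.shape[0]
    n = 0
    for i in range(N):
        if types_row[i] == k + 1:
            n += 1
    idxs = np.empty(n, dtype=np.int64)
    j = 0
    for i in range(N):
        if types_row[i] == k + 1:
            idxs[j] = i
            j += 1
    for a in range(1, n):
        v = idxs[a]
        b = a - 1
        while b >= 0 and (key[idxs[b]] > key[v] or (key[idxs[b]] == key[v] and idxs[b] > v)):
            idxs[b + 1] = idxs[b]
            b -= 1
        idxs[b + 1] = v
    return idxs


@njit(cache=True)
def _expr_cut_density(types_row, k, move, key):
    """1/(n-1) if the moved side is a contiguous prefix/suffix of the
    type's members in expression order, else 0."""
    idxs = _sorted_members(types_row, k, key)
    n = idxs.shape[0]
    if n < 2:
        return 0.0
    changes = 0
    for a in range(1, n):
        if (move[idxs[a]] == 1) != (move[idxs[a - 1]] == 1):
            changes += 1
    if changes == 1:
        return 1.0 / (n - 1.0)
    return 0.0


@njit(cache=True)
def _split_density_extra(X, T, types_row, k, move, n_k_val):
    """Marker-route proposal density S of an unordered split of type k into
    (moved, stayed): sum over (marker, code) pairs whose genotype pattern
    induces exactly this split, each weighted 1 / (M * T_m)."""
    M, N = X.shape
    S = 0.0
    for m in range(M):
        # does {X[m] == c} over the type's members equal one side?
        c_moved = -1
        c_stayed = -1
        ok_moved = True
        ok_stayed = True
        for i in range(N):
            if types_row[i] != k + 1:
                continue
            xm = X[m, i]
            if move[i] == 1:
                if c_moved == -1:
                    c_moved = xm
                elif xm != c_moved:
                    ok_moved = False
            else:
                if c_stayed == -1:
                    c_stayed = xm
                elif xm != c_stayed:
                    ok_stayed = False
            if not ok_moved and not ok_stayed:
                break
        # (m, c_moved) induces the split iff moved side is {==c_moved}
        if ok_moved and c_moved != -1:
            bad = False
            for i in range(N):
                if types_row[i] == k + 1 and move[i] == 0 and X[m, i] == c_moved:
                    bad = True
                    break
            if not bad:
                S += 1.0 / (M * T[m])
        if ok_stayed and c_stayed != -1:
            bad = False
            for i in range(N):
                if types_row[i] == k + 1 and move[i] == 1 and X[m, i] == c_stayed:
                    bad = True
                    break
            if not bad:
                S += 1.0 / (M * T[m])
    return S


@njit(cache=True)
def _split_merge(
    rng, idx, Y, X, T,
    types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb,
    gamma, delta, lamK, lamM, beta, maxK,
):
    """One split or merge proposal (prob 1/2 each) on module idx's types.

    Split allocations are drawn either uniformly at random or along a
    random marker's genotype (``SPLIT_MARKER_FRAC``); the acceptance ratio
    uses the exact mixture proposal density, so the move is reversible."""
    N = Y.shape[1]
    M = X.shape[0]
    rho_m = SPLIT_MARKER_FRAC
    rho_e = SPLIT_EXPR_FRAC
    rho_r = 1.0 - rho_m - rho_e
    G = Gd[idx]
    kk = K[idx]
    C = Cmod[idx]
    has_mk = Mcnt[idx] > 0
    us, uq = _u_stats(sumy[idx], sumy2[idx], G, rsum[idx])
    zz = sumsq[idx] - 2.0 * rc[idx] + G * rsumsq[idx]
    key = np.empty(N)
    for i in range(N):
        key[i] = colsum[idx, i] - G * r[idx, i]
    do_split = rng.random() < 0.5
    if do_split:
        if kk >= maxK:
            return 0
        k = int(rng.random() * kk)
        if k >= kk:
            k = kk - 1
        nk_old = n_k[idx, k]
        move = np.zeros(N, dtype=np.int64)
        n_new = 0
        route = rng.random()
        if route < rho_m:
            m = int(rng.random() * M)
            if m >= M:
                m = M - 1
            c = int(rng.random() * T[m])
            for i in range(N):
                if types[idx, i] == k + 1 and X[m, i] == c:
                    move[i] = 1
                    n_new += 1
        elif route < rho_m + rho_e:
            if nk_old < 2:
                return 0
            idxs = _sorted_members(types[idx], k, key)
            cut = 1 + int(rng.random() * (nk_old - 1))
            if cut > nk_old - 1:
                cut = nk_old - 1
            for a in range(cut, nk_old):
                move[idxs[a]] = 1
                n_new += 1
        else:
            for i in range(N):
                if types[idx, i] == k + 1 and rng.random() < 0.5:
                    move[i] = 1
                    n_new += 1
        if n_new == 0 or n_new == nk_old:
            return 0
        k2v = np.zeros(kk + 1)
        k2n = np.zeros(kk + 1)
        cs_new = 0.0
        rt_new = 0.0
        for k3 in range(kk):
            k2n[k3] = n_k[idx, k3]
            k2v[k3] = vcol[idx, k3] - G * rtyp[idx, k3]
        cc2 = np.zeros((kk + 1, ccounts.shape[2]), dtype=np.int64)
        cc2[:kk, :] = ccounts[idx, :kk, :]
        for i in range(N):
            if move[i] == 1:
                cs_new += colsum[idx, i]
                rt_new += r[idx, i]
                if has_mk:
                    cc2[k, combo[idx, i]] -= 1
                    cc2[kk, combo[idx, i]] += 1
        k2n[k] -= n_new
        k2n[kk] = n_new
        k2v[k] -= cs_new - G * rt_new
        k2v[kk] = cs_new - G * rt_new
        tb2 = _tb_eval(G, kk + 1, k2n, us, uq, zz, k2v,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        mb2 = _dm_table(cc2, kk + 1, C, gamma) if has_mk else 0.0
        S_m = _split_density_extra(X, T, types[idx], k, move, nk_old)
        S_e = _expr_cut_density(types[idx], k, move, key)
        q_split = rho_r * 2.0 ** (1.0 - nk_old) + rho_m * S_m + rho_e * S_e
        logq = math.log(kk) - math.log(q_split) - math.log((kk + 1.0) * kk / 2.0)
        dalloc = _alloc_ll(k2n, kk + 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dlog = tb2 - tb[idx] + beta * (mb2 - mb[idx] + dalloc) \
            + beta * (-(lamK + lamM * slT[idx])) + logq
        if math.log(rng.random()) < dlog:
            for i in range(N):
                if move[i] == 1:
                    types[idx, i] = kk + 1
            n_k[idx, k] -= n_new
            n_k[idx, kk] = n_new
            vcol[idx, k] -= cs_new
            vcol[idx, kk] = cs_new
            rtyp[idx, k] -= rt_new
            rtyp[idx, kk] = rt_new
            ccounts[idx, : kk + 1, :] = cc2
            K[idx] = kk + 1
            tb[idx] = tb2
            mb[idx] = mb2
            return 1
        return 0
    else:
        if kk <= 1:
            return 0
        a = int(rng.random() * kk)
        b = int(rng.random() * (kk - 1))
        if b >= a:
            b += 1
        k1 = a if a < b else b
        k2 = b if a < b else a
        n_merged = n_k[idx, k1] + n_k[idx, k2]
        k2v = np.zeros(kk - 1)
        k2n = np.zeros(kk - 1)
        cc2 = np.zeros((kk - 1, ccounts.shape[2]), dtype=np.int64)
        # merged layout: slot k1 absorbs k2; last slot (kk-1) moves into k2
        for k3 in range(kk - 1):
            src = k3 if k3 != k2 else kk - 1
            k2n[k3] = n_k[idx, src]
            k2v[k3] = vcol[idx, src] - G * rtyp[idx, src]
            cc2[k3, :] = ccounts[idx, src, :]
        k2n[k1] = n_merged
        k2v[k1] = (vcol[idx, k1] + vcol[idx, k2]) - G * (rtyp[idx, k1] + rtyp[idx, k2])
        cc2[k1, :] = ccounts[idx, k1, :] + ccounts[idx, k2, :]
        tb2 = _tb_eval(G, kk - 1, k2n, us, uq, zz, k2v,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        mb2 = _dm_table(cc2, kk - 1, C, gamma) if has_mk else 0.0
        tmp_types = types[idx].copy()
        move = np.zeros(N, dtype=np.int64)
        for i in range(N):
            if tmp_types[i] == k2 + 1:
                tmp_types[i] = k1 + 1
                move[i] = 1
        S_m = _split_density_extra(X, T, tmp_types, k1, move, n_merged)
        S_e = _expr_cut_density(tmp_types, k1, move, key)
        q_split_rev = rho_r * 2.0 ** (1.0 - n_merged) + rho_m * S_m + rho_e * S_e
        logq = math.log(kk * (kk - 1.0) / 2.0) - math.log(kk - 1.0) \
            + math.log(q_split_rev)
        dalloc = _alloc_ll(k2n, kk - 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dlog = tb2 - tb[idx] + beta * (mb2 - mb[idx] + dalloc) \
            + beta * (lamK + lamM * slT[idx]) + logq
        if math.log(rng.random()) < dlog:
            last = kk - 1
            for i in range(N):
                t = types[idx, i]
                if t == k2 + 1:
                    types[idx, i] = k1 + 1
                elif t == last + 1 and k2 != last:
                    types[idx, i] = k2 + 1
            vc1 = vcol[idx, k1] + vcol[idx, k2]
            rt1 = rtyp[idx, k1] + rtyp[idx, k2]
            cc1 = ccounts[idx, k1, :] + ccounts[idx, k2, :]
            if k2 != last:
                n_k[idx, k2] = n_k[idx, last]
                vcol[idx, k2] = vcol[idx, last]
                rtyp[idx, k2] = rtyp[idx, last]
                ccounts[idx, k2, :] = ccounts[idx, last, :]
            n_k[idx, k1] = n_merged
            vcol[idx, k1] = vc1
            rtyp[idx, k1] = rt1
            ccounts[idx, k1, :] = cc1
            n_k[idx, last] = 0
            vcol[idx, last] = 0.0
            rtyp[idx, last] = 0.0
            ccounts[idx, last, :] = 0
            K[idx] = kk - 1
            tb[idx] = tb2
            mb[idx] = mb2
            return 1
        return 0


# ----------------------------------------------------- marker birth/death


@njit(cache=True)
def _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k):
    N = types.shape[1]
    vcol[idx, :] = 0.0
    rtyp[idx, :] = 0.0
    n_k[idx, :] = 0
    for i in range(N):
        k = types[idx, i] - 1
        n_k[idx, k] += 1
        vcol[idx, k] += colsum[idx, i]
        rtyp[idx, k] += r[idx, i]


@njit(cache=True)
def _weighted_pick(rng, cum):
    u = rng.random() * cum[cum.shape[0] - 1]
    j = np.searchsorted(cum, u)
    if j >= cum.shape[0]:
        j = cum.shape[0] - 1
    return j


@njit(cache=True)
def _marker_birth_death(
    rng, idx, Y, X, T, logT, nullm, excl, mw, mcum,
    marker_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb, nulls,
    gamma, delta, lamK, lamM, maxMarkers, maxK, beta,
):
    """Joint move: add a null marker to module idx while splitting one
    individual type along its genotype (birth), or remove an in-module
    marker while merging a pair of types that differ exactly by one of its
    codes (death).  A type partition and its defining marker only pay off
    jointly, so separate moves rarely cross this barrier."""
    M, N = X.shape
    kk = K[idx]
    G = Gd[idx]
    us, uq = _u_stats(sumy[idx], sumy2[idx], G, rsum[idx])
    zz = sumsq[idx] - 2.0 * rc[idx] + G * rsumsq[idx]
    maxC = ccounts.shape[2]
    maxKs = ccounts.shape[1]
    birth = rng.random() < 0.5
    if birth:
        if kk >= maxK or Mcnt[idx] >= maxMarkers:
            return 0
        m = _weighted_pick(rng, mcum)
        if marker_ind[m] != 0:
            return 0
        if not _marker_excl_ok(m, idx, marker_ind, excl, -1):
            return 0
        c = int(rng.random() * T[m])
        k = int(rng.random() * kk)
        nk_old = n_k[idx, k]
        nA = 0
        for i in range(N):
            if types[idx, i] == k + 1 and X[m, i] == c:
                nA += 1
        if nA == 0 or nA == nk_old:
            return 0
        # codes of m inducing the same unordered split of type k
        cnt = 0
        for c2 in range(T[m]):
            eqA = True
            eqB = True
            for i in range(N):
                if types[idx, i] != k + 1:
                    continue
                inA = X[m, i] == c
                in2 = X[m, i] == c2
                if in2 != inA:
                    eqA = False
                if in2 == inA:
                    eqB = False
                if not eqA and not eqB:
                    break
            if eqA or eqB:
                cnt += 1
        types2 = types[idx].copy()
        for i in range(N):
            if types[idx, i] == k + 1 and X[m, i] == c:
                types2[i] = kk + 1
        # expression side
        n2 = np.zeros(kk + 1)
        v2 = np.zeros(kk + 1)
        for i in range(N):
            k3 = types2[i] - 1
            n2[k3] += 1.0
            v2[k3] += colsum[idx, i] - G * r[idx, i]
        tb2 = _tb_eval(G, kk + 1, n2, us, uq, zz, v2,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        # marker side
        combo_s = np.zeros(N, dtype=np.int64)
        cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
        marker_ind[m] = idx + 1
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types2, kk + 1, combo_s, cc_s, gamma
        )
        dalloc = _alloc_ll(n2, kk + 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dprior = -lamK - lamM * ((kk + 1.0) * sl2 - kk * slT[idx])
        dlog = (tb2 - tb[idx]) + beta * (
            mb2 - mb[idx] - nullm[m] + dalloc + dprior
        )
        logq = (
            -math.log(Mcnt[idx] + 1.0)
            - math.log((kk + 1.0) * kk / 2.0)
            - math.log(mw[m])
            - math.log(1.0 * cnt)
            + math.log(1.0 * T[m])
            + math.log(1.0 * kk)
        )
        if math.log(rng.random()) < dlog + logq:
            types[idx, :] = types2
            K[idx] = kk + 1
            _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k)
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            tb[idx] = tb2
            nulls[1] -= nullm[m]
            return 1
        marker_ind[m] = 0
        return 0
    else:
        if kk <= 1 or Mcnt[idx] == 0:
            return 0
        j = int(rng.random() * Mcnt[idx])
        m = -1
        c1 = 0
        for m2 in range(M):
            if marker_ind[m2] == idx + 1:
                if c1 == j:
                    m = m2
                    break
                c1 += 1
        a = int(rng.random() * kk)
        b = int(rng.random() * (kk - 1))
        if b >= a:
            b += 1
        k1 = a if a < b else b
        k2 = b if a < b else a
        # reachability: a code of m must separate k2's members from k1's
        cnt = 0
        for c2 in range(T[m]):
            eqA = True  # {X==c2} among pair members == k2 members
            eqB = True  # == k1 members
            for i in range(N):
                t = types[idx, i]
                if t != k1 + 1 and t != k2 + 1:
                    continue
                in2 = X[m, i] == c2
                if in2 != (t == k2 + 1):
                    eqA = False
                if in2 != (t == k1 + 1):
                    eqB = False
                if not eqA and not eqB:
                    break
            if eqA or eqB:
                cnt += 1
        if cnt == 0:
            return 0
        n_merged = n_k[idx, k1] + n_k[idx, k2]
        types2 = types[idx].copy()
        last = kk - 1
        for i in range(N):
            t = types2[i]
            if t == k2 + 1:
                types2[i] = k1 + 1
            elif t == last + 1 and k2 != last:
                types2[i] = k2 + 1
        n2 = np.zeros(kk - 1)
        v2 = np.zeros(kk - 1)
        for i in range(N):
            k3 = types2[i] - 1
            n2[k3] += 1.0
            v2[k3] += colsum[idx, i] - G * r[idx, i]
        tb2 = _tb_eval(G, kk - 1, n2, us, uq, zz, v2,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        combo_s = np.zeros(N, dtype=np.int64)
        cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
        marker_ind[m] = 0
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types2, kk - 1, combo_s, cc_s, gamma
        )
        dalloc = _alloc_ll(n2, kk - 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dprior = lamK + lamM * (kk * slT[idx] - (kk - 1.0) * sl2)
        dlog = (tb2 - tb[idx]) + beta * (
            mb2 - mb[idx] + nullm[m] + dalloc + dprior
        )
        logq = (
            math.log(mw[m])
            + math.log(1.0 * cnt)
            - math.log(1.0 * T[m])
            - math.log(kk - 1.0)
            + math.log(1.0 * Mcnt[idx])
            + math.log(kk * (kk - 1.0) / 2.0)
        )
        if math.log(rng.random()) < dlog + logq:
            types[idx, :] = types2
            K[idx] = kk - 1
            _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k)
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            tb[idx] = tb2
            nulls[1] += nullm[m]
            return 1
        marker_ind[m] = idx + 1
        return 0


@njit(cache=True)
def _marker_null_exchange(
    rng, idx, X, T, logT, nullm, excl, mw, mcum,
    marker_ind, types, K,
    combo, Cmod, Mcnt, slT, ccounts, mb, nulls,
    gamma, lamM, maxMarkers, beta,
):
    """Exchange one marker between module idx and the null pool without
    touching the types; insertions are drawn from the association-weighted
    proposal, so captured high-signal markers are also easy to release."""
    M, N = X.shape
    maxC = ccounts.shape[2]
    maxKs = ccounts.shape[1]
    combo_s = np.zeros(N, dtype=np.int64)
    cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
    if rng.random() < 0.5:
        if Mcnt[idx] == 0:
            return 0
        j = int(rng.random() * Mcnt[idx])
        m = -1
        c1 = 0
        for m3 in range(M):
            if marker_ind[m3] == idx + 1:
                if c1 == j:
                    m = m3
                    break
                c1 += 1
        marker_ind[m] = 0
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types[idx], K[idx], combo_s, cc_s, gamma
        )
        dlog = beta * (mb2 - mb[idx] + nullm[m] + lamM * K[idx] * logT[m])
        logq = math.log(mw[m]) + math.log(1.0 * Mcnt[idx])
        if math.log(rng.random()) < dlog + logq:
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            nulls[1] += nullm[m]
            return 1
        marker_ind[m] = idx + 1
        return 0
    else:
        if Mcnt[idx] >= maxMarkers:
            return 0
        m = _weighted_pick(rng, mcum)
        if marker_ind[m] != 0:
            return 0
        if not _marker_excl_ok(m, idx, marker_ind, excl, -1):
            return 0
        marker_ind[m] = idx + 1
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types[idx], K[idx], combo_s, cc_s, gamma
        )
        dlog = beta * (mb2 - mb[idx] - nullm[m] - lamM * K[idx] * logT[m])
        logq = -math.log(Mcnt[idx] + 1.0) - math.log(mw[m])
        if math.log(rng.random()) < dlog + logq:
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            nulls[1] -= nullm[m]
            return 1
        marker_ind[m] = 0
        return 0


@njit(cache=True)
def _marker_swap_split(
    rng, idx, Y, X, T, logT, nullm, excl, mw, mcum,
    marker_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb, nulls,
    gamma, delta, lamK, lamM, maxK, beta,
):
    """Exchange an in-module marker for a null marker while splitting one
    type along the incoming marker (or the reverse: swap back and merge).
    Lets a module escape a chance-correlated squatter marker whose slot
    blocks the entry of the truly associated one."""
    M, N = X.shape
    kk = K[idx]
    G = Gd[idx]
    us, uq = _u_stats(sumy[idx], sumy2[idx], G, rsum[idx])
    zz = sumsq[idx] - 2.0 * rc[idx] + G * rsumsq[idx]
    maxC = ccounts.shape[2]
    maxKs = ccounts.shape[1]
    if Mcnt[idx] == 0:
        return 0
    m_in = _weighted_pick(rng, mcum)
    if marker_ind[m_in] != 0:
        return 0
    j1 = int(rng.random() * Mcnt[idx])
    m_out = -1
    c1 = 0
    for m3 in range(M):
        if marker_ind[m3] == idx + 1:
            if c1 == j1:
                m_out = m3
                break
            c1 += 1
    if not _marker_excl_ok(m_in, idx, marker_ind, excl, m_out):
        return 0
    split_dir = rng.random() < 0.5
    if split_dir:
        # swap + split a type along the incoming marker
        if kk >= maxK:
            return 0
        c = int(rng.random() * T[m_in])
        k = int(rng.random() * kk)
        nk_old = n_k[idx, k]
        nA = 0
        for i in range(N):
            if types[idx, i] == k + 1 and X[m_in, i] == c:
                nA += 1
        if nA == 0 or nA == nk_old:
            return 0
        cnt = 0
        for cc in range(T[m_in]):
            eqA = True
            eqB = True
            for i in range(N):
                if types[idx, i] != k + 1:
                    continue
                inA = X[m_in, i] == c
                in2 = X[m_in, i] == cc
                if in2 != inA:
                    eqA = False
                if in2 == inA:
                    eqB = False
                if not eqA and not eqB:
                    break
            if eqA or eqB:
                cnt += 1
        types2 = types[idx].copy()
        for i in range(N):
            if types[idx, i] == k + 1 and X[m_in, i] == c:
                types2[i] = kk + 1
        n2 = np.zeros(kk + 1)
        v2 = np.zeros(kk + 1)
        for i in range(N):
            k3 = types2[i] - 1
            n2[k3] += 1.0
            v2[k3] += colsum[idx, i] - G * r[idx, i]
        tb2 = _tb_eval(G, kk + 1, n2, us, uq, zz, v2,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        combo_s = np.zeros(N, dtype=np.int64)
        cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
        marker_ind[m_out] = 0
        marker_ind[m_in] = idx + 1
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types2, kk + 1, combo_s, cc_s, gamma
        )
        dalloc = _alloc_ll(n2, kk + 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dprior = -lamK - lamM * ((kk + 1.0) * sl2 - kk * slT[idx])
        dlog = (tb2 - tb[idx]) + beta * (
            mb2 - mb[idx] + nullm[m_out] - nullm[m_in] + dalloc + dprior
        )
        logq = (
            math.log(mw[m_out])
            - math.log(mw[m_in])
            - math.log((kk + 1.0) * kk / 2.0)
            + math.log(1.0 * kk)
            - math.log(1.0 * cnt)
            + math.log(1.0 * T[m_in])
        )
        if math.log(rng.random()) < dlog + logq:
            types[idx, :] = types2
            K[idx] = kk + 1
            _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k)
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            tb[idx] = tb2
            nulls[1] += nullm[m_out] - nullm[m_in]
            return 1
        marker_ind[m_out] = idx + 1
        marker_ind[m_in] = 0
        return 0
    else:
        # swap + merge a type pair separated exactly by the outgoing marker
        if kk <= 1:
            return 0
        a = int(rng.random() * kk)
        b = int(rng.random() * (kk - 1))
        if b >= a:
            b += 1
        k1 = a if a < b else b
        k2 = b if a < b else a
        cnt = 0
        for cc in range(T[m_out]):
            eqA = True
            eqB = True
            for i in range(N):
                t = types[idx, i]
                if t != k1 + 1 and t != k2 + 1:
                    continue
                in2 = X[m_out, i] == cc
                if in2 != (t == k2 + 1):
                    eqA = False
                if in2 != (t == k1 + 1):
                    eqB = False
                if not eqA and not eqB:
                    break
            if eqA or eqB:
                cnt += 1
        if cnt == 0:
            return 0
        n_merged = n_k[idx, k1] + n_k[idx, k2]
        types2 = types[idx].copy()
        last = kk - 1
        for i in range(N):
            t = types2[i]
            if t == k2 + 1:
                types2[i] = k1 + 1
            elif t == last + 1 and k2 != last:
                types2[i] = k2 + 1
        n2 = np.zeros(kk - 1)
        v2 = np.zeros(kk - 1)
        for i in range(N):
            k3 = types2[i] - 1
            n2[k3] += 1.0
            v2[k3] += colsum[idx, i] - G * r[idx, i]
        tb2 = _tb_eval(G, kk - 1, n2, us, uq, zz, v2,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        combo_s = np.zeros(N, dtype=np.int64)
        cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
        marker_ind[m_out] = 0
        marker_ind[m_in] = idx + 1
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types2, kk - 1, combo_s, cc_s, gamma
        )
        dalloc = _alloc_ll(n2, kk - 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dprior = lamK - lamM * ((kk - 1.0) * sl2 - kk * slT[idx])
        dlog = (tb2 - tb[idx]) + beta * (
            mb2 - mb[idx] + nullm[m_out] - nullm[m_in] + dalloc + dprior
        )
        logq = (
            math.log(mw[m_out])
            - math.log(mw[m_in])
            + math.log(kk * (kk - 1.0) / 2.0)
            - math.log(kk - 1.0)
            + math.log(1.0 * cnt)
            - math.log(1.0 * T[m_out])
        )
        if math.log(rng.random()) < dlog + logq:
            types[idx, :] = types2
            K[idx] = kk - 1
            _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k)
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            tb[idx] = tb2
            nulls[1] += nullm[m_out] - nullm[m_in]
            return 1
        marker_ind[m_out] = idx + 1
        marker_ind[m_in] = 0
        return 0


@njit(cache=True)
def _pair_birth_death(
    rng, idx, Y, X, T, logT, nullm, excl, pw, pcum, pi, pj,
    marker_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb, nulls,
    gamma, delta, lamK, lamM, maxMarkers, maxK, beta,
):
    """Joint move for epistatic marker pairs: add two null markers while
    splitting one type into the two genotype-combination cells the pair
    occupies there (birth), or remove two markers while merging a type
    pair that coincides with those cells (death).  Purely epistatic loci
    (no marginal effects) are only reachable through such paired moves."""
    M, N = X.shape
    kk = K[idx]
    G = Gd[idx]
    us, uq = _u_stats(sumy[idx], sumy2[idx], G, rsum[idx])
    zz = sumsq[idx] - 2.0 * rc[idx] + G * rsumsq[idx]
    maxC = ccounts.shape[2]
    maxKs = ccounts.shape[1]
    birth = rng.random() < 0.5
    if birth:
        if kk >= maxK or Mcnt[idx] + 2 > maxMarkers:
            return 0
        flat = _weighted_pick(rng, pcum)
        m1 = pi[flat]
        m2_ = pj[flat]
        if marker_ind[m1] != 0 or marker_ind[m2_] != 0:
            return 0
        if excl[m1, m2_] or T[m1] != 2 or T[m2_] != 2:
            return 0
        if not _marker_excl_ok(m1, idx, marker_ind, excl, -1):
            return 0
        if not _marker_excl_ok(m2_, idx, marker_ind, excl, -1):
            return 0
        k = int(rng.random() * kk)
        # split type k along the pair's diagonal (genotypes agree/disagree);
        # this is the bipartition a purely epistatic pair induces, and it
        # tolerates the type impurity real heritabilities produce
        nA = 0
        nk_old = n_k[idx, k]
        for i in range(N):
            if types[idx, i] == k + 1 and X[m1, i] == X[m2_, i]:
                nA += 1
        if nA == 0 or nA == nk_old:
            return 0
        types2 = types[idx].copy()
        for i in range(N):
            if types[idx, i] == k + 1 and X[m1, i] != X[m2_, i]:
                types2[i] = kk + 1
        n2 = np.zeros(kk + 1)
        v2 = np.zeros(kk + 1)
        for i in range(N):
            k3 = types2[i] - 1
            n2[k3] += 1.0
            v2[k3] += colsum[idx, i] - G * r[idx, i]
        tb2 = _tb_eval(G, kk + 1, n2, us, uq, zz, v2,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        combo_s = np.zeros(N, dtype=np.int64)
        cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
        marker_ind[m1] = idx + 1
        marker_ind[m2_] = idx + 1
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types2, kk + 1, combo_s, cc_s, gamma
        )
        dalloc = _alloc_ll(n2, kk + 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dprior = -lamK - lamM * ((kk + 1.0) * sl2 - kk * slT[idx])
        dlog = (tb2 - tb[idx]) + beta * (
            mb2 - mb[idx] - nullm[m1] - nullm[m2_] + dalloc + dprior
        )
        logq = (
            -math.log((Mcnt[idx] + 2.0) * (Mcnt[idx] + 1.0) / 2.0)
            - math.log((kk + 1.0) * kk / 2.0)
            - math.log(pw[m1, m2_])
            + math.log(1.0 * kk)
        )
        if math.log(rng.random()) < dlog + logq:
            types[idx, :] = types2
            K[idx] = kk + 1
            _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k)
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            tb[idx] = tb2
            nulls[1] -= nullm[m1] + nullm[m2_]
            return 1
        marker_ind[m1] = 0
        marker_ind[m2_] = 0
        return 0
    else:
        if kk <= 1 or Mcnt[idx] < 2:
            return 0
        j1 = int(rng.random() * Mcnt[idx])
        j2 = int(rng.random() * (Mcnt[idx] - 1))
        if j2 >= j1:
            j2 += 1
        m1 = -1
        m2_ = -1
        c1 = 0
        for m3 in range(M):
            if marker_ind[m3] == idx + 1:
                if c1 == j1:
                    m1 = m3
                if c1 == j2:
                    m2_ = m3
                c1 += 1
        a = int(rng.random() * kk)
        b = int(rng.random() * (kk - 1))
        if b >= a:
            b += 1
        k1 = a if a < b else b
        k2 = b if a < b else a
        if T[m1] != 2 or T[m2_] != 2:
            return 0
        # reverse reachability: the pair's diagonal must separate k1 from
        # k2 exactly over their union (one side agrees, the other differs)
        ok_a = True  # k1 = agree side
        ok_b = True  # k2 = agree side
        for i in range(N):
            t = types[idx, i]
            if t != k1 + 1 and t != k2 + 1:
                continue
            agree = X[m1, i] == X[m2_, i]
            if agree != (t == k1 + 1):
                ok_a = False
            if agree != (t == k2 + 1):
                ok_b = False
            if not ok_a and not ok_b:
                break
        if not ok_a and not ok_b:
            return 0
        n_merged = n_k[idx, k1] + n_k[idx, k2]
        types2 = types[idx].copy()
        last = kk - 1
        for i in range(N):
            t = types2[i]
            if t == k2 + 1:
                types2[i] = k1 + 1
            elif t == last + 1 and k2 != last:
                types2[i] = k2 + 1
        n2 = np.zeros(kk - 1)
        v2 = np.zeros(kk - 1)
        for i in range(N):
            k3 = types2[i] - 1
            n2[k3] += 1.0
            v2[k3] += colsum[idx, i] - G * r[idx, i]
        tb2 = _tb_eval(G, kk - 1, n2, us, uq, zz, v2,
                       var[idx, 0], var[idx, 1], var[idx, 2], beta)
        combo_s = np.zeros(N, dtype=np.int64)
        cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
        marker_ind[m1] = 0
        marker_ind[m2_] = 0
        C2, Mc2, sl2, mb2 = _rebuild_marker_side(
            idx, marker_ind, X, T, logT, types2, kk - 1, combo_s, cc_s, gamma
        )
        dalloc = _alloc_ll(n2, kk - 1, delta) - _alloc_ll(n_k[idx], kk, delta)
        dprior = lamK + lamM * (kk * slT[idx] - (kk - 1.0) * sl2)
        dlog = (tb2 - tb[idx]) + beta * (
            mb2 - mb[idx] + nullm[m1] + nullm[m2_] + dalloc + dprior
        )
        logq = (
            math.log(pw[m1, m2_])
            - math.log(kk - 1.0)
            + math.log(Mcnt[idx] * (Mcnt[idx] - 1.0) / 2.0)
            + math.log(kk * (kk - 1.0) / 2.0)
        )
        if math.log(rng.random()) < dlog + logq:
            types[idx, :] = types2
            K[idx] = kk - 1
            _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k)
            _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                           combo, Cmod, Mcnt, slT, mb, ccounts)
            tb[idx] = tb2
            nulls[1] += nullm[m1] + nullm[m2_]
            return 1
        marker_ind[m1] = idx + 1
        marker_ind[m2_] = idx + 1
        return 0


# -------------------------------------------------- reallocation proposals


@njit(cache=True)
def _canonical_row(types_row):
    """Relabel a type row by first occurrence (canonical set partition)."""
    N = types_row.shape[0]
    out = np.zeros(N, dtype=np.int64)
    mapping = np.zeros(N + 2, dtype=np.int64)
    nxt = 0
    for i in range(N):
        lab = types_row[i]
        if mapping[lab] == 0:
            nxt += 1
            mapping[lab] = nxt
        out[i] = mapping[lab]
    return out


@njit(cache=True)
def _realloc(rng, combo_row, C, maxK, delta, gamma, use_informed,
             do_sample, forced):
    """Sequential allocation of individuals to types.

    Individuals are processed in index order; each joins an existing type
    with weight ``(n_c + delta)`` times — on the informed route — the
    Dirichlet-multinomial predictive of its genotype combination, or
    opens a new type with weight ``delta / C`` (informed) / ``delta``
    (plain).  With ``do_sample`` the partition is drawn; otherwise the
    (canonical) ``forced`` partition is replayed and its density
    accumulated.  Any partition has positive density on either route.
    """
    N = combo_row.shape[0]
    n_c = np.zeros(maxK)
    cnt = np.zeros((maxK, C))
    out = np.zeros(N, dtype=np.int64)
    K = 0
    logq = 0.0
    lw = np.empty(maxK + 1)
    for i in range(N):
        cb = combo_row[i]
        tot = 0.0
        for c in range(K):
            w = n_c[c] + delta
            if use_informed:
                w *= (gamma + cnt[c, cb]) / (C * gamma + n_c[c])
            lw[c] = w
            tot += w
        if K < maxK:
            w_new = delta / C if use_informed else delta
            lw[K] = w_new
            tot += w_new
            ncand = K + 1
        else:
            ncand = K
        if do_sample:
            u = rng.random() * tot
            acc = 0.0
            pick = ncand - 1
            for c in range(ncand):
                acc += lw[c]
                if u <= acc:
                    pick = c
                    break
        else:
            pick = forced[i] - 1
            if pick > K or pick >= ncand:
                return out, 0, -np.inf
        logq += math.log(lw[pick] / tot)
        out[i] = pick + 1
        if pick == K:
            K += 1
        n_c[pick] += 1.0
        cnt[pick, cb] += 1.0
    return out, K, logq


@njit(cache=True)
def _realloc_mixture_density(rng, combo_row, C, maxK, delta, gamma, forced):
    """Log density of the (canonical) ``forced`` partition under the
    half/half mixture of the informed and plain allocation routes.  The
    plain route gives coarse partitions high density, so moves between
    unstructured and structured partitions stay reversible."""
    _, _, lq_m = _realloc(rng, combo_row, C, maxK, delta, gamma,
                          True, False, forced)
    _, _, lq_p = _realloc(rng, combo_row, C, maxK, delta, gamma,
                          False, False, forced)
    hi = lq_m if lq_m > lq_p else lq_p
    if not np.isfinite(hi):
        return -np.inf
    return hi + math.log(0.5 * math.exp(lq_m - hi) + 0.5 * math.exp(lq_p - hi))


@njit(cache=True)
def _module_combo(idx, marker_ind, X, T, extra1, extra2):
    """Genotype-combination codes over the module's markers plus up to two
    extra markers (pass -1 to skip), with the cell count C."""
    M, N = X.shape
    combo = np.zeros(N, dtype=np.int64)
    C = 1
    for m in range(M):
        use = marker_ind[m] == idx + 1 or m == extra1 or m == extra2
        if use:
            t = T[m]
            C *= t
            for i in range(N):
                combo[i] = combo[i] * t + X[m, i]
    return combo, C


@njit(cache=True)
def _realloc_move(
    rng, idx, kind, Y, X, T, logT, nullm, excl, mw, mcum, pw, pcum, pi, pj,
    marker_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb, nulls,
    gamma, delta, a0, b0, lamK, lamM, maxMarkers, maxK, beta,
):
    """Joint marker change plus full type reallocation.

    kind 0: reallocate types only; kind 1: single marker birth (+realloc)
    or death; kind 2: marker-pair birth (+realloc) or death; kind 3: swap
    two in-module markers for a proposed pair (+realloc).  The new
    partition is proposed by ``_realloc`` under the proposed marker set;
    the reverse density replays the current partition under the reverse
    marker set, so acceptance is exact.  Marker births require the
    sampled partition to have at least two types (and deaths start from
    at least two), which keeps markers out of modules that give them no
    type structure to explain.
    """
    M, N = X.shape
    maxC = ccounts.shape[2]
    maxKs = ccounts.shape[1]
    cur_canon = _canonical_row(types[idx])
    birth = rng.random() < 0.5
    m1 = -1
    m2 = -1
    v1 = -1
    v2 = -1
    dnull = 0.0
    logq_marker = 0.0
    if kind > 0 and not birth and K[idx] == 1 and kind != 3:
        return 0
    if kind == 0:
        pass
    elif kind == 3:
        # symmetric: evict two in-module markers, bring in a proposed pair
        if Mcnt[idx] < 2:
            return 0
        j1 = int(rng.random() * Mcnt[idx])
        j2 = int(rng.random() * (Mcnt[idx] - 1))
        if j2 >= j1:
            j2 += 1
        c1 = 0
        for m3 in range(M):
            if marker_ind[m3] == idx + 1:
                if c1 == j1:
                    v1 = m3
                if c1 == j2:
                    v2 = m3
                c1 += 1
        flat = _weighted_pick(rng, pcum)
        m1 = pi[flat]
        m2 = pj[flat]
        if marker_ind[m1] != 0 or marker_ind[m2] != 0 or excl[m1, m2]:
            return 0
        marker_ind[v1] = 0
        marker_ind[v2] = 0
        if (not _marker_excl_ok(m1, idx, marker_ind, excl, -1)
                or not _marker_excl_ok(m2, idx, marker_ind, excl, -1)):
            marker_ind[v1] = idx + 1
            marker_ind[v2] = idx + 1
            return 0
        dnull = nullm[v1] + nullm[v2] - nullm[m1] - nullm[m2]
        logq_marker = math.log(pw[v1, v2]) - math.log(pw[m1, m2])
    elif kind == 1:
        if birth:
            if Mcnt[idx] >= maxMarkers:
                return 0
            m1 = _weighted_pick(rng, mcum)
            if marker_ind[m1] != 0:
                return 0
            if not _marker_excl_ok(m1, idx, marker_ind, excl, -1):
                return 0
            dnull = -nullm[m1]
            # forward: pick from mw; reverse: pick 1 of Mcnt+1 uniformly
            logq_marker = -math.log(Mcnt[idx] + 1.0) - math.log(mw[m1])
        else:
            if Mcnt[idx] == 0:
                return 0
            j = int(rng.random() * Mcnt[idx])
            c1 = 0
            for m3 in range(M):
                if marker_ind[m3] == idx + 1:
                    if c1 == j:
                        m1 = m3
                        break
                    c1 += 1
            dnull = nullm[m1]
            logq_marker = math.log(mw[m1]) + math.log(1.0 * Mcnt[idx])
    else:
        if birth:
            if Mcnt[idx] + 2 > maxMarkers:
                return 0
            flat = _weighted_pick(rng, pcum)
            m1 = pi[flat]
            m2 = pj[flat]
            if marker_ind[m1] != 0 or marker_ind[m2] != 0:
                return 0
            if excl[m1, m2]:
                return 0
            if not _marker_excl_ok(m1, idx, marker_ind, excl, -1):
                return 0
            if not _marker_excl_ok(m2, idx, marker_ind, excl, -1):
                return 0
            dnull = -nullm[m1] - nullm[m2]
            logq_marker = (
                -math.log((Mcnt[idx] + 2.0) * (Mcnt[idx] + 1.0) / 2.0)
                - math.log(pw[m1, m2])
            )
        else:
            if Mcnt[idx] < 2:
                return 0
            j1 = int(rng.random() * Mcnt[idx])
            j2 = int(rng.random() * (Mcnt[idx] - 1))
            if j2 >= j1:
                j2 += 1
            c1 = 0
            for m3 in range(M):
                if marker_ind[m3] == idx + 1:
                    if c1 == j1:
                        m1 = m3
                    if c1 == j2:
                        m2 = m3
                    c1 += 1
            dnull = nullm[m1] + nullm[m2]
            logq_marker = (
                math.log(pw[m1, m2])
                + math.log(Mcnt[idx] * (Mcnt[idx] - 1.0) / 2.0)
            )
    if kind == 3:
        add1, add2 = m1, m2
    else:
        add1 = m1 if (kind > 0 and birth) else -1
        add2 = m2 if (kind == 2 and birth) else -1
        # proposed marker set: current +/- the move's markers
        if kind > 0 and not birth:
            marker_ind[m1] = 0
            if kind == 2:
                marker_ind[m2] = 0

    combo_new, C_new = _module_combo(idx, marker_ind, X, T, add1, add2)
    bad = C_new > maxC
    types2 = cur_canon
    K2 = 0
    logq_fwd = 0.0
    logq_rev = 0.0
    G = Gd[idx]
    if not bad:
        route_marker = rng.random() < 0.5
        types2, K2, _ = _realloc(rng, combo_new, C_new, maxK, 1.0,
                                 gamma, route_marker, True, cur_canon)
        logq_fwd = _realloc_mixture_density(rng, combo_new, C_new, maxK, 1.0,
                                            gamma, types2)
        if kind == 1 or kind == 2:
            if birth and K2 == 1:
                bad = True
    if not bad:
        # reverse replay under the reverse marker set (the current one)
        if kind == 3:
            combo_old, C_old = _module_combo(idx, marker_ind, X, T, v1, v2)
        else:
            combo_old, C_old = _module_combo(
                idx, marker_ind, X, T,
                m1 if (kind > 0 and not birth) else -1,
                m2 if (kind == 2 and not birth) else -1,
            )
        logq_rev = _realloc_mixture_density(rng, combo_old, C_old, maxK, 1.0,
                                            gamma, cur_canon)
        if not np.isfinite(logq_rev):
            bad = True
    if bad:
        if kind == 3:
            marker_ind[v1] = idx + 1
            marker_ind[v2] = idx + 1
        elif kind > 0 and not birth:
            marker_ind[m1] = idx + 1
            if kind == 2:
                marker_ind[m2] = idx + 1
        return 0
    # commit marker indicators for the proposal evaluation
    if kind == 3:
        marker_ind[m1] = idx + 1
        marker_ind[m2] = idx + 1
    elif kind > 0 and birth:
        marker_ind[m1] = idx + 1
        if kind == 2:
            marker_ind[m2] = idx + 1
    # proposal's expression stats, plus a sigma_t^2 tailored to the
    # proposed partition (modes with different type structure sit at very
    # different type-variance scales; jumping without rescaling is vetoed)
    n2 = np.zeros(K2)
    vv2 = np.zeros(K2)
    for i in range(N):
        k3 = types2[i] - 1
        n2[k3] += 1.0
        vv2[k3] += colsum[idx, i] - G * r[idx, i]
    kk = K[idx]
    us, uq = _u_stats(sumy[idx], sumy2[idx], G, rsum[idx])
    zz = sumsq[idx] - 2.0 * rc[idx] + G * rsumsq[idx]
    tb2 = _tb_eval(G, K2, n2, us, uq, zz, vv2,
                   var[idx, 0], var[idx, 1], var[idx, 2], beta)
    combo_s = np.zeros(N, dtype=np.int64)
    cc_s = np.zeros((maxKs, maxC), dtype=np.int64)
    C2, Mc2, sl2, mb2 = _rebuild_marker_side(
        idx, marker_ind, X, T, logT, types2, K2, combo_s, cc_s, gamma
    )
    dalloc = _alloc_ll(n2, K2, delta) - _alloc_ll(n_k[idx], kk, delta)
    dprior = -lamK * (K2 - kk) - lamM * (K2 * sl2 - kk * slT[idx])
    dlog = (tb2 - tb[idx]) + beta * (mb2 - mb[idx] + dnull + dalloc + dprior)
    if math.log(rng.random()) < dlog + logq_marker + logq_rev - logq_fwd:
        types[idx, :] = types2
        K[idx] = K2
        _recompute_type_stats(idx, types, r, colsum, vcol, rtyp, n_k)
        _commit_marker(idx + 1, C2, Mc2, sl2, mb2, combo_s, cc_s,
                       combo, Cmod, Mcnt, slT, mb, ccounts)
        tb[idx] = tb2
        nulls[1] += dnull
        return 1
    # revert marker indicators
    if kind == 3:
        marker_ind[m1] = 0
        marker_ind[m2] = 0
        marker_ind[v1] = idx + 1
        marker_ind[v2] = idx + 1
    elif kind > 0:
        if birth:
            marker_ind[m1] = 0
            if kind == 2:
                marker_ind[m2] = 0
        else:
            marker_ind[m1] = idx + 1
            if kind == 2:
                marker_ind[m2] = idx + 1
    return 0


# ------------------------------------------------------ continuous update


@njit(cache=True)
def _continuous_update(
    rng, idx, Y,
    gene_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, tb,
    a0, b0, ar, br, beta,
):
    """Gibbs refresh of module idx's continuous parameters.

    Draws (alpha, mu) exactly from their joint tempered conditional (the
    parameters the collapsed moves integrate out), then the individual
    effects r_i and the four variance components, then discards alpha/mu
    (partially collapsed Gibbs: marginal moves precede the conditional
    refresh)."""
    Gn, N = Y.shape
    G = Gd[idx]
    kk = K[idx]
    s2 = var[idx, 0]
    s2g = var[idx, 1]
    s2t = var[idx, 2]
    s2r = var[idx, 3]
    if G > 0:
        genes = np.empty(G, dtype=np.int64)
        j = 0
        for g in range(Gn):
            if gene_ind[g] == idx + 1:
                genes[j] = g
                j += 1
        # joint (alpha, mu) draw: N(P^{-1} Uz, (s2/beta) P^{-1})
        d = G + kk
        P = np.zeros((d, d))
        rhs = np.empty(d)
        a = N + s2 / s2g
        for gi in range(G):
            P[gi, gi] = a
        for gi in range(G):
            g = genes[gi]
            acc = 0.0
            for i in range(N):
                acc += Y[g, i] - r[idx, i]
            rhs[gi] = acc
            for k in range(kk):
                P[gi, G + k] = n_k[idx, k]
                P[G + k, gi] = n_k[idx, k]
        for k in range(kk):
            P[G + k, G + k] = G * n_k[idx, k] + s2 / s2t
            rhs[G + k] = vcol[idx, k] - G * rtyp[idx, k]
        L = np.linalg.cholesky(P)
        # mean: solve P m = rhs
        yv = np.empty(d)
        for i in range(d):
            acc = rhs[i]
            for j2 in range(i):
                acc -= L[i, j2] * yv[j2]
            yv[i] = acc / L[i, i]
        mvec = np.empty(d)
        for i in range(d - 1, -1, -1):
            acc = yv[i]
            for j2 in range(i + 1, d):
                acc -= L[j2, i] * mvec[j2]
            mvec[i] = acc / L[i, i]
        # sample: x = m + sqrt(s2/beta) * L^{-T} xi
        xi = np.empty(d)
        for i in range(d):
            xi[i] = rng.standard_normal()
        zv = np.empty(d)
        for i in range(d - 1, -1, -1):
            acc = xi[i]
            for j2 in range(i + 1, d):
                acc -= L[j2, i] * zv[j2]
            zv[i] = acc / L[i, i]
        sc = math.sqrt(s2 / beta)
        alpha = np.empty(G)
        mu = np.empty(kk)
        for gi in range(G):
            alpha[gi] = mvec[gi] + sc * zv[gi]
        for k in range(kk):
            mu[k] = mvec[G + k] + sc * zv[G + k]
        asum = 0.0
        a2 = 0.0
        for gi in range(G):
            asum += alpha[gi]
            a2 += alpha[gi] * alpha[gi]
        m2 = 0.0
        for k in range(kk):
            m2 += mu[k] * mu[k]
        # r_i | alpha, mu
        prec = beta * G / s2 + 1.0 / s2r
        sd = 1.0 / math.sqrt(prec)
        for i in range(N):
            resid = colsum[idx, i] - asum - G * mu[types[idx, i] - 1]
            mean = (beta / s2) * resid / prec
            r[idx, i] = mean + sd * rng.standard_normal()
        # error SS
        ss = 0.0
        for gi in range(G):
            g = genes[gi]
            for i in range(N):
                e = Y[g, i] - alpha[gi] - mu[types[idx, i] - 1] - r[idx, i]
                ss += e * e
        var[idx, 0] = (b0 + 0.5 * beta * ss) / _gamma_sample(rng, a0 + 0.5 * beta * G * N)
        var[idx, 1] = (b0 + 0.5 * beta * a2) / _gamma_sample(rng, a0 + 0.5 * beta * G)
        var[idx, 2] = (b0 + 0.5 * beta * m2) / _gamma_sample(rng, a0 + 0.5 * beta * kk)
    else:
        # no genes: r from its prior, variances from theirs
        var[idx, 0] = b0 / _gamma_sample(rng, a0)
        var[idx, 1] = b0 / _gamma_sample(rng, a0)
        var[idx, 2] = b0 / _gamma_sample(rng, a0)
        sdr = math.sqrt(var[idx, 3])
        for i in range(N):
            r[idx, i] = sdr * rng.standard_normal()
    rr = 0.0
    for i in range(N):
        rr += r[idx, i] * r[idx, i]
    var[idx, 3] = (br + 0.5 * rr) / _gamma_sample(rng, ar + 0.5 * N)
    # refresh r-dependent caches
    rs = 0.0
    rss = 0.0
    rcv = 0.0
    rtyp[idx, :] = 0.0
    for i in range(N):
        ri = r[idx, i]
        rs += ri
        rss += ri * ri
        rcv += colsum[idx, i] * ri
        rtyp[idx, types[idx, i] - 1] += ri
    rsum[idx] = rs
    rsumsq[idx] = rss
    rc[idx] = rcv
    tb[idx] = _tb_module(idx, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                         vcol, rtyp, n_k, K, var, beta)


# ------------------------------------------------------------- full sweep


@njit(cache=True)
def _sweep(
    rng, Y, rowsum, rowsumsq, X, T, logT, nullg, nullm, excl,
    mw, mcum, pw, pcum, pi, pj,
    gene_ind, marker_ind, types, K, r, var,
    colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
    vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb, nulls,
    gamma, delta, a0, b0, ar, br, lamK, lamM, lamG, maxMarkers, maxK, beta,
    sample_continuous,
):
    """One systematic sweep: genes -> markers -> per-module individuals ->
    split/merge -> continuous parameters."""
    D = types.shape[0]
    _gene_sweep(rng, Y, rowsum, rowsumsq, nullg,
                gene_ind, types, K, r, var,
                colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                vcol, rtyp, n_k, tb, nulls, lamG, beta)
    _marker_sweep(rng, X, T, logT, nullm, excl,
                  marker_ind, types, K, slT,
                  combo, Cmod, Mcnt, ccounts, mb, nulls,
                  gamma, lamM, maxMarkers, beta)
    for idx in range(D):
        _indiv_sweep(rng, idx, Y, types, K, r, var,
                     colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                     vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb,
                     gamma, delta, lamK, lamM, beta, maxK)
        for _rep in range(3):
            _split_merge(rng, idx, Y, X, T, types, K, r, var,
                         colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                         vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts, tb, mb,
                         gamma, delta, lamK, lamM, beta, maxK)
            _marker_birth_death(rng, idx, Y, X, T, logT, nullm, excl, mw, mcum,
                                marker_ind, types, K, r, var,
                                colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                                vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts,
                                tb, mb, nulls,
                                gamma, delta, lamK, lamM, maxMarkers, maxK, beta)
        for _rep in range(2):
            _marker_null_exchange(rng, idx, X, T, logT, nullm, excl, mw, mcum,
                                  marker_ind, types, K,
                                  combo, Cmod, Mcnt, slT, ccounts, mb, nulls,
                                  gamma, lamM, maxMarkers, beta)
        for _rep in range(3):
            _marker_swap_split(rng, idx, Y, X, T, logT, nullm, excl, mw, mcum,
                               marker_ind, types, K, r, var,
                               colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                               vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts,
                               tb, mb, nulls,
                               gamma, delta, lamK, lamM, maxK, beta)
        # epistatic pairs are a needle among C(M, 2) candidates: try many
        for _rep in range(15):
            _pair_birth_death(rng, idx, Y, X, T, logT, nullm, excl, pw, pcum, pi, pj,
                              marker_ind, types, K, r, var,
                              colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                              vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts,
                              tb, mb, nulls,
                              gamma, delta, lamK, lamM, maxMarkers, maxK, beta)
        # joint marker +/- full type reallocation (escapes partitions that
        # drifted onto expression quantile bands)
        for kind in (0, 1, 1, 2, 2, 2, 3, 3):
            _realloc_move(rng, idx, kind, Y, X, T, logT, nullm, excl,
                          mw, mcum, pw, pcum, pi, pj,
                          marker_ind, types, K, r, var,
                          colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                          vcol, rtyp, n_k, combo, Cmod, Mcnt, slT, ccounts,
                          tb, mb, nulls,
                          gamma, delta, a0, b0, lamK, lamM, maxMarkers, maxK, beta)
        if sample_continuous:
            _continuous_update(rng, idx, Y, gene_ind, types, K, r, var,
                               colsum, Gd, sumy, sumy2, sumsq, rsum, rsumsq, rc,
                               vcol, rtyp, n_k, tb, a0, b0, ar, br, beta)
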