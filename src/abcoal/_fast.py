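"""Compiled kernels: structured-coalescent simulation, mutation, locus stats.

These are the hot inner loops behind :mod:`abcoal.coalsim` and the ABC
reference-table builder.  Everything here is deliberately low-level; the
public, documented surfaces live in the wrapping modules.

Conventions:
  * time in generations, increasing into the past;
  * diploid sizes, pairwise coalescence rate 1/(2N) per generation;
  * three populations (0, 1, 2); inactive populations simply hold no lineages;
  * migration rates are *backward* lineage-movement rates per generation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: cap on logged migration events per genealogy (counting continues past it)
MIG_LOG_CAP = 4096


@njit(cache=True)
def sim_tree(
    seed,
    npp,
    t_starts,
    sizes,
    mig,
    merge_src,
    merge_dst,
    parent,
    time_arr,
    node_pop,
    mig_log,
    log_events,
):
    """Simulate one genealogy; fills parent/time/node_pop, returns #migrations.

    Epoch ``e`` spans [t_starts[e], t_starts[e+1]); on entry to epoch ``e``
    lineages in ``merge_src[e]`` are moved to ``merge_dst[e]`` (no merge when
    -1).  ``mig_log`` rows are (time, node, from, to) when ``log_events``.
    """
    np.random.seed(seed)
    n = npp[0] + npp[1] + npp[2]
    n_nodes = 2 * n - 1
    for v in range(n_nodes):
        parent[v] = -1
        time_arr[v] = 0.0
        node_pop[v] = -1
    lin_node = np.empty(n, np.int64)
    lin_pop = np.empty(n, np.int64)
    idx = 0
    for p in range(3):
        for _ in range(npp[p]):
            lin_node[idx] = idx
            lin_pop[idx] = p
            node_pop[idx] = p
            idx += 1
    k = n
    nxt = n
    t = 0.0
    n_mig = 0
    K = t_starts.shape[0]
    crate = np.zeros(3)
    mrate = np.zeros((3, 3))
    cnt = np.zeros(3, np.int64)
    for e in range(K):
        if k > 1 and merge_src[e] >= 0:
            for i in range(k):
                if lin_pop[i] == merge_src[e]:
                    lin_pop[i] = merge_dst[e]
        if k <= 1:
            continue
        t_end = t_starts[e + 1] if e + 1 < K else 1.0e300
        while k > 1:
            for p in range(3):
                cnt[p] = 0
            for i in range(k):
                cnt[lin_pop[i]] += 1
            tot = 0.0
            for p in range(3):
                crate[p] = 0.0
                if cnt[p] > 1 and sizes[e, p] > 0.0:
                    crate[p] = cnt[p] * (cnt[p] - 1) * 0.25 / sizes[e, p]
                    tot += crate[p]
                for q in range(3):
                    mrate[p, q] = 0.0
                    if q != p and cnt[p] > 0 and mig[e, p, q] > 0.0:
                        mrate[p, q] = cnt[p] * mig[e, p, q]
                        tot += mrate[p, q]
            if tot <= 0.0:
                t = t_end
                break
            dt = np.random.exponential(1.0 / tot)
            if t + dt >= t_end:
                t = t_end
                break
            t += dt
            u = np.random.random() * tot
            acc = 0.0
            handled = False
            for p in range(3):
                acc += crate[p]
                if crate[p] > 0.0 and u < acc:
                    r1 = np.random.randint(cnt[p])
                    r2 = np.random.randint(cnt[p] - 1)
                    if r2 >= r1:
                        r2 += 1
                    i1 = -1
                    i2 = -1
                    seen = 0
                    for i in range(k):
                        if lin_pop[i] == p:
                            if seen == r1:
                                i1 = i
                            if seen == r2:
                                i2 = i
                            seen += 1
                    v = nxt
                    nxt += 1
                    parent[lin_node[i1]] = v
                    parent[lin_node[i2]] = v
                    time_arr[v] = t
                    node_pop[v] = p
                    lin_node[i1] = v
                    lin_node[i2] = lin_node[k - 1]
                    lin_pop[i2] = lin_pop[k - 1]
                    k -= 1
                    handled = True
                    break
            if handled:
                continue
            for p in range(3):
                if handled:
                    break
                for q in range(3):
                    if mrate[p, q] <= 0.0:
                        continue
                    acc += mrate[p, q]
                    if u < acc:
                        r = np.random.randint(cnt[p])
                        seen = 0
                        for i in range(k):
                            if lin_pop[i] == p:
                                if seen == r:
                                    lin_pop[i] = q
                                    if log_events and n_mig < MIG_LOG_CAP:
                                        mig_log[n_mig, 0] = t
                                        mig_log[n_mig, 1] = lin_node[i]
                                        mig_log[n_mig, 2] = p
                                        mig_log[n_mig, 3] = q
                                    n_mig += 1
                                    break
                                seen += 1
                        handled = True
                        break
        if k <= 1:
            break
    return n_mig


@njit(cache=True)
def mutate_infinite(seed, parent, time_arr, n, mu_locus):
    """Infinite-sites mutations: returns an (n, n_mutations) 0/1 matrix.

    ``mu_locus`` is the total per-generation mutation rate of the locus
    (per-site rate times locus length).
    """
    np.random.seed(seed)
    n_nodes = 2 * n - 1
    nb = n_nodes - 1  # branches (all nodes but the root)
    blen = np.empty(nb)
    total = 0.0
    for v in range(nb):
        blen[v] = time_arr[parent[v]] - time_arr[v]
        total += blen[v]
    m = np.random.poisson(mu_locus * total)
    out = np.zeros((n, m), np.int8)
    if m == 0:
        return out
    nw = (n + 63) // 64
    masks = np.zeros((n_nodes, nw), np.uint64)
    one = np.uint64(1)
    for leaf in range(n):
        masks[leaf, leaf // 64] = one << np.uint64(leaf % 64)
    for v in range(nb):  # children always have smaller index than parents
        p = parent[v]
        for w in range(nw):
            masks[p, w] |= masks[v, w]
    cum = np.empty(nb)
    acc = 0.0
    for v in range(nb):
        acc += blen[v]
        cum[v] = acc
    for j in range(m):
        r = np.random.random() * total
        v = np.searchsorted(cum, r)
        if v >= nb:
            v = nb - 1
        for leaf in range(n):
            if (masks[v, leaf // 64] >> np.uint64(leaf % 64)) & one:
                out[leaf, j] = 1
    return out


@njit(cache=True)
def mutate_finite(seed, parent, time_arr, n, mu_site, length):
    """Finite-sites Jukes-Cantor mutations: returns an (n, length) base matrix
    with values 0..3; parallel and back mutation are possible."""
    np.random.seed(seed)
    n_nodes = 2 * n - 1
    seq = np.empty((n_nodes, length), np.int8)
    root = n_nodes - 1
    for s in range(length):
        seq[root, s] = np.random.randint(4)
    for v in range(n_nodes - 2, -1, -1):  # parents precede children
        p = parent[v]
        for s in range(length):
            seq[v, s] = seq[p, s]
        blen = time_arr[p] - time_arr[v]
        nm = np.random.poisson(blen * mu_site * length)
        for _ in range(nm):
            s = np.random.randint(length)
            seq[v, s] = (seq[v, s] + 1 + np.random.randint(3)) % 4
    return seq[:n].copy()


@njit(cache=True)
def locus_block(mat, npp, logstir, out):
    """Per-locus statistic block from a base matrix with pop-blocked rows.

    ``out`` (length 21): per species [S, h, k, TajD, Fs] (15), then per pair
    Phi_ST (3), then per pair mean between-species pairwise differences (3).
    Undefined entries are NaN.
    """
    n_sites = mat.shape[1]
    off = np.empty(4, np.int64)
    off[0] = 0
    for p in range(3):
        off[p + 1] = off[p] + npp[p]
    counts = np.zeros((3, n_sites, 4), np.int64)
    for p in range(3):
        for i in range(off[p], off[p + 1]):
            for s in range(n_sites):
                counts[p, s, mat[i, s]] += 1
    for p in range(3):
        nsp = npp[p]
        if nsp < 2:
            for j in range(5):
                out[5 * p + j] = np.nan
            continue
        s_sp = 0
        sumpairs = 0.0
        for s in range(n_sites):
            nal = 0
            c2 = 0
            for b in range(4):
                c = counts[p, s, b]
                if c > 0:
                    nal += 1
                c2 += c * c
            if nal > 1:
                s_sp += 1
            sumpairs += (nsp * nsp - c2) * 0.5
        k = sumpairs / (nsp * (nsp - 1) * 0.5)
        # haplotype count via double 64-bit polynomial row hashes
        h1 = np.empty(nsp, np.uint64)
        h2 = np.empty(nsp, np.uint64)
        m1 = np.uint64(1099511628211)
        m2 = np.uint64(33554467)
        salt = np.uint64(2654435761)
        for ii in range(nsp):
            a = np.uint64(1469598103934665603)
            b = np.uint64(88172645463325252)
            row = off[p] + ii
            for s in range(n_sites):
                v = np.uint64(mat[row, s] + 1)
                a = a * m1 + v
                b = b * m2 + v * salt
            h1[ii] = a
            h2[ii] = b
        h = 0
        for ii in range(nsp):
            dup = False
            for jj in range(ii):
                if h1[ii] == h1[jj] and h2[ii] == h2[jj]:
                    dup = True
                    break
            if not dup:
                h += 1
        out[5 * p + 0] = s_sp
        out[5 * p + 1] = h
        out[5 * p + 2] = k
        if s_sp == 0 or nsp < 4:  # D's variance vanishes for n <= 3
            out[5 * p + 3] = np.nan
        else:
            a1 = 0.0
            a2 = 0.0
            for i in range(1, nsp):
                a1 += 1.0 / i
                a2 += 1.0 / (i * i)
            b1 = (nsp + 1) / (3.0 * (nsp - 1))
            b2 = 2.0 * (nsp * nsp + nsp + 3) / (9.0 * nsp * (nsp - 1))
            c1 = b1 - 1.0 / a1
            c2 = b2 - (nsp + 2) / (a1 * nsp) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            out[5 * p + 3] = (k - s_sp / a1) / math.sqrt(
                e1 * s_sp + e2 * s_sp * (s_sp - 1)
            )
        if k <= 0.0:
            out[5 * p + 4] = np.nan
        else:
            logtheta = math.log(k)
            log_rising = 0.0
            for i in range(nsp):
                log_rising += math.log(k + i)
            terms = np.empty(nsp)
            mx = -1.0e308
            for j in range(1, nsp + 1):
                tv = logstir[nsp, j] + j * logtheta - log_rising
                terms[j - 1] = tv
                if tv > mx:
                    mx = tv
            tot = 0.0
            for j in range(nsp):
                tot += math.exp(terms[j] - mx)
            tail = 0.0
            for j in range(h - 1, nsp):
                tail += math.exp(terms[j] - mx)
            sp_ = tail / tot
            if sp_ < 1e-12:
                sp_ = 1e-12
            if sp_ > 1.0 - 1e-12:
                sp_ = 1.0 - 1e-12
            out[5 * p + 4] = math.log(sp_ / (1.0 - sp_))
    pi_ = 0
    for p in range(3):
        for q in range(p + 1, 3):
            na = npp[p]
            nb_ = npp[q]
            if na < 2 or nb_ < 2:
                out[15 + pi_] = np.nan
                out[18 + pi_] = np.nan
                pi_ += 1
                continue
            cross = 0.0
            suma = 0.0
            sumb = 0.0
            for s in range(n_sites):
                cpq = 0
                c2a = 0
                c2b = 0
                for b in range(4):
                    ca = counts[p, s, b]
                    cb = counts[q, s, b]
                    cpq += ca * cb
                    c2a += ca * ca
                    c2b += cb * cb
                cross += na * nb_ - cpq
                suma += (na * na - c2a) * 0.5
                sumb += (nb_ * nb_ - c2b) * 0.5
            out[18 + pi_] = cross / (na * nb_)
            ntot = na + nb_
            ssd_w = suma / na + sumb / nb_
            ssd_t = (suma + sumb + cross) / ntot
            sigma_w = ssd_w / (ntot - 2)
            n_prime = ntot - (na * na + nb_ * nb_) / ntot
            sigma_a = ((ssd_t - ssd_w) - sigma_w) / n_prime
            tot2 = sigma_a + sigma_w
            if tot2 == 0.0:
                out[15 + pi_] = np.nan
            else:
                out[15 + pi_] = sigma_a / tot2
            pi_ += 1


@njit(cache=True)
def dataset_blocks(
    tree_seeds,
    mut_seeds,
    npp,
    t_starts,
    sizes,
    mig,
    merge_src,
    merge_dst,
    mu_sites,
    length,
    infinite,
    logstir,
):
    """Simulate ``len(tree_seeds)`` unlinked loci and return their stat blocks."""
    n_loci = tree_seeds.shape[0]
    out = np.full((n_loci, 21), np.nan)
    n = npp[0] + npp[1] + npp[2]
    n_nodes = 2 * n - 1
    parent = np.empty(n_nodes, np.int64)
    time_arr = np.empty(n_nodes)
    node_pop = np.empty(n_nodes, np.int64)
    mig_log = np.empty((1, 4))
    for li in range(n_loci):
        sim_tree(
            tree_seeds[li],
            npp,
            t_starts,
            sizes,
            mig,
            merge_src,
            merge_dst,
            parent,
            time_arr,
            node_pop,
            mig_log,
            False,
        )
        if infinite:
            mat = mutate_infinite(
                mut_seeds[li], parent, time_arr, n, mu_sites[li] * length
            )
        else:
            mat = mutate_finite(mut_seeds[li], parent, time_arr, n, mu_sites[li], length)
        locus_block(mat, npp, logstir, out[li])
    return out


def log_stirling_table(n_max: int) -> np.ndarray:
    """(n_max+1, n_max+1) table of log |s(n, j)|, -inf where zero."""
    table = np.full((n_max + 1, n_max + 1), -np.inf)
    row = [1]
    table[0, 0] = 0.0
    for m in range(n_max):
        nxt = [0] * (m + 2)
        for j in range(m + 2):
            nxt[j] = (row[j - 1] if 1 <= j <= m + 1 else 0) + m * (
                row[j] if j <= m else 0
            )
        row = nxt
        for j, v in enumerate(row):
            if v:
                table[m + 1, j] = math.log(v)
    return table
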