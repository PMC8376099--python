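"""Compiled inner loops of the genetic algorithm.

Everything here operates on plain numpy arrays so numba can compile it; the
object-level API in :mod:`degroot_ga.ga` wraps these kernels.  All
randomness is drawn from a single ``numpy.random.Generator`` threaded
through every kernel, which makes a fit bit-reproducible given its seed.

Array conventions
-----------------
``pop``        (P, n, n) population of candidate weight matrices
``gene``       (P, n)    per-gene (per-row) objective values
``totals``     (P,)      total objective values (= gene.sum(axis=1))
``obs, mask``  (n, T)    observed opinions and observedness mask
``free_idx``   (n, n)    column indices of the non-fixed entries of each
                         row, padded; ``free_cnt[i]`` of them are valid
``wfixed``     (n,)      per-row sum of fixed weights
"""

from __future__ import annotations

import numpy as np
from numba import njit

# objective codes
OBJ_CONTINUOUS = 0
OBJ_LIKERT = 1

_HALF_UP_EPS = 1e-12


@njit(cache=True)
def back_bin(y, n_bins):
    """Bin index (1..n_bins) of a continuous opinion: half-up rounding of
    y * n_bins, clamped.  Mirrors core.likert_back."""
    k = int(np.floor(y * n_bins + 0.5 + _HALF_UP_EPS))
    if k < 1:
        k = 1
    elif k > n_bins:
        k = n_bins
    return k


@njit(cache=True)
def evaluate(W, obs, mask, obj_code, n_bins, gene_out):
    """Objective of one chromosome; fills per-gene values, returns total.

    The predicted trajectory is seeded at the observed initial opinions
    (xhat(0) = x(0)), so t = 0 contributes nothing; objective terms are
    accumulated only where ``mask`` is True.
    """
    n, T = obs.shape
    x = np.empty(n)
    xn = np.empty(n)
    for i in range(n):
        x[i] = obs[i, 0]
        gene_out[i] = 0.0
    for t in range(1, T):
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += W[i, j] * x[j]
            xn[i] = s
        for i in range(n):
            x[i] = xn[i]
            if mask[i, t]:
                d = x[i] - obs[i, t]
                if obj_code == OBJ_CONTINUOUS:
                    gene_out[i] += d * d
                else:
                    b = back_bin(x[i], n_bins) - back_bin(obs[i, t], n_bins)
                    if b < 0:
                        b = -b
                    if d < 0.0:
                        d = -d
                    gene_out[i] += b * d
    total = 0.0
    for i in range(n):
        total += gene_out[i]
    return total


# ---------------------------------------------------------------------------
# gene-level operators
# ---------------------------------------------------------------------------


@njit(cache=True)
def blend_gene(row_b, row_c, beta, fidx, fcnt):
    """Replace the free entries of a gene pair by their beta-weighted
    averages (beta*B + (1-beta)*C and the mirror image).  Fixed entries are
    never touched."""
    for m in range(fcnt):
        j = fidx[m]
        b = row_b[j]
        c = row_c[j]
        row_b[j] = beta * b + (1.0 - beta) * c
        row_c[j] = (1.0 - beta) * b + beta * c


@njit(cache=True)
def crossover_gene(row, fidx, fcnt, rng):
    """Uniform random permutation (Fisher-Yates) of the free entries of a
    gene; fixed entries and the row sum are preserved exactly."""
    for m in range(fcnt - 1, 0, -1):
        r = rng.integers(0, m + 1)
        ja = fidx[m]
        jb = fidx[r]
        tmp = row[ja]
        row[ja] = row[jb]
        row[jb] = tmp


@njit(cache=True)
def mutate_gene(row, fidx, fcnt, wfixed, sel, eps):
    """Perturb one free weight of a gene by ``eps`` and renormalise.

    The selected weight becomes ``w* = w + eps`` subject to:
      * ``w* < 0``            -> ``w*`` set to 0;
      * ``w* > 1 - wfixed``   -> ``w*`` set to ``1 - wfixed`` and every
        other free weight set to 0;
      * original ``w == 1 - wfixed`` (the rest of the row is 0, so a
        multiplicative rescale is undefined) -> the excess
        ``1 - wfixed - w*`` is spread evenly over the other free weights;
      * otherwise the other free weights are rescaled by
        ``(1 - wfixed - w*)/(1 - wfixed - w)`` so the row sums to 1.

    A gene with no free entries is left untouched; with a single free entry
    the weight must stay at ``1 - wfixed``.
    """
    if fcnt == 0:
        return
    cap = 1.0 - wfixed
    j = fidx[sel]
    if fcnt == 1:
        row[j] = cap
        return
    w = row[j]
    wstar = w + eps
    if wstar < 0.0:
        wstar = 0.0
    if wstar > cap:
        for m in range(fcnt):
            row[fidx[m]] = 0.0
        row[j] = cap
        return
    # the other free weights sum to cap - w in exact arithmetic; rescaling
    # against their actual float sum keeps the row sum exact even when
    # cap - w is tiny and the scale factor large
    others = 0.0
    for m in range(fcnt):
        if m != sel:
            others += row[fidx[m]]
    if w > cap - 1e-12 or others <= 0.0:
        share = (cap - wstar) / (fcnt - 1)
        for m in range(fcnt):
            row[fidx[m]] = share
        row[j] = wstar
    else:
        scale = (cap - wstar) / others
        for m in range(fcnt):
            row[fidx[m]] *= scale
        row[j] = wstar


# ---------------------------------------------------------------------------
# gene swapping
# ---------------------------------------------------------------------------


@njit(cache=True)
def elite_gene_swap(pop, gene, totals, e, obs, mask, obj_code, n_bins):
    """Swap genes into the best chromosome from chromosomes holding fitter
    genes, en bloc.

    For each gene i the donor is the chromosome whose gene i has the
    smallest objective value in its own context, provided it is strictly
    below the elite's (ties broken by lowest index).  The elite's old genes
    move to the donors ("swapped between").  All swaps are retained iff the
    modified elite has a strictly lower total objective; otherwise every
    chromosome is restored.  Returns True when swaps were retained.
    """
    P = pop.shape[0]
    n = pop.shape[1]
    donor = np.full(n, -1, dtype=np.int64)
    any_swap = False
    for i in range(n):
        best = gene[e, i]
        for k in range(P):
            if k == e:
                continue
            if gene[k, i] < best:
                best = gene[k, i]
                donor[i] = k
        if donor[i] >= 0:
            any_swap = True
    if not any_swap:
        return False
    orig_elite = pop[e].copy()
    for i in range(n):
        d = donor[i]
        if d >= 0:
            for j in range(n):
                pop[e, i, j] = pop[d, i, j]
    new_gene = np.empty(n)
    new_total = evaluate(pop[e], obs, mask, obj_code, n_bins, new_gene)
    if new_total < totals[e]:
        for i in range(n):
            d = donor[i]
            if d >= 0:
                for j in range(n):
                    pop[d, i, j] = orig_elite[i, j]
        # re-evaluate every distinct donor in its modified form
        for k in range(P):
            touched = False
            for i in range(n):
                if donor[i] == k:
                    touched = True
            if touched:
                totals[k] = evaluate(pop[k], obs, mask, obj_code, n_bins, gene[k])
        totals[e] = new_total
        for i in range(n):
            gene[e, i] = new_gene[i]
        return True
    for i in range(n):
        for j in range(n):
            pop[e, i, j] = orig_elite[i, j]
    return False


@njit(cache=True)
def pairwise_gene_swap(ret_W, ret_gene, ret_total, rej_W, rej_gene,
                       obs, mask, obj_code, n_bins):
    """Gene swapping between a retained chromosome and its rejected
    counterpart (the survival step's second phase).

    Genes of the rejected chromosome with strictly lower gene objectives
    replace the retained chromosome's genes; all swaps are kept iff the
    modified chromosome improves strictly, else it is restored.  The
    rejected chromosome is discarded afterwards, so only the retained side
    is updated.  Returns the (possibly improved) total objective.
    """
    n = ret_W.shape[0]
    any_swap = False
    for i in range(n):
        if rej_gene[i] < ret_gene[i]:
            any_swap = True
    if not any_swap:
        return ret_total
    orig = ret_W.copy()
    for i in range(n):
        if rej_gene[i] < ret_gene[i]:
            for j in range(n):
                ret_W[i, j] = rej_W[i, j]
    new_gene = np.empty(n)
    new_total = evaluate(ret_W, obs, mask, obj_code, n_bins, new_gene)
    if new_total < ret_total:
        for i in range(n):
            ret_gene[i] = new_gene[i]
        return new_total
    for i in range(n):
        for j in range(n):
            ret_W[i, j] = orig[i, j]
    return ret_total


# ---------------------------------------------------------------------------
# driver loop
# ---------------------------------------------------------------------------

# adaptation event codes
ADAPT_PB = 0
ADAPT_PC = 1
ADAPT_PM = 2
ADAPT_SIGMA = 3
ADAPT_REINTRODUCE = 4


@njit(cache=True)
def ga_fit(pop, obs, mask, free_idx, free_cnt, wfixed, diag_chrom,
           obj_code, n_bins,
           pb0, factorb, maxb, iterb,
           pc0, factorc, minc, iterc,
           pm0, factorm, minm, iterm,
           sig0, factors_, mins_, iters_,
           max_iter, min_improve, min_dev, reint_elite, iterr,
           rng):
    """Full GA run on a pre-initialised population.  Returns the best
    weight matrix and objective plus the improvement and adaptation
    histories and the final adapted hyperparameter values.

    Iteration order: identify elite -> elite gene swap against all others
    -> pair and blend non-elite offspring -> crossover -> mutation ->
    survival with pairwise gene swap -> hyperparameter adaptation, with the
    reintroduction check last.
    """
    P, n, _ = pop.shape
    gene = np.empty((P, n))
    totals = np.empty(P)
    for k in range(P):
        totals[k] = evaluate(pop[k], obs, mask, obj_code, n_bins, gene[k])

    imp_iters = np.empty(max_iter + 2, dtype=np.int64)
    imp_vals = np.empty(max_iter + 2)
    min_gap = iterb
    if iterc < min_gap:
        min_gap = iterc
    if iterm < min_gap:
        min_gap = iterm
    if iters_ < min_gap:
        min_gap = iters_
    if min_gap < 1:
        min_gap = 1
    rr = iterr if iterr >= 1 else 1
    n_adapt_max = 4 * (max_iter // min_gap) + (max_iter // rr) + 8
    adapt_iters = np.empty(n_adapt_max, dtype=np.int64)
    adapt_codes = np.empty(n_adapt_max, dtype=np.int64)
    adapt_vals = np.empty(n_adapt_max)

    best_overall = totals[0]
    for k in range(1, P):
        if totals[k] < best_overall:
            best_overall = totals[k]
    n_imp = 0
    imp_iters[n_imp] = 0
    imp_vals[n_imp] = best_overall
    n_imp += 1
    n_adapt = 0

    pb = pb0
    pc = pc0
    pm = pm0
    sig = sig0
    cb = 0
    cc = 0
    cm = 0
    cs = 0
    cr = 0

    nonelite = np.empty(P - 1, dtype=np.int64)
    perm = np.empty(P - 1, dtype=np.int64)
    off = np.empty((P - 1, n, n))
    off_gene = np.empty((P - 1, n))
    off_tot = np.empty(P - 1)

    it = 0
    while it < max_iter and best_overall > min_dev:
        it += 1

        # --- elite identification (ties -> lowest index) and gene swap
        e = 0
        for k in range(1, P):
            if totals[k] < totals[e]:
                e = k
        elite_gene_swap(pop, gene, totals, e, obs, mask, obj_code, n_bins)

        m = 0
        for k in range(P):
            if k != e:
                nonelite[m] = k
                m += 1

        # --- offspring copies of the non-elite chromosomes
        for kk in range(P - 1):
            k = nonelite[kk]
            for i in range(n):
                for j in range(n):
                    off[kk, i, j] = pop[k, i, j]

        # --- blending over a random pairing; odd leftover sits out
        for q in range(P - 1):
            perm[q] = q
        for q in range(P - 2, 0, -1):
            r = rng.integers(0, q + 1)
            tmp = perm[q]
            perm[q] = perm[r]
            perm[r] = tmp
        n_pairs = (P - 1) // 2
        for q in range(n_pairs):
            a = perm[2 * q]
            b = perm[2 * q + 1]
            for i in range(n):
                if free_cnt[i] > 0 and rng.random() < pb:
                    beta = rng.random()
                    blend_gene(off[a, i], off[b, i], beta,
                               free_idx[i], free_cnt[i])

        # --- crossover and mutation, gene by gene
        for kk in range(P - 1):
            for i in range(n):
                if free_cnt[i] > 1 and rng.random() < pc:
                    crossover_gene(off[kk, i], free_idx[i], free_cnt[i], rng)
            for i in range(n):
                if free_cnt[i] > 1 and rng.random() < pm:
                    sel = rng.integers(0, free_cnt[i])
                    eps = rng.normal(0.0, sig)
                    mutate_gene(off[kk, i], free_idx[i], free_cnt[i],
                                wfixed[i], sel, eps)

        # --- survival: keep the fitter of each parent/offspring pair
        #     (ties keep the parent), then pairwise gene swap with the
        #     rejected counterpart
        for kk in range(P - 1):
            k = nonelite[kk]
            off_tot[kk] = evaluate(off[kk], obs, mask, obj_code, n_bins,
                                   off_gene[kk])
            if off_tot[kk] < totals[k]:
                new_total = pairwise_gene_swap(
                    off[kk], off_gene[kk], off_tot[kk], pop[k], gene[k],
                    obs, mask, obj_code, n_bins)
                for i in range(n):
                    gene[k, i] = off_gene[kk, i]
                    for j in range(n):
                        pop[k, i, j] = off[kk, i, j]
                totals[k] = new_total
            else:
                totals[k] = pairwise_gene_swap(
                    pop[k], gene[k], totals[k], off[kk], off_gene[kk],
                    obs, mask, obj_code, n_bins)

        # --- improvement bookkeeping and hyperparameter adaptation
        nb = totals[0]
        for k in range(1, P):
            if totals[k] < nb:
                nb = totals[k]
        if best_overall - nb > min_improve:
            best_overall = nb
            imp_iters[n_imp] = it
            imp_vals[n_imp] = nb
            n_imp += 1
            cb = 0
            cc = 0
            cm = 0
            cs = 0
            cr = 0
        else:
            cb += 1
            cc += 1
            cm += 1
            cs += 1
            cr += 1
            if cb >= iterb:
                pb = min(pb * factorb, maxb)
                cb = 0
                adapt_iters[n_adapt] = it
                adapt_codes[n_adapt] = ADAPT_PB
                adapt_vals[n_adapt] = pb
                n_adapt += 1
            if cc >= iterc:
                pc = max(pc * factorc, minc)
                cc = 0
                adapt_iters[n_adapt] = it
                adapt_codes[n_adapt] = ADAPT_PC
                adapt_vals[n_adapt] = pc
                n_adapt += 1
            if cm >= iterm:
                pm = max(pm * factorm, minm)
                cm = 0
                adapt_iters[n_adapt] = it
                adapt_codes[n_adapt] = ADAPT_PM
                adapt_vals[n_adapt] = pm
                n_adapt += 1
            if cs >= iters_:
                sig = max(sig * factors_, mins_)
                cs = 0
                adapt_iters[n_adapt] = it
                adapt_codes[n_adapt] = ADAPT_SIGMA
                adapt_vals[n_adapt] = sig
                n_adapt += 1
            if cr >= iterr:
                worst = 0
                for k in range(1, P):
                    if totals[k] > totals[worst]:
                        worst = k
                if reint_elite:
                    src = 0
                    for k in range(1, P):
                        if totals[k] < totals[src]:
                            src = k
                    if src != worst:
                        for i in range(n):
                            gene[worst, i] = gene[src, i]
                            for j in range(n):
                                pop[worst, i, j] = pop[src, i, j]
                        totals[worst] = totals[src]
                else:
                    for i in range(n):
                        for j in range(n):
                            pop[worst, i, j] = diag_chrom[i, j]
                    totals[worst] = evaluate(pop[worst], obs, mask, obj_code,
                                             n_bins, gene[worst])
                cr = 0
                adapt_iters[n_adapt] = it
                adapt_codes[n_adapt] = ADAPT_REINTRODUCE
                adapt_vals[n_adapt] = totals[worst]
                n_adapt += 1

    best = 0
    for k in range(1, P):
        if totals[k] < totals[best]:
            best = k
    return (pop[best].copy(), totals[best], gene[best].copy(), it,
            imp_iters[:n_imp].copy(), imp_vals[:n_imp].copy(),
            adapt_iters[:n_adapt].copy(), adapt_codes[:n_adapt].copy(),
            adapt_vals[:n_adapt].copy(), pb, pc, pm, sig)
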