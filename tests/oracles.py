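"""Independent brute-force oracles used by multiple test modules.

These deliberately re-derive each quantity from first principles with plain
loops so they share no code path with the package implementations.
"""

import numpy as np

from admixbreed.containers import MISSING


def wc_theta_site(calls_by_pop):
    """Weir & Cockerham (1984) per-site theta for r populations, two alleles.

    ``calls_by_pop``: list of 1-D arrays of diploid calls (0/1/2, -1 missing).
    Returns (a, b, c) variance components; theta = a / (a + b + c).
    """
    r = len(calls_by_pop)
    n = []
    p = []
    h = []
    for calls in calls_by_pop:
        called = [c for c in calls if c != MISSING]
        ni = len(called)
        if ni < 1:
            return np.nan, np.nan, np.nan
        n.append(ni)
        p.append(sum(called) / (2 * ni))
        h.append(sum(1 for c in called if c == 1) / ni)
    n = np.array(n, float)
    p = np.array(p, float)
    h = np.array(h, float)
    nbar = n.mean()
    if nbar <= 1:
        return np.nan, np.nan, np.nan
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def roh_scan_oracle(pos, calls, min_snps, min_kb, max_het, max_missing,
                    max_gap_kb):
    """Plain re-implementation of the declared greedy ROH scan contract."""
    runs = []
    n = len(pos)
    i = 0
    while i < n:
        if calls[i] not in (0, 2):
            i += 1
            continue
        j = i
        het = miss = 0
        while j + 1 < n:
            c = calls[j + 1]
            if pos[j + 1] - pos[j] > max_gap_kb * 1000:
                break
            if c == 1 and het == max_het:
                break
            if c == MISSING and miss == max_missing:
                break
            j += 1
            het += c == 1
            miss += c == MISSING
        lo, hi = i, j
        while lo <= hi and calls[lo] not in (0, 2):
            lo += 1
        while hi >= lo and calls[hi] not in (0, 2):
            hi -= 1
        if lo <= hi:
            n_snps = hi - lo + 1
            if n_snps >= min_snps and pos[hi] - pos[lo] >= min_kb * 1000:
                runs.append((int(pos[lo]), int(pos[hi])))
        i = j + 1
    return runs


def gene_drop_kinship(ped, n_loci, seed):
    """Monte-Carlo kinship by dropping unique founder alleles down a pedigree.

    Returns dict id -> (allele array pair); kinship estimated by the caller.
    """
    rng = np.random.default_rng(seed)
    alleles = {}
    next_allele = 0
    for id_ in ped.topological_order():
        rec = ped.record(id_)
        if rec.sire is None:
            alleles[id_] = (np.full(n_loci, next_allele),
                            np.full(n_loci, next_allele + 1))
            next_allele += 2
        else:
            a = np.where(rng.random(n_loci) < 0.5, *alleles[rec.sire])
            b = np.where(rng.random(n_loci) < 0.5, *alleles[rec.dam])
            alleles[id_] = (a, b)
    return alleles


def kinship_from_drop(alleles, i, j):
    ai, bi = alleles[i]
    aj, bj = alleles[j]
    return float(np.mean([(ai == aj), (ai == bj), (bi == aj), (bi == bj)]))
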