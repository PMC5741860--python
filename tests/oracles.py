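"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own recursions: the HMM oracle sums
over every state sequence explicitly, and the pedigree oracle counts
inbreeding paths through common ancestors.  They are only feasible on tiny
instances, which is the point.
"""

import itertools

import numpy as np

from hbdmix import hmm


def enumerate_decoding(model, codes, mmap, freqs):
    """Posterior, log-likelihood and best path by exhaustive enumeration of
    all K^T state sequences (chromosomes handled independently)."""
    K = model.K
    T = mmap.n_markers
    post = np.zeros((T, K))
    total_ll = 0.0
    best_path = np.empty(T, dtype=int)
    for sl in mmap.chromosome_slices():
        em = hmm.emission_matrix(model, codes[sl], freqs[sl])
        d = mmap.distances(sl)
        A = [hmm.transition_matrix(model, dd) for dd in d]
        n = sl.stop - sl.start
        tot = 0.0
        sub_post = np.zeros((n, K))
        best_p, best = -1.0, None
        for path in itertools.product(range(K), repeat=n):
            p = model.mixing[path[0]] * em[0, path[0]]
            for t in range(1, n):
                p *= A[t - 1][path[t - 1], path[t]] * em[t, path[t]]
            tot += p
            for t, s in enumerate(path):
                sub_post[t, s] += p
            if p > best_p:  # strict: lexicographically-first path wins ties
                best_p, best = p, path
        post[sl] = sub_post / tot
        total_ll += np.log(tot)
        best_path[sl] = best
    return post, total_ll, best_path


def path_counting_inbreeding(parents: dict):
    """Wright's path-counting inbreeding coefficients.

    ``parents`` maps individual -> (sire or None, dam or None).  F(X) is the
    sum over common ancestors A of the sire and dam, and over all
    non-overlapping ancestor paths sire<-..<-A->..->dam, of
    (1/2)^(n1+n2+1) (1 + F_A).
    """

    def ancestor_paths(start, acc, path):
        """All (ancestor, path-node-set, length) walks up from ``start``."""
        acc.append((start, frozenset(path), len(path) - 1))
        s, d = parents.get(start, (None, None))
        for p in (s, d):
            if p is not None:
                ancestor_paths(p, acc, path + [p])
        return acc

    memo = {}

    def F(x):
        if x in memo:
            return memo[x]
        s, d = parents.get(x, (None, None))
        if s is None or d is None:
            memo[x] = 0.0
            return 0.0
        val = 0.0
        for anc_s, nodes_s, n1 in ancestor_paths(s, [], [s]):
            for anc_d, nodes_d, n2 in ancestor_paths(d, [], [d]):
                if anc_s != anc_d:
                    continue
                # paths may share only the common ancestor itself
                if (nodes_s & nodes_d) != frozenset([anc_s]):
                    continue
                val += 0.5 ** (n1 + n2 + 1) * (1.0 + F(anc_s))
        memo[x] = val
        return val

    return {x: F(x) for x in parents}


def sliding_window_flags(codes, window, max_het, max_missing, threshold):
    """Literal re-implementation of the window scan with explicit loops."""
    n = len(codes)
    w = min(window, n)
    hits = []
    for s in range(n - w + 1):
        win = codes[s:s + w]
        het = int(np.sum(win == 1))
        miss = int(np.sum(win == -1))
        hits.append(het <= max_het and miss <= max_missing)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        cover = [hits[s] for s in range(max(0, i - w + 1), min(i, n - w) + 1)]
        frac = sum(cover) / len(cover)
        flags[i] = frac >= threshold and codes[i] != 1
    return flags
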