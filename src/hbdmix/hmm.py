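"""Multi-class homozygosity-by-descent (HBD) mixture hidden Markov model.

An individual genome is modelled as a mosaic of segments from K classes:
K-1 HBD classes and one non-HBD class.  Segment lengths (Morgans) in class k
are exponential with rate R_k (R_k is approximately twice the number of
generations to the common ancestor), and each new segment's class is drawn
from mixing proportions m_k.  Between two markers separated by d Morgans the
transition probability is

    a(k, l) = exp(-R_k d) [k == l] + (1 - exp(-R_k d)) m_l,

i.e. the current segment survives with exponential survival and, on
termination, the next class is drawn from the mixing proportions
(self-transitions allowed).  Emissions: inside an HBD segment a marker with
allele-A frequency f is homozygous AA with probability f(1-eps), homozygous
BB with probability (1-f)(1-eps) and heterozygous with probability eps (a
genotyping-error term); in non-HBD segments genotypes follow Hardy-Weinberg
proportions.  With genotype probabilities (sequence data) emissions are
integrated over the three genotypes.

Model flavours
--------------
``1R``     one HBD + one non-HBD class sharing a single free rate.
``KR``     K classes, each with its own free rate.
``MixKR``  fixed dyadic rates 2^1 ... 2^(K-1) for the HBD classes and
           2^(K-1) for the non-HBD class; only mixing proportions are free.

Parameters are fitted per individual by EM (Baum-Welch for the mixing
proportions, bounded one-dimensional maximization of the expected
complete-data log-likelihood for free rates, constrained to [1, 8192]), and
the number of classes can be chosen by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from . import _kernels
from .data import MISSING, MarkerMap

RATE_BOUNDS = (1.0, 8192.0)


# ---------------------------------------------------------------------------
# model parameterization
# ---------------------------------------------------------------------------

@dataclass
class HbdModel:
    """Parameterization of the K-class mixture HMM.

    States 0 .. K-2 are HBD classes ordered by increasing rate; state K-1 is
    the single non-HBD class.
    """

    rates: np.ndarray          # (K,) exponential rates, Morgans^-1
    mixing: np.ndarray         # (K,) mixing proportions, sum to 1
    epsilon: float = 0.002     # P(heterozygous genotype | HBD)
    nonhbd_error: float = 0.0  # optional genotyping-error rate in non-HBD
    kind: str = "KR"           # "1R", "KR" or "MixKR"
    free_rates: np.ndarray = None   # (K,) bool; which rates EM may move
    free_mixing: bool = True
    shared_rate: bool = False  # 1R: both states share one free rate
    rate_bounds: tuple = RATE_BOUNDS

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=np.float64)
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        K = len(self.rates)
        if K < 2:
            raise ValueError("need at least one HBD and one non-HBD class")
        if len(self.mixing) != K:
            raise ValueError("rates and mixing must have equal length")
        if not np.isclose(self.mixing.sum(), 1.0, atol=1e-8):
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.mixing < 0):
            raise ValueError("mixing proportions must be non-negative")
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must be in [0, 1)")
        if self.free_rates is None:
            self.free_rates = np.zeros(K, dtype=bool)
        else:
            self.free_rates = np.asarray(self.free_rates, dtype=bool)

    @property
    def K(self) -> int:
        return len(self.rates)

    @property
    def nonhbd_state(self) -> int:
        return self.K - 1

    @property
    def hbd_states(self) -> np.ndarray:
        return np.arange(self.K - 1)

    @property
    def n_free_parameters(self) -> int:
        """Free parameters counted for BIC: free rates + (K-1) free mixing."""
        n_rates = 1 if self.shared_rate else int(self.free_rates.sum())
        n_mix = self.K - 1 if self.free_mixing else 0
        return n_rates + n_mix

    def copy(self) -> "HbdModel":
        return replace(
            self,
            rates=self.rates.copy(),
            mixing=self.mixing.copy(),
            free_rates=self.free_rates.copy(),
        )


def make_model(kind: str, K: int = 2, epsilon: float = 0.002,
               rates=None, mixing=None) -> HbdModel:
    """Build a 1R, KR or MixKR model with standard initialization.

    Mixing starts uniform.  Free rates start at the geometric midpoints of K
    equal log-width bins spanning the [1, 8192] bounds (staggered so that EM
    can separate the classes); MixKR rates are the fixed dyadic grid
    2, 4, ..., 2^(K-1) with the non-HBD class at 2^(K-1).
    """
    lo, hi = RATE_BOUNDS
    if kind == "1R":
        if K != 2:
            raise ValueError("1R model has exactly two states")
        r0 = np.sqrt(lo * hi)
        init_rates = np.array([r0, r0]) if rates is None else np.asarray(rates, float)
        model = HbdModel(
            rates=init_rates,
            mixing=np.full(2, 0.5) if mixing is None else np.asarray(mixing, float),
            epsilon=epsilon, kind="1R",
            free_rates=np.array([True, True]), shared_rate=True,
        )
    elif kind == "KR":
        if K < 2:
            raise ValueError("KR model needs K >= 2")
        if rates is None:
            edges = np.logspace(np.log10(lo), np.log10(hi), K + 1)
            init_rates = np.sqrt(edges[:-1] * edges[1:])
        else:
            init_rates = np.asarray(rates, float)
        model = HbdModel(
            rates=init_rates,
            mixing=np.full(K, 1.0 / K) if mixing is None else np.asarray(mixing, float),
            epsilon=epsilon, kind="KR", free_rates=np.ones(K, dtype=bool),
        )
    elif kind == "MixKR":
        if K < 2:
            raise ValueError("MixKR model needs K >= 2")
        if rates is None:
            if K > 14:
                raise ValueError(
                    "default dyadic grid supports K <= 14; pass custom rates"
                )
            init_rates = np.array([2.0 ** j for j in range(1, K)] + [2.0 ** (K - 1)])
        else:
            init_rates = np.asarray(rates, float)
        model = HbdModel(
            rates=init_rates,
            mixing=np.full(K, 1.0 / K) if mixing is None else np.asarray(mixing, float),
            epsilon=epsilon, kind="MixKR", free_rates=np.zeros(K, dtype=bool),
        )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return model


# ---------------------------------------------------------------------------
# emissions and transitions
# ---------------------------------------------------------------------------

def genotype_probs_given_state(hbd: bool, f_a, epsilon: float,
                               nonhbd_error: float = 0.0) -> np.ndarray:
    """P(genotype | state) for genotypes ordered by allele-A count (0,1,2).

    HBD: ((1-f)(1-eps), eps, f(1-eps)); non-HBD: Hardy-Weinberg
    ((1-f)^2, 2f(1-f), f^2), optionally blended with a uniform
    genotyping-error component ``nonhbd_error`` (off by default).
    ``f_a`` may be a scalar or vector.
    """
    f = np.asarray(f_a, dtype=np.float64)
    if hbd:
        return np.stack([(1.0 - f) * (1.0 - epsilon),
                         np.broadcast_to(epsilon, f.shape).astype(float),
                         f * (1.0 - epsilon)], axis=-1)
    hw = np.stack([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f ** 2], axis=-1)
    if nonhbd_error > 0.0:
        hw = (1.0 - nonhbd_error) * hw + nonhbd_error / 3.0
    return hw


def emission_probability(model: HbdModel, state: int, genotype, f_a: float) -> float:
    """Emission probability of one observation under one state.

    ``genotype`` is an allele-A count (0/1/2), ``MISSING``, or a length-3
    genotype-probability triple (integrated emission).
    """
    if not (0.0 <= f_a <= 1.0):
        raise ValueError("allele frequency must be in [0, 1]")
    hbd = state != model.nonhbd_state
    table = genotype_probs_given_state(hbd, f_a, model.epsilon,
                                       model.nonhbd_error)
    g = np.asarray(genotype)
    if g.ndim == 1 and g.size == 3:
        return float(np.dot(table, g))
    code = int(g)
    if code == MISSING:
        return 1.0
    if code not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {code}")
    return float(table[code])


def emission_matrix(model: HbdModel, codes: np.ndarray, freqs: np.ndarray,
                    genoprobs: np.ndarray | None = None) -> np.ndarray:
    """(T, K) emission matrix for one individual.

    Missing hard genotypes emit 1 under every state (the marker is
    uninformative).  All HBD classes share one emission distribution, so the
    matrix has at most two distinct columns.
    """
    T = len(freqs)
    K = model.K
    hbd_tab = genotype_probs_given_state(True, freqs, model.epsilon)    # (T,3)
    non_tab = genotype_probs_given_state(False, freqs, model.epsilon,
                                         model.nonhbd_error)            # (T,3)
    if genoprobs is not None:
        e_hbd = np.einsum("tg,tg->t", hbd_tab, genoprobs)
        e_non = np.einsum("tg,tg->t", non_tab, genoprobs)
    else:
        codes = np.asarray(codes)
        e_hbd = np.ones(T)
        e_non = np.ones(T)
        obs = codes != MISSING
        idx = codes[obs].astype(np.intp)
        rows = np.nonzero(obs)[0]
        e_hbd[rows] = hbd_tab[rows, idx]
        e_non[rows] = non_tab[rows, idx]
    em = np.empty((T, K))
    em[:, : K - 1] = e_hbd[:, None]
    em[:, K - 1] = e_non
    bad = np.nonzero(em.sum(axis=1) == 0.0)[0]
    if bad.size:
        raise ValueError(
            f"all emission probabilities are zero at marker index {bad[0]}"
        )
    return em


def transition_matrix(model: HbdModel, d: float) -> np.ndarray:
    """K x K transition matrix over a distance of d Morgans."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    stay = np.exp(-model.rates * d)
    A = (1.0 - stay)[:, None] * model.mixing[None, :]
    A[np.diag_indices(model.K)] += stay
    return A


# ---------------------------------------------------------------------------
# decoding containers
# ---------------------------------------------------------------------------

@dataclass
class HBDSegment:
    """A maximal run of one HBD class along the Viterbi path."""
    chromosome: str
    start_bp: int
    end_bp: int
    start_index: int
    end_index: int
    class_index: int
    n_markers: int
    length_bp: int
    length_morgans: float


@dataclass
class Decoding:
    """Posterior decoding (and optionally Viterbi output) for one individual."""
    posteriors: np.ndarray          # (T, K)
    loglik: float
    viterbi_path: np.ndarray | None = None
    segments: list = field(default_factory=list)
    n_obs: int = 0


class _Prepared:
    """Per-individual quantities that are constant across EM iterations:
    per-chromosome emission matrices and compressed inter-marker distances
    (unique distance values plus per-interval group indices)."""

    def __init__(self, model, codes, mmap, freqs, genoprobs):
        slices = list(mmap.chromosome_slices())
        d_parts = [mmap.distances(sl) for sl in slices]
        if d_parts and sum(len(d) for d in d_parts):
            concat = np.concatenate(d_parts)
            self.d_unique, inv = np.unique(concat, return_inverse=True)
        else:
            self.d_unique, inv = np.zeros(1), np.zeros(0, dtype=np.int64)
        self.n_groups = len(self.d_unique)
        self.chunks = []
        offset = 0
        for sl, d in zip(slices, d_parts):
            em = emission_matrix(
                model,
                None if codes is None else codes[sl],
                freqs[sl],
                None if genoprobs is None else genoprobs[sl],
            )
            group = np.ascontiguousarray(inv[offset:offset + len(d)], dtype=np.int64)
            offset += len(d)
            self.chunks.append((sl, em, group))

    def survival(self, model) -> np.ndarray:
        """(n_unique, K) survival probabilities exp(-R_k d) per unique d."""
        return np.exp(-np.outer(self.d_unique, model.rates))


def count_observed(codes: np.ndarray | None, genoprobs=None) -> int:
    """Markers contributing information: non-missing hard calls, or all
    markers when only genotype probabilities are available."""
    if codes is not None:
        return int(np.sum(np.asarray(codes) != MISSING))
    return 0 if genoprobs is None else len(genoprobs)


def forward_backward(model: HbdModel, codes, mmap: MarkerMap, freqs,
                     genoprobs=None, _prep: "_Prepared | None" = None) -> Decoding:
    """Posterior state probabilities and total log-likelihood.

    Chromosomes are independent: each chain restarts from the mixing
    proportions, and the log-likelihood is summed over chromosomes.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    prep = _prep or _Prepared(model, codes, mmap, freqs, genoprobs)
    su = prep.survival(model)
    T = len(freqs)
    post = np.empty((T, model.K))
    loglik = 0.0
    for sl, em, group in prep.chunks:
        alpha, c = _kernels.forward(em, su, group, model.mixing)
        if np.any(c <= 0.0):
            bad = int(np.nonzero(c <= 0.0)[0][0])
            raise ValueError(f"zero forward probability at marker index {sl.start + bad}")
        beta = _kernels.backward(em, su, group, model.mixing, c)
        g = alpha * beta
        g /= g.sum(axis=1, keepdims=True)
        post[sl] = g
        loglik += float(np.log(c).sum())
    return Decoding(posteriors=post, loglik=loglik,
                    n_obs=count_observed(codes, genoprobs))


def viterbi(model: HbdModel, codes, mmap: MarkerMap, freqs,
            genoprobs=None) -> np.ndarray:
    """Most probable state path (per chromosome; ties -> lowest state index)."""
    freqs = np.asarray(freqs, dtype=np.float64)
    prep = _Prepared(model, codes, mmap, freqs, genoprobs)
    su = prep.survival(model)
    path = np.empty(len(freqs), dtype=np.int64)
    for sl, em, group in prep.chunks:
        with np.errstate(divide="ignore"):
            log_em = np.log(em)
        p, _ = _kernels.viterbi(log_em, su, group, model.mixing)
        path[sl] = p
    return path


def decode_segments(path: np.ndarray, mmap: MarkerMap, model: HbdModel,
                    chromosome_filter=None) -> list[HBDSegment]:
    """Maximal runs of a single HBD class along a state path.

    Segment bp bounds are the first and last marker positions of the run;
    length_bp = end - start + 1 (inclusive coordinates).
    """
    segments: list[HBDSegment] = []
    for sl in mmap.chromosome_slices():
        chrom = mmap.chrom[sl.start]
        if chromosome_filter is not None and chrom not in chromosome_filter:
            continue
        sub = path[sl]
        n = len(sub)
        i = 0
        while i < n:
            state = sub[i]
            j = i
            while j + 1 < n and sub[j + 1] == state:
                j += 1
            if state != model.nonhbd_state:
                gi, gj = sl.start + i, sl.start + j
                segments.append(HBDSegment(
                    chromosome=chrom,
                    start_bp=int(mmap.bp[gi]),
                    end_bp=int(mmap.bp[gj]),
                    start_index=gi,
                    end_index=gj,
                    class_index=int(state),
                    n_markers=j - i + 1,
                    length_bp=int(mmap.bp[gj] - mmap.bp[gi] + 1),
                    length_morgans=float(mmap.morgans[gj] - mmap.morgans[gi]),
                ))
            i = j + 1
    return segments


def decode(model: HbdModel, codes, mmap: MarkerMap, freqs,
           genoprobs=None) -> Decoding:
    """Forward-backward posteriors plus Viterbi path and HBD segments."""
    dec = forward_backward(model, codes, mmap, freqs, genoprobs)
    dec.viterbi_path = viterbi(model, codes, mmap, freqs, genoprobs)
    dec.segments = decode_segments(dec.viterbi_path, mmap, model)
    return dec


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _e_step_stats(model, prep: _Prepared):
    """One E-step sweep over all chromosomes.

    Returns (loglik, entries, stay_w, jump_w): ``entries[l]`` is the
    expected number of segment entries into class l (chromosome starts
    included); ``stay_w``/``jump_w`` are (n_unique_distances, K) expected
    stay/jump counts per unique inter-marker distance, the sufficient
    statistics for the rate M-step.
    """
    K = model.K
    su = prep.survival(model)
    loglik = 0.0
    entries = np.zeros(K)
    stay_w = np.zeros((prep.n_groups, K))
    jump_w = np.zeros((prep.n_groups, K))
    for sl, em, group in prep.chunks:
        bad, ll, post0, ent, sw, jw = _kernels.em_sweep(
            em, su, group, model.mixing, prep.n_groups
        )
        if bad >= 0:
            raise ValueError(f"zero forward probability at marker index {sl.start + bad}")
        loglik += ll
        entries += ent + post0   # chromosome start draws its class from mixing
        stay_w += sw
        jump_w += jw
    return loglik, entries, stay_w, jump_w


def _rate_q(R, states, d_unique, stay_w, jump_w):
    """Expected complete-data log-likelihood terms that depend on rate R,
    summed over the given states (more than one only for the shared 1R rate)."""
    with np.errstate(divide="ignore"):
        log_term = np.log1p(-np.exp(-R * d_unique))
    q = 0.0
    for k in states:
        q += -R * float(d_unique @ stay_w[:, k]) + float(jump_w[:, k] @ log_term)
    return q


def _maximize_rate(states, d_unique, stay_w, jump_w, bounds, current):
    """Bounded 1-D maximization of the rate term; never worse than current."""
    res = minimize_scalar(
        lambda R: -_rate_q(R, states, d_unique, stay_w, jump_w),
        bounds=bounds, method="bounded", options={"xatol": 1e-4},
    )
    cand = float(np.clip(res.x, *bounds))
    if _rate_q(cand, states, d_unique, stay_w, jump_w) >= _rate_q(
        current, states, d_unique, stay_w, jump_w
    ):
        return cand
    return current


def em_fit(model: HbdModel, codes, mmap: MarkerMap, freqs, genoprobs=None,
           n_iter: int = 1000, tol: float | None = None):
    """Fit free parameters of ``model`` to one individual by EM.

    Mixing proportions are updated from expected segment-entry counts
    (Baum-Welch); each free rate by bounded maximization of the expected
    complete-data log-likelihood, clamped to [1, 8192].  Stops after
    ``n_iter`` iterations or when the log-likelihood improves by less than
    ``tol`` (if given).  Returns ``(fitted_model, loglik_trace)`` where the
    trace holds the log-likelihood evaluated at the start of each iteration
    plus a final value at the fitted parameters.
    """
    if not (model.free_mixing or model.free_rates.any()):
        raise ValueError("model has no free parameters to fit")
    freqs = np.asarray(freqs, dtype=np.float64)
    m = model.copy()
    trace: list[float] = []
    lo, hi = m.rate_bounds
    m.rates = np.clip(m.rates, lo, hi)
    prep = _Prepared(m, codes, mmap, freqs, genoprobs)
    d_unique = prep.d_unique
    for it in range(n_iter):
        try:
            loglik, entries, stay_w, jump_w = _e_step_stats(m, prep)
        except ValueError as err:
            raise FloatingPointError(f"{err} (EM iteration {it})") from err
        if not np.isfinite(loglik):
            raise FloatingPointError(f"non-finite log-likelihood at EM iteration {it}")
        trace.append(loglik)
        if tol is not None and it > 0 and trace[-1] - trace[-2] < tol:
            break
        if m.free_mixing:
            total = entries.sum()
            if total > 0:
                m.mixing = entries / total
        if m.shared_rate:
            r = _maximize_rate(range(m.K), d_unique, stay_w, jump_w,
                               (lo, hi), m.rates[0])
            m.rates = np.full(m.K, r)
        else:
            for k in np.nonzero(m.free_rates)[0]:
                m.rates[k] = _maximize_rate([k], d_unique, stay_w, jump_w,
                                            (lo, hi), m.rates[k])
    final = forward_backward(m, codes, mmap, freqs, genoprobs, _prep=prep).loglik
    trace.append(final)
    return m, np.asarray(trace)


def bic(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, -2 logL + p ln(n)."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return -2.0 * loglik + n_params * np.log(n_obs)


def bic_select(candidates, n_obs: int):
    """Pick the best of several fitted models by BIC.

    ``candidates`` is a sequence of (model, loglik) pairs fitted on the same
    data; ``n_obs`` is the number of non-missing marker observations.
    Smallest BIC wins; ties break to the model with fewer free parameters.
    Returns (best_model, best_loglik, bics).
    """
    if not candidates:
        raise ValueError("no candidate models")
    scores = [bic(ll, mod.n_free_parameters, n_obs) for mod, ll in candidates]
    order = sorted(
        range(len(candidates)),
        key=lambda i: (scores[i], candidates[i][0].n_free_parameters),
    )
    best = order[0]
    return candidates[best][0], candidates[best][1], np.asarray(scores)
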