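"""Reproducible simulation studies exercising the whole pipeline.

Each study simulates mosaic genomes under known conditions, runs the HMM
(and, where relevant, the classical estimators or the ROH caller) and
returns the measured quantities.  The studies dimension their cohorts after
the commercial-panel setting the package targets: an HD-like panel density
of 24,000 markers per Morgan (~600K SNPs on a ~25-Morgan genome), with
20x / 85x thinnings standing in for the 50K and LD arrays.

All randomness flows from a single seed argument.
"""

from __future__ import annotations

import numpy as np

from . import hmm, report, roh as roh_mod
from .data import MISSING
from .hmm import HbdModel
from .model import HbdMixtureModel
from .simulate import SimConfig, downsample_panel, simulate_frequencies, \
    simulate_map, simulate_mosaic

HD_MARKERS_PER_MORGAN = 24_000.0


def _spaced_config(model, morgans, markers_per_morgan, seed, n_chrom=1):
    return SimConfig(model=model, n_chromosomes=n_chrom,
                     chrom_length=morgans / n_chrom,
                     marker_spacing=1.0 / markers_per_morgan, seed=seed)


def _simulate_cohort(model, n_individuals, morgans, markers_per_morgan, seed,
                     n_chrom=1):
    cfg = _spaced_config(model, morgans, markers_per_morgan, seed,
                         n_chrom=n_chrom)
    mmap = simulate_map(cfg)
    freqs = simulate_frequencies(mmap.n_markers, 1.0, 1.0, 0.01, seed=seed + 1)
    geno, truth = simulate_mosaic(cfg, mmap, freqs, n_individuals, seed=seed + 2)
    return mmap, freqs, geno, truth


# ---------------------------------------------------------------------------
# decoding oracle agreement
# ---------------------------------------------------------------------------

def oracle_agreement(seed: int, n_instances: int = 200) -> dict:
    """Forward-backward and Viterbi vs exhaustive path enumeration on random
    tiny instances (<= 8 markers, K <= 3)."""
    import itertools

    from .data import MarkerMap

    rng = np.random.default_rng(seed)
    max_post_err = 0.0
    max_ll_err = 0.0
    viterbi_mismatches = 0
    for _ in range(n_instances):
        K = int(rng.integers(2, 4))
        T = int(rng.integers(2, 9))
        model = HbdModel(rates=np.sort(rng.uniform(2.0, 2000.0, K)),
                         mixing=rng.dirichlet(np.ones(K)),
                         epsilon=float(rng.uniform(0.0, 0.05)))
        spacing = float(rng.uniform(1e-4, 0.05))
        g = np.arange(T) * spacing
        mmap = MarkerMap(["1"] * T, (np.round(g / 1e-8) + 1).astype(int), g)
        freqs = rng.uniform(0.05, 0.95, T)
        codes = rng.integers(0, 3, T).astype(np.int8)
        codes[rng.random(T) < 0.1] = MISSING
        em = hmm.emission_matrix(model, codes, freqs)
        d = np.diff(g)
        A = [hmm.transition_matrix(model, dd) for dd in d]
        tot = 0.0
        post = np.zeros((T, K))
        best_p, best_path = -1.0, None
        for path in itertools.product(range(K), repeat=T):
            p = model.mixing[path[0]] * em[0, path[0]]
            for t in range(1, T):
                p *= A[t - 1][path[t - 1], path[t]] * em[t, path[t]]
            tot += p
            for t, s in enumerate(path):
                post[t, s] += p
            if p > best_p:
                best_p, best_path = p, path
        post /= tot
        dec = hmm.forward_backward(model, codes, mmap, freqs)
        max_post_err = max(max_post_err, float(np.abs(dec.posteriors - post).max()))
        max_ll_err = max(max_ll_err, abs(dec.loglik - np.log(tot)))
        vp = hmm.viterbi(model, codes, mmap, freqs)
        viterbi_mismatches += int(tuple(vp) != best_path)
    return {
        "n_instances": n_instances,
        "max_posterior_error": max_post_err,
        "max_loglik_error": max_ll_err,
        "viterbi_mismatches": viterbi_mismatches,
    }


# ---------------------------------------------------------------------------
# EM behaviour
# ---------------------------------------------------------------------------

def em_monotonicity(seed: int, n_iter: int = 1000) -> dict:
    """Full-length EM run on one simulated individual: log-likelihood steps
    and constraint respect for the fitted rates."""
    gen = HbdModel(rates=np.array([20.0, 20.0]), mixing=np.array([0.25, 0.75]),
                   epsilon=0.002, kind="1R")
    mmap, freqs, geno, _ = _simulate_cohort(gen, 1, 4.0, 1300.0, seed, n_chrom=4)
    m0 = hmm.make_model("KR", K=2, epsilon=0.002)
    m, trace = hmm.em_fit(m0, geno.codes[0], mmap, freqs, n_iter=n_iter, tol=None)
    steps = np.diff(trace[:-1])
    return {
        "n_iterations": int(len(trace) - 1),
        "min_loglik_step": float(steps.min()),
        "n_decreases_beyond_tol": int(np.sum(steps < -1e-8)),
        "rates_within_bounds": bool(np.all((m.rates >= 1.0) & (m.rates <= 8192.0))),
        "fitted_rates": [float(r) for r in m.rates],
    }


# ---------------------------------------------------------------------------
# parameter recovery (single recent HBD class)
# ---------------------------------------------------------------------------

def recovery_study(seed: int, n_individuals: int = 20, morgans: float = 10.0,
                   markers_per_morgan: float = HD_MARKERS_PER_MORGAN) -> dict:
    """1R and MixKR fits on a cohort simulated from a known one-HBD-class
    model (R = 20, stationary HBD fraction 0.25, epsilon = 0.002)."""
    gen = HbdModel(rates=np.array([20.0, 20.0]), mixing=np.array([0.25, 0.75]),
                   epsilon=0.002, kind="1R")
    mmap, freqs, geno, truth = _simulate_cohort(
        gen, n_individuals, morgans, markers_per_morgan, seed,
        n_chrom=max(1, int(round(morgans))))
    true_frac = truth.hbd_fraction()

    res_1r = HbdMixtureModel(geno, mmap, kind="1R", epsilon=0.002,
                             freqs=freqs).fit(tol=1e-4)
    rates_1r = res_1r.rates["R0"].to_numpy()
    fg_1r = res_1r.inbreeding().to_numpy()

    res_mix = HbdMixtureModel(geno, mmap, kind="MixKR", K=14, epsilon=0.002,
                              freqs=freqs).fit(tol=1e-3)
    fg_mix = res_mix.inbreeding().to_numpy()
    return {
        "n_individuals": n_individuals,
        "true_fraction_mean": float(true_frac.mean()),
        "median_rate_1r": float(np.median(rates_1r)),
        "fg_max_abs_error_1r": float(np.abs(fg_1r - true_frac).max()),
        "fg_mean_abs_error_1r": float(np.abs(fg_1r - true_frac).mean()),
        "mixkr_truth_correlation": float(np.corrcoef(fg_mix, true_frac)[0, 1]),
        "_cohort": (mmap, freqs, geno, truth),
        "_results_mix": res_mix,
        "_results_1r": res_1r,
    }


# ---------------------------------------------------------------------------
# age-based partitioning (two HBD classes)
# ---------------------------------------------------------------------------

def two_class_generator(recent_frac=0.10, ancient_frac=0.15,
                        recent_rate=10.0, ancient_rate=1000.0) -> HbdModel:
    """Generative truth with a recent and an ancient HBD class; mixing
    proportions are chosen so the stationary genome fractions equal the
    requested values (m_k proportional to fraction_k * R_k)."""
    non_frac = 1.0 - recent_frac - ancient_frac
    rates = np.array([recent_rate, ancient_rate, ancient_rate])
    weights = np.array([recent_frac, ancient_frac, non_frac]) * rates
    return HbdModel(rates=rates, mixing=weights / weights.sum(), epsilon=0.002)


def age_partition_study(seed: int, n_replicates: int = 20,
                        morgans: float = 2.0,
                        markers_per_morgan: float = HD_MARKERS_PER_MORGAN) -> dict:
    """Per replicate: one individual simulated with recent (R=10) and
    ancient (R=1000) HBD classes; MixKR decoding of the recent-segment mass
    and KR model choice by BIC (K=3 vs K=2)."""
    gen = two_class_generator()
    recent_mass_shares = []
    total_recent_mass = 0.0
    total_hbd_mass = 0.0
    k3_wins = 0
    for rep in range(n_replicates):
        s = seed + 1000 * rep
        mmap, freqs, geno, truth = _simulate_cohort(
            gen, 1, morgans, markers_per_morgan, s,
            n_chrom=max(1, int(round(morgans))))
        codes = geno.codes[0]
        # MixKR decoding: where is the posterior HBD mass inside true
        # recent segments?
        m_mix, _ = hmm.em_fit(hmm.make_model("MixKR", K=14, epsilon=0.002),
                              codes, mmap, freqs, tol=1e-3)
        dec = hmm.forward_backward(m_mix, codes, mmap, freqs)
        recent_markers = truth.marker_classes(mmap)[0] == 0
        post = dec.posteriors[recent_markers]
        hbd_mass = post[:, :13].sum()
        recent_classes = np.nonzero(m_mix.rates[:13] <= 32.0)[0]
        recent_mass = post[:, recent_classes].sum()
        total_recent_mass += recent_mass
        total_hbd_mass += hbd_mass
        if hbd_mass > 0:  # a short genome can draw no recent segment at all
            recent_mass_shares.append(recent_mass / hbd_mass)
        # BIC: 2-state vs 3-state KR fits
        fits = []
        for K in (2, 3):
            m, _ = hmm.em_fit(hmm.make_model("KR", K=K, epsilon=0.002),
                              codes, mmap, freqs, tol=1e-4)
            ll = hmm.forward_backward(m, codes, mmap, freqs).loglik
            fits.append((m, ll))
        n_obs = int(np.sum(codes != MISSING))
        best, _, _ = hmm.bic_select(fits, n_obs)
        k3_wins += best.K == 3
    return {
        "n_replicates": n_replicates,
        "recent_mass_share": total_recent_mass / total_hbd_mass,
        "recent_mass_share_mean": float(np.mean(recent_mass_shares)),
        "bic_prefers_k3_fraction": k3_wins / n_replicates,
    }


# ---------------------------------------------------------------------------
# marker-density behaviour
# ---------------------------------------------------------------------------

def age_structured_generator(
        classes=((4.0, 0.027), (32.0, 0.041), (256.0, 0.054), (2048.0, 0.180)),
) -> HbdModel:
    """Generative truth with several age classes, dimensioned after the
    pattern typical of an intensively selected cattle population: a small
    but highly variable very-recent component (few long segments per
    genome), and a large, stable ancient background of very short segments.
    ``classes`` lists (rate, stationary genome fraction) pairs; the non-HBD
    class takes the largest rate."""
    rates = np.array([r for r, _ in classes])
    fracs = np.array([f for _, f in classes])
    non_frac = 1.0 - fracs.sum()
    all_rates = np.append(rates, rates.max())
    weights = np.append(fracs, non_frac) * all_rates
    return HbdModel(rates=all_rates, mixing=weights / weights.sum(),
                    epsilon=0.002)


def mixkr_classes_for_spacing(spacing: float, max_k: int = 14) -> int:
    """Number of MixKR classes supported by a panel: the upper rate of the
    dyadic grid is capped at the largest power of two not exceeding
    1/spacing, since segments shorter than the marker spacing cannot be
    captured as segments."""
    cap = min(8192.0, 2.0 ** np.floor(np.log2(1.0 / spacing)))
    return min(max_k, int(np.log2(cap)) + 1)


def heterogeneous_cohort(n_individuals, morgans, markers_per_morgan, seed,
                         recent_span=0.10):
    """Cohort whose individuals differ in true recent inbreeding, as real
    cohorts do: each individual's very-recent (R=4) genome fraction is
    drawn uniformly on [0, ``recent_span``] (matching the spread of
    very-recent inbreeding coefficients reported in intensively selected
    cattle, where F for the most recent classes ranges from zero to ~0.14),
    on top of a shared recent/ancient background (R = 32, 256, 2048 with
    fractions 0.041, 0.054, 0.180)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    base = age_structured_generator()
    cfg = _spaced_config(base, morgans, markers_per_morgan, seed,
                         n_chrom=max(1, int(round(morgans))))
    mmap = simulate_map(cfg)
    freqs = simulate_frequencies(mmap.n_markers, 1.0, 1.0, 0.01, seed=seed + 1)
    codes = []
    fracs = []
    seg_tables = []
    individuals = []
    for i in range(n_individuals):
        u = float(rng.uniform(0.0, recent_span))
        gen_i = age_structured_generator(
            classes=((4.0, u), (32.0, 0.041), (256.0, 0.054), (2048.0, 0.180)))
        cfg_i = _spaced_config(gen_i, morgans, markers_per_morgan, seed,
                               n_chrom=max(1, int(round(morgans))))
        g_i, t_i = simulate_mosaic(cfg_i, mmap, freqs, 1,
                                   seed=int(rng.integers(2 ** 31)))
        name = f"ind{i + 1}"
        individuals.append(name)
        codes.append(g_i.codes[0])
        fracs.append(t_i.class_fractions[0])
        seg = t_i.segments.copy()
        seg["individual"] = name
        seg_tables.append(seg)
    from .data import GenotypeData
    from .simulate import SimTruth

    geno = GenotypeData(individuals, np.stack(codes), freqs=freqs)
    truth = SimTruth(segments=pd.concat(seg_tables, ignore_index=True),
                     class_fractions=np.stack(fracs),
                     individuals=individuals,
                     nonhbd_state=base.nonhbd_state)
    return mmap, freqs, geno, truth


def density_study(seed: int, n_individuals: int = 20, morgans: float = 10.0,
                  markers_per_morgan: float = HD_MARKERS_PER_MORGAN,
                  thinnings=(20, 85)) -> dict:
    """MixKR inbreeding on an HD-like panel vs 20x/85x thinned panels
    (mimicking 50K and LD arrays).

    The cohort carries autozygosity of four ages (rates 4 to 2048) with
    individually variable recent inbreeding (``heterogeneous_cohort``).
    Each panel is fitted with the dyadic class grid its density supports
    (``mixkr_classes_for_spacing``): thinning should lose the ancient,
    short-segment autozygosity while preserving the individual ranking and
    the recent-class coefficients F_G-32."""
    mmap, freqs, geno, truth = heterogeneous_cohort(
        n_individuals, morgans, markers_per_morgan, seed)

    def fit_panel(g, m):
        spacing = float(np.median(np.diff(m.morgans[:200])))
        K = mixkr_classes_for_spacing(spacing)
        res = HbdMixtureModel(g, m, kind="MixKR", K=K, epsilon=0.002,
                              freqs=g.freqs).fit(tol=1e-3)
        fg = res.inbreeding().to_numpy()
        fg32 = res.inbreeding(T=32.0).to_numpy()
        return fg, fg32, K

    fg_hd, fg32_hd, K_hd = fit_panel(geno, mmap)
    out = {
        "n_individuals": n_individuals,
        "fg_mean_hd": float(fg_hd.mean()),
        "true_fraction_mean": float(truth.hbd_fraction().mean()),
        "truth_correlation_hd": float(
            np.corrcoef(fg_hd, truth.hbd_fraction())[0, 1]),
        "classes_hd": K_hd,
    }
    for factor in thinnings:
        g_thin, m_thin = downsample_panel(geno, mmap, factor)
        fg, fg32, K = fit_panel(g_thin, m_thin)
        out[f"fg_mean_thin{factor}"] = float(fg.mean())
        out[f"fg_correlation_thin{factor}"] = float(np.corrcoef(fg, fg_hd)[0, 1])
        out[f"fg32_mean_abs_diff_thin{factor}"] = float(
            np.abs(fg32 - fg32_hd).mean())
        out[f"classes_thin{factor}"] = K
    return out


# ---------------------------------------------------------------------------
# pedigree estimator, exhaustive-style check
# ---------------------------------------------------------------------------

def enumerate_pedigrees(n_members: int):
    """All pedigrees on ``n_members`` topologically-labelled individuals:
    each member's sire and dam are independently unknown or any earlier
    member (excluding selfing).  F is invariant to which parent is called
    sire, so this covers every distinct pedigree shape up to relabelling."""
    def options(j):
        opts = [(None, None)]
        for s in range(j):
            opts.append((s, None))
            opts.append((None, s))
            for d in range(j):
                if d != s:
                    opts.append((s, d))
        return opts

    import itertools

    per_member = [options(j) for j in range(n_members)]
    for combo in itertools.product(*per_member):
        yield {j: combo[j] for j in range(n_members)}


def pedigree_estimator_check(max_members: int = 5) -> dict:
    """Tabular-kinship F_PED vs Wright path counting over the exhaustive
    pedigree enumeration (plus nothing random: the sweep is complete)."""
    from .data import Pedigree
    from .estimators import f_ped

    def path_counting(parents):
        def paths(x, acc, path):
            acc.append((x, frozenset(path), len(path) - 1))
            s, d = parents[x]
            for p in (s, d):
                if p is not None:
                    paths(p, acc, path + [p])
            return acc

        memo = {}

        def F(x):
            if x in memo:
                return memo[x]
            s, d = parents[x]
            if s is None or d is None:
                memo[x] = 0.0
                return 0.0
            val = 0.0
            for a_s, ns, n1 in paths(s, [], [s]):
                for a_d, nd, n2 in paths(d, [], [d]):
                    if a_s == a_d and (ns & nd) == frozenset([a_s]):
                        val += 0.5 ** (n1 + n2 + 1) * (1.0 + F(a_s))
            memo[x] = val
            return val

        return {x: F(x) for x in parents}

    n_checked = 0
    max_err = 0.0
    for n in range(1, max_members + 1):
        for parents in enumerate_pedigrees(n):
            # "0" is the unknown-parent code, so member j is named "p{j}"
            ped = Pedigree.from_tuples([
                (f"p{j}",
                 "0" if s is None else f"p{s}",
                 "0" if d is None else f"p{d}")
                for j, (s, d) in parents.items()])
            got = f_ped(ped)
            exp = path_counting(parents)
            for j in parents:
                max_err = max(max_err, abs(got[f"p{j}"] - exp[j]))
            n_checked += 1
    return {"n_pedigrees": n_checked, "max_abs_error": max_err}


# ---------------------------------------------------------------------------
# ROH vs truth
# ---------------------------------------------------------------------------

def roh_truth_correlation(cohort) -> dict:
    """F_ROH with the HD preset vs true HBD fraction on an HD-like cohort."""
    mmap, freqs, geno, truth = cohort
    table = roh_mod.find_roh(geno, mmap, "HD")
    f = roh_mod.f_roh(table, mmap.total_length_bp(),
                      individuals=geno.individuals).to_numpy()
    true_frac = truth.hbd_fraction()
    return {
        "n_individuals": geno.n_individuals,
        "froh_mean": float(f.mean()),
        "froh_truth_correlation": float(np.corrcoef(f, true_frac)[0, 1]),
    }


# ---------------------------------------------------------------------------
# report invariants
# ---------------------------------------------------------------------------

def report_invariants(results_mix) -> dict:
    """F_G-T monotonicity, class-fraction normalization and length-bin
    partitioning, measured on fitted MixKR results."""
    curve = results_mix.f_t_curve().to_numpy()
    monotone_violations = int(np.sum(np.diff(curve, axis=1) < -1e-12))
    cf = results_mix.class_fractions().to_numpy()
    max_norm_err = float(np.abs(cf.sum(axis=1) - 1.0).max())
    segs = results_mix.segments()
    table = report.segment_length_table(segs.to_dict("records"))

    # correlation of F_G-T with total F_G should not fall as T grows;
    # a threshold column without variance counts as zero correlation
    total = curve[:, -1]

    def corr_or_zero(col):
        if np.std(col) == 0.0 or np.std(total) == 0.0:
            return 0.0
        return float(np.corrcoef(col, total)[0, 1])

    return {
        "n_individuals": cf.shape[0],
        "ft_monotone_violations": monotone_violations,
        "class_fraction_norm_error": max_norm_err,
        "n_segments": int(len(segs)),
        "bins_partition_segments": bool(table.sum() == len(segs)),
        "corr_with_total_at_min_t": corr_or_zero(curve[:, 0]),
        "corr_with_total_at_max_t": corr_or_zero(total),
    }
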