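"""Core HMM: emissions, transitions, decoding vs brute force, EM, BIC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_small_model, uniform_map
from hbdmix import hmm, simulate as sim
from hbdmix.data import MISSING
from oracles import enumerate_decoding


class TestFactories:
    def test_mixkr_dyadic_rates(self):
        m = hmm.make_model("MixKR", K=14)
        np.testing.assert_allclose(m.rates[:13], [2.0 ** j for j in range(1, 14)])
        assert m.rates[13] == 2.0 ** 13          # non-HBD class shares 2^13
        assert not m.free_rates.any() and m.free_mixing
        assert m.n_free_parameters == 13

    def test_1r_shared_rate(self):
        m = hmm.make_model("1R")
        assert m.K == 2 and m.shared_rate
        assert m.rates[0] == m.rates[1]
        assert m.n_free_parameters == 2

    def test_kr_free_rates_within_bounds(self):
        m = hmm.make_model("KR", K=3)
        assert m.free_rates.all()
        assert np.all((m.rates >= 1.0) & (m.rates <= 8192.0))
        assert m.n_free_parameters == 2 * 3 - 1

    def test_mixkr_grid_limit(self):
        with pytest.raises(ValueError, match="K <= 14"):
            hmm.make_model("MixKR", K=15)
        m = hmm.make_model("MixKR", K=15, rates=np.geomspace(2, 8192, 15))
        assert m.K == 15


class TestEmissions:
    def test_hbd_formula(self):
        m = hmm.make_model("1R", epsilon=0.01)
        vals = [hmm.emission_probability(m, 0, g, 0.3) for g in (2, 1, 0)]
        np.testing.assert_allclose(vals, [0.297, 0.010, 0.693])

    def test_nonhbd_hardy_weinberg(self):
        m = hmm.make_model("1R", epsilon=0.01)
        vals = [hmm.emission_probability(m, 1, g, 0.5) for g in (2, 1, 0)]
        np.testing.assert_allclose(vals, [0.25, 0.5, 0.25])

    def test_missing_uninformative(self):
        m = hmm.make_model("MixKR", K=4)
        for state in range(4):
            assert hmm.emission_probability(m, state, MISSING, 0.3) == 1.0

    def test_uniform_genoprobs_flat(self):
        m = hmm.make_model("MixKR", K=4, epsilon=0.01)
        gp = np.array([1 / 3] * 3)
        for state in range(4):
            assert hmm.emission_probability(m, state, gp, 0.42) == pytest.approx(1 / 3)

    def test_nonhbd_error_switch(self):
        m = hmm.make_model("1R", epsilon=0.01)
        m.nonhbd_error = 0.3
        vals = np.array([hmm.emission_probability(m, 1, g, 0.5)
                         for g in (0, 1, 2)])
        expect = 0.7 * np.array([0.25, 0.5, 0.25]) + 0.1
        np.testing.assert_allclose(vals, expect)
        assert vals.sum() == pytest.approx(1.0)

    def test_genoprob_emission_matches_integration(self, rng):
        m = hmm.make_model("1R", epsilon=0.02)
        gp = rng.dirichlet(np.ones(3))
        f = 0.37
        for state in (0, 1):
            hard = [hmm.emission_probability(m, state, g, f) for g in (0, 1, 2)]
            assert hmm.emission_probability(m, state, gp, f) == pytest.approx(
                float(np.dot(gp, hard)))


class TestTransitions:
    def test_zero_distance_identity(self):
        m = hmm.make_model("MixKR", K=5)
        np.testing.assert_allclose(hmm.transition_matrix(m, 0.0), np.eye(5))

    def test_long_distance_reaches_mixing(self):
        m = hmm.HbdModel(rates=np.array([50.0, 10.0]),
                         mixing=np.array([0.3, 0.7]), epsilon=0.0)
        A = hmm.transition_matrix(m, 100.0)
        np.testing.assert_allclose(A, np.tile(m.mixing, (2, 1)), atol=1e-12)

    def test_scalar_example(self):
        m = hmm.HbdModel(rates=np.array([2.0, 2.0]),
                         mixing=np.array([0.5, 0.5]), epsilon=0.0)
        A = hmm.transition_matrix(m, 0.5)
        stay = np.exp(-1) + (1 - np.exp(-1)) * 0.5
        assert A[0, 0] == pytest.approx(stay, abs=1e-5)
        assert A[0, 1] == pytest.approx(1 - stay, abs=1e-5)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            hmm.transition_matrix(hmm.make_model("1R"), -0.1)

    @given(st.floats(min_value=0.0, max_value=10.0),
           st.integers(min_value=2, max_value=6),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_rows_stochastic(self, d, K, seed):
        m = random_small_model(np.random.default_rng(seed), K)
        A = hmm.transition_matrix(m, d)
        assert np.all(A >= 0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)


def _random_instance(rng, K=None, T=None, n_chrom=1):
    K = K or int(rng.integers(2, 4))
    T = T or int(rng.integers(2, 9))
    model = random_small_model(rng, K)
    mmap = uniform_map(T, spacing=float(rng.uniform(1e-4, 0.05)), n_chrom=n_chrom)
    freqs = rng.uniform(0.05, 0.95, mmap.n_markers)
    codes = rng.integers(0, 3, mmap.n_markers).astype(np.int8)
    codes[rng.random(mmap.n_markers) < 0.1] = MISSING
    return model, mmap, freqs, codes


class TestDecodingAgainstEnumeration:
    def test_single_marker_recovers_prior(self):
        m = hmm.make_model("MixKR", K=3)
        mmap = uniform_map(1)
        dec = hmm.forward_backward(m, np.array([MISSING], dtype=np.int8),
                                   mmap, np.array([0.5]))
        np.testing.assert_allclose(dec.posteriors[0], m.mixing)

    def test_posteriors_and_viterbi_match_brute_force(self, rng):
        for _ in range(40):
            model, mmap, freqs, codes = _random_instance(rng)
            post, ll, path = enumerate_decoding(model, codes, mmap, freqs)
            dec = hmm.forward_backward(model, codes, mmap, freqs)
            assert abs(dec.loglik - ll) < 1e-10
            assert np.abs(dec.posteriors - post).max() < 1e-10
            vp = hmm.viterbi(model, codes, mmap, freqs)
            np.testing.assert_array_equal(vp, path)

    def test_duplicate_chromosome_doubles_loglik(self, rng):
        model = random_small_model(rng, 3)
        mmap = uniform_map(6, spacing=0.01)
        freqs = rng.uniform(0.05, 0.95, 6)
        codes = rng.integers(0, 3, 6).astype(np.int8)
        dec1 = hmm.forward_backward(model, codes, mmap, freqs)
        mmap2 = uniform_map(6, spacing=0.01, n_chrom=2)
        codes2 = np.tile(codes, 2)
        freqs2 = np.tile(freqs, 2)
        dec2 = hmm.forward_backward(model, codes2, mmap2, freqs2)
        assert dec2.loglik == pytest.approx(2 * dec1.loglik, abs=1e-9)

    def test_zero_probability_column_raises(self):
        model = hmm.HbdModel(rates=np.array([10.0, 10.0]),
                             mixing=np.array([0.5, 0.5]), epsilon=0.0)
        codes = np.array([2, 1, 2], dtype=np.int8)
        freqs = np.array([0.5, 0.0, 0.5])  # het impossible: HBD eps=0, HWE f=0
        mmap = uniform_map(3)
        with pytest.raises(ValueError, match="marker index 1"):
            hmm.forward_backward(model, codes, mmap, freqs)

    def test_posterior_rows_normalized(self, rng):
        model, mmap, freqs, codes = _random_instance(rng, K=3, T=8)
        dec = hmm.forward_backward(model, codes, mmap, freqs)
        np.testing.assert_allclose(dec.posteriors.sum(axis=1), 1.0, atol=1e-9)


class TestViterbiSegments:
    def test_all_heterozygous_no_segments(self):
        model = hmm.make_model("1R", epsilon=0.002)
        mmap = uniform_map(30)
        codes = np.ones(30, dtype=np.int8)
        freqs = np.full(30, 0.5)
        path = hmm.viterbi(model, codes, mmap, freqs)
        assert np.all(path == model.nonhbd_state)
        assert hmm.decode_segments(path, mmap, model) == []

    def test_tie_breaks_to_lowest_state(self):
        # equal rates, equal mixing, all-missing data: every path equally
        # likely; the documented tie-break picks state 0 everywhere
        model = hmm.HbdModel(rates=np.array([10.0, 10.0, 10.0]),
                             mixing=np.array([1 / 3] * 3), epsilon=0.0)
        mmap = uniform_map(5)
        codes = np.full(5, MISSING, dtype=np.int8)
        path = hmm.viterbi(model, codes, mmap, np.full(5, 0.5))
        np.testing.assert_array_equal(path, 0)

    def test_segment_bounds_and_lengths(self):
        model = hmm.make_model("MixKR", K=3)
        mmap = uniform_map(10, spacing=0.01)
        path = np.array([2, 0, 0, 0, 2, 1, 1, 2, 2, 2])
        segs = hmm.decode_segments(path, mmap, model)
        assert len(segs) == 2
        s0, s1 = segs
        assert (s0.class_index, s0.n_markers) == (0, 3)
        assert s0.start_bp == mmap.bp[1] and s0.end_bp == mmap.bp[3]
        assert s0.length_bp == mmap.bp[3] - mmap.bp[1] + 1
        assert s0.length_morgans == pytest.approx(0.02)
        assert (s1.class_index, s1.n_markers) == (1, 2)


class TestEmFit:
    def _sim_1r(self, seed=0, n_markers=4000, rate=20.0, frac=0.25, eps=0.002):
        gen = hmm.HbdModel(rates=np.array([rate, rate]),
                           mixing=np.array([frac, 1 - frac]),
                           epsilon=eps, kind="1R")
        cfg = sim.SimConfig(model=gen, chrom_length=(n_markers - 1) * 0.001,
                            marker_spacing=0.001, seed=seed)
        mmap = sim.simulate_map(cfg)
        freqs = sim.simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=seed + 1)
        geno, truth = sim.simulate_mosaic(cfg, mmap, freqs, 1, seed=seed + 2)
        return gen, mmap, freqs, geno, truth

    def test_monotone_loglik_and_bounds(self):
        gen, mmap, freqs, geno, _ = self._sim_1r(seed=1)
        m0 = hmm.make_model("KR", K=2, epsilon=0.002)
        m, trace = hmm.em_fit(m0, geno.codes[0], mmap, freqs, n_iter=150, tol=None)
        assert np.all(np.diff(trace[:-1]) >= -1e-8)
        assert np.all((m.rates >= 1.0) & (m.rates <= 8192.0))

    def test_mixing_recovery_mixkr(self):
        # generative MixKR-style model; only mixing is free in the fit
        gen = hmm.HbdModel(rates=np.array([8.0, 128.0, 128.0]),
                           mixing=np.array([0.02, 0.3, 0.68]), epsilon=0.002)
        cfg = sim.SimConfig(model=gen, chrom_length=10.0,
                            marker_spacing=0.0005, seed=2)
        mmap = sim.simulate_map(cfg)
        freqs = sim.simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=3)
        geno, truth = sim.simulate_mosaic(cfg, mmap, freqs, 1, seed=4)
        m0 = hmm.make_model("MixKR", K=3, rates=gen.rates, epsilon=0.002)
        m, _ = hmm.em_fit(m0, geno.codes[0], mmap, freqs, tol=1e-5)
        dec = hmm.forward_backward(m, geno.codes[0], mmap, freqs)
        est_frac = dec.posteriors.mean(axis=0)
        np.testing.assert_allclose(est_frac, truth.class_fractions[0], atol=0.03)

    def test_1r_rate_recovery(self):
        meds = []
        for seed in range(3):
            _, mmap, freqs, geno, _ = self._sim_1r(seed=10 + 7 * seed,
                                                   n_markers=10000)
            m, _ = hmm.em_fit(hmm.make_model("1R", epsilon=0.002),
                              geno.codes[0], mmap, freqs, tol=1e-5)
            meds.append(m.rates[0])
        assert abs(np.median(meds) - 20.0) / 20.0 < 0.3

    def test_stationary_at_truth(self):
        gen, mmap, freqs, geno, _ = self._sim_1r(seed=5)
        start = gen.copy()
        start.kind = "1R"
        start.shared_rate = True
        start.free_rates = np.array([True, True])
        _, trace = hmm.em_fit(start, geno.codes[0], mmap, freqs,
                              n_iter=12, tol=None)
        steps = np.diff(trace[:-1])
        # started at the generating parameters, EM is already near a
        # stationary point: increments shrink below 5e-3 after iteration 5
        # and are orders of magnitude below a default-initialized fit
        assert np.all(steps[5:] < 5e-3)
        _, default_trace = hmm.em_fit(
            hmm.make_model("1R", epsilon=0.002), geno.codes[0], mmap, freqs,
            n_iter=12, tol=None)
        assert np.max(np.diff(default_trace[:-1])) > 100 * np.max(steps)

    def test_no_free_parameters_rejected(self):
        m = hmm.make_model("MixKR", K=3)
        m.free_mixing = False
        mmap = uniform_map(5)
        with pytest.raises(ValueError, match="free parameters"):
            hmm.em_fit(m, np.zeros(5, dtype=np.int8), mmap, np.full(5, 0.5))


class TestBic:
    def test_penalty_ordering_on_equal_loglik(self):
        m2 = hmm.make_model("1R")            # p = 2
        m4 = hmm.make_model("KR", K=2)       # p = 3
        best, ll, _ = hmm.bic_select([(m4, -100.0), (m2, -100.0)], n_obs=1000)
        assert best is m2

    def test_arithmetic_example(self):
        # p=2 vs p=4 at n=1e4: BIC = 2018.42 vs 2036.84
        assert hmm.bic(-1000.0, 2, 10_000) == pytest.approx(2018.42, abs=0.01)
        assert hmm.bic(-990.0, 4, 10_000) == pytest.approx(2016.84, abs=0.01)
        m_small = hmm.make_model("1R")
        m_big = hmm.make_model("KR", K=3)    # p = 5
        best, _, scores = hmm.bic_select(
            [(m_small, -1000.0), (m_big, -990.0)], n_obs=10_000)
        assert best is m_small
        np.testing.assert_allclose(
            scores, [2018.4207, 2026.0518], atol=1e-3)

    def test_model_preference_two_class_truth(self):
        # data with two well-separated HBD rates: BIC should prefer the
        # 3-state KR model over the 2-state model in most replicates
        wins = 0
        n_rep = 6
        for seed in range(n_rep):
            gen = hmm.HbdModel(rates=np.array([10.0, 1000.0, 100.0]),
                               mixing=np.array([0.01, 0.4, 0.59]),
                               epsilon=0.002)
            cfg = sim.SimConfig(model=gen, chrom_length=5.0,
                                marker_spacing=0.0005, seed=100 + seed)
            mmap = sim.simulate_map(cfg)
            freqs = sim.simulate_frequencies(mmap.n_markers, 1, 1, 0.05,
                                             seed=200 + seed)
            geno, _ = sim.simulate_mosaic(cfg, mmap, freqs, 1, seed=300 + seed)
            fits = []
            for K in (2, 3):
                m, _ = hmm.em_fit(hmm.make_model("KR", K=K, epsilon=0.002),
                                  geno.codes[0], mmap, freqs, tol=1e-4)
                ll = hmm.forward_backward(m, geno.codes[0], mmap, freqs).loglik
                fits.append((m, ll))
            n_obs = int(np.sum(geno.codes[0] != MISSING))
            best, _, _ = hmm.bic_select(fits, n_obs)
            wins += best.K == 3
        assert wins > n_rep / 2


class TestQualitativeProperties:
    def test_recent_segment_masks_ancient_classes(self):
        # posterior mass on ancient classes drops inside a long recent
        # autozygous interval laid on top of background inbreeding
        gen = hmm.HbdModel(rates=np.array([1000.0, 1000.0]),
                           mixing=np.array([0.4, 0.6]), epsilon=0.002)
        cfg = sim.SimConfig(model=gen, chrom_length=4.0,
                            marker_spacing=0.0005, seed=42)
        mmap = sim.simulate_map(cfg)
        freqs = sim.simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=43)
        geno, _ = sim.simulate_mosaic(cfg, mmap, freqs, 1, seed=44)
        codes = geno.codes[0].copy()
        # overwrite [1.0, 2.0] Morgans with a fully homozygous recent segment
        rng = np.random.default_rng(45)
        inside = (mmap.morgans >= 1.0) & (mmap.morgans < 2.0)
        codes[inside] = np.where(rng.random(inside.sum()) < freqs[inside], 2, 0)
        model = hmm.make_model("MixKR", K=14, epsilon=0.002)
        m, _ = hmm.em_fit(model, codes, mmap, freqs, tol=1e-4)
        dec = hmm.forward_backward(m, codes, mmap, freqs)
        ancient = [k for k in range(13) if m.rates[k] > 256]
        mass_in = dec.posteriors[inside][:, ancient].sum(axis=1).mean()
        mass_out = dec.posteriors[~inside][:, ancient].sum(axis=1).mean()
        assert mass_in < mass_out
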