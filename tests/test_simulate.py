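"""Tests of the mosaic-genome generator against analytic expectations."""

import numpy as np
import pytest

from hbdmix import hmm
from hbdmix.data import MISSING, Pedigree
from hbdmix.estimators import f_hom
from hbdmix.simulate import (
    SimConfig,
    downsample_panel,
    gene_drop,
    simulate_frequencies,
    simulate_map,
    simulate_mosaic,
)


def two_class_model(rate=20.0, hbd_frac=0.25, epsilon=0.002):
    """1R generative truth: shared rate, stationary HBD fraction = mixing."""
    return hmm.HbdModel(rates=np.array([rate, rate]),
                        mixing=np.array([hbd_frac, 1 - hbd_frac]),
                        epsilon=epsilon, kind="1R")


class TestFrequencies:
    def test_uniform_mean_half(self):
        f = simulate_frequencies(100_000, 1.0, 1.0, maf_floor=0.0, seed=1)
        se = np.sqrt(1.0 / 12.0 / 100_000)
        assert abs(f.mean() - 0.5) < 3 * se
        assert f.min() > 0.0 and f.max() < 1.0

    def test_maf_floor_respected(self):
        f = simulate_frequencies(20_000, 0.3, 0.3, maf_floor=0.01, seed=2)
        assert np.minimum(f, 1 - f).min() >= 0.01

    def test_deterministic_given_seed(self):
        a = simulate_frequencies(500, 2.0, 5.0, 0.01, seed=7)
        b = simulate_frequencies(500, 2.0, 5.0, 0.01, seed=7)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("a,b", [(0.0, 1.0), (-1.0, 2.0)])
    def test_invalid_shapes_rejected(self, a, b):
        with pytest.raises(ValueError):
            simulate_frequencies(10, a, b)


class TestMap:
    def test_regular_grid(self):
        cfg = SimConfig(model=two_class_model(), chrom_length=1.0,
                        marker_spacing=0.01)
        mmap = simulate_map(cfg)
        assert mmap.n_markers == 101
        np.testing.assert_allclose(mmap.morgans, np.arange(101) * 0.01)

    def test_physical_genetic_conversion(self):
        # 0.01 Morgan <-> 1 Mb at the fixed 1 cM/Mb conversion
        cfg = SimConfig(model=two_class_model(), chrom_length=0.1,
                        marker_spacing=0.01)
        mmap = simulate_map(cfg)
        assert mmap.bp[1] - mmap.bp[0] == 1_000_000

    def test_chromosome_labels_partition(self):
        cfg = SimConfig(model=two_class_model(), n_chromosomes=2,
                        chrom_length=0.5, marker_spacing=0.05)
        mmap = simulate_map(cfg)
        assert mmap.chromosomes() == ["1", "2"]
        assert sum(sl.stop - sl.start for sl in mmap.chromosome_slices()) == mmap.n_markers


class TestMosaic:
    def test_degenerate_all_nonhbd(self):
        model = hmm.HbdModel(rates=np.array([20.0, 20.0]),
                             mixing=np.array([0.0, 1.0]), epsilon=0.0)
        cfg = SimConfig(model=model, chrom_length=2.0, marker_spacing=0.01, seed=1)
        mmap = simulate_map(cfg)
        f = simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=1)
        _, truth = simulate_mosaic(cfg, mmap, f, 5)
        assert np.all(truth.hbd_fraction() == 0.0)

    def test_segment_lengths_exponential(self):
        model = two_class_model(rate=20.0, hbd_frac=0.5)
        cfg = SimConfig(model=model, chrom_length=10.0, marker_spacing=0.1, seed=3)
        mmap = simulate_map(cfg)
        f = simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=3)
        _, truth = simulate_mosaic(cfg, mmap, f, 30)
        seg = truth.segments
        # interior HBD segments (truncated chromosome-end segments excluded)
        hbd = seg[(seg.class_index == 0) & (seg.end_m < 10.0)]
        lengths = (hbd.end_m - hbd.start_m).to_numpy()
        assert len(lengths) >= 2000
        se = lengths.std() / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 1 / 20.0) < 3 * se

    def test_stationary_class_fractions(self):
        # renewal theory: fraction in class k = (m_k/R_k) / sum_l (m_l/R_l)
        rates = np.array([10.0, 100.0, 50.0])
        mixing = np.array([0.2, 0.5, 0.3])
        model = hmm.HbdModel(rates=rates, mixing=mixing, epsilon=0.0)
        cfg = SimConfig(model=model, chrom_length=10.0, marker_spacing=0.1, seed=4)
        mmap = simulate_map(cfg)
        f = simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=4)
        _, truth = simulate_mosaic(cfg, mmap, f, 200)
        expected = (mixing / rates) / np.sum(mixing / rates)
        observed = truth.class_fractions
        for k in range(3):
            se = observed[:, k].std() / np.sqrt(200)
            assert abs(observed[:, k].mean() - expected[k]) < 3 * se

    def test_tiling_invariant(self):
        model = two_class_model()
        cfg = SimConfig(model=model, n_chromosomes=2, chrom_length=1.0,
                        marker_spacing=0.01, seed=5)
        mmap = simulate_map(cfg)
        f = simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=5)
        _, truth = simulate_mosaic(cfg, mmap, f, 4)
        for (_, _), grp in truth.segments.groupby(["individual", "chrom"]):
            assert abs(grp.start_m.iloc[0]) < 1e-12
            assert abs(grp.end_m.iloc[-1] - 1.0) < 1e-12
            gaps = grp.start_m.iloc[1:].to_numpy() - grp.end_m.iloc[:-1].to_numpy()
            assert np.all(np.abs(gaps) < 1e-12)

    def test_heterozygote_rate_in_hbd_matches_epsilon(self):
        eps = 0.05
        model = two_class_model(rate=5.0, hbd_frac=0.6, epsilon=eps)
        cfg = SimConfig(model=model, chrom_length=5.0, marker_spacing=0.002, seed=6)
        mmap = simulate_map(cfg)
        f = simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=6)
        geno, truth = simulate_mosaic(cfg, mmap, f, 10)
        classes = truth.marker_classes(mmap)
        in_hbd = classes == 0
        het = geno.codes == 1
        n = in_hbd.sum()
        rate = het[in_hbd].mean()
        se = np.sqrt(eps * (1 - eps) / n)
        assert abs(rate - eps) < 3 * se

    def test_bit_identical_given_seed(self):
        model = two_class_model()
        cfg = SimConfig(model=model, chrom_length=1.0, marker_spacing=0.01, seed=11)
        mmap = simulate_map(cfg)
        f = simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=11)
        g1, t1 = simulate_mosaic(cfg, mmap, f, 3)
        g2, t2 = simulate_mosaic(cfg, mmap, f, 3)
        np.testing.assert_array_equal(g1.codes, g2.codes)
        assert t1.segments.equals(t2.segments)

    def test_bad_mixing_rejected(self):
        with pytest.raises(ValueError):
            hmm.HbdModel(rates=np.array([10.0, 20.0]),
                         mixing=np.array([0.6, 0.6]), epsilon=0.0)


class TestDownsample:
    def _cohort(self):
        model = two_class_model()
        cfg = SimConfig(model=model, chrom_length=1.0, marker_spacing=0.01, seed=8)
        mmap = simulate_map(cfg)
        f = simulate_frequencies(mmap.n_markers, 1, 1, 0.05, seed=8)
        geno, _ = simulate_mosaic(cfg, mmap, f, 3)
        return geno, mmap

    def test_identity(self):
        geno, mmap = self._cohort()
        g2, m2 = downsample_panel(geno, mmap, 1)
        assert g2 is geno and m2 is mmap

    def test_keep_every_20(self):
        geno, mmap = self._cohort()
        g2, m2 = downsample_panel(geno, mmap, 20)
        assert m2.n_markers == 6
        np.testing.assert_array_equal(m2.morgans, mmap.morgans[[0, 20, 40, 60, 80, 100]])
        np.testing.assert_array_equal(g2.codes, geno.codes[:, [0, 20, 40, 60, 80, 100]])

    def test_fhom_differs_after_thinning(self):
        geno, mmap = self._cohort()
        g2, _ = downsample_panel(geno, mmap, 20)
        assert not np.allclose(f_hom(geno).to_numpy(), f_hom(g2).to_numpy())


class TestGeneDrop:
    def test_founder_heterozygosity(self):
        mmap = _dense_map(2000)
        freqs = np.full(2000, 0.3)
        ped = Pedigree.from_tuples([("f1", "0", "0")])
        res = gene_drop(ped, mmap, freqs, seed=1)
        h = np.mean(res.genotypes.codes[0] == 1)
        exp = 2 * 0.3 * 0.7
        se = np.sqrt(exp * (1 - exp) / 2000)
        assert abs(h - exp) < 3 * se

    def test_parent_offspring_autozygosity(self):
        # child of a parent-offspring mating: E[autozygous fraction] = 0.25
        mmap = _dense_map(50, spacing=0.02)
        freqs = np.full(50, 0.5)
        vals = []
        for rep in range(500):
            ped = Pedigree.from_tuples(
                [("s", "0", "0"), ("d", "s", "0"), ("x", "s", "d")])
            res = gene_drop(ped, mmap, freqs, seed=1000 + rep)
            vals.append(res.autozygosity("x"))
        vals = np.asarray(vals)
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.25) < 3 * se

    def test_single_marker_degenerate_map(self):
        mmap = _dense_map(1)
        freqs = np.array([0.5])
        ped = Pedigree.from_tuples([("a", "0", "0"), ("b", "0", "0"),
                                    ("c", "a", "b")])
        res = gene_drop(ped, mmap, freqs, seed=3)
        assert res.genotypes.codes.shape == (3, 1)
        assert set(np.unique(res.genotypes.codes)) <= {0, 1, 2}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree.from_tuples([("a", "b", "0"), ("b", "a", "0")])


def _dense_map(n, spacing=0.001):
    from conftest import uniform_map

    return uniform_map(n, spacing=spacing)
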