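"""Model/Results interface for fitting the HBD mixture HMM to a cohort.

``HbdMixtureModel`` pairs genotype data with a model specification (1R, KR
or MixKR); ``fit()`` runs per-individual EM and returns an
``HbdMixtureResults`` carrying the fitted parameters, log-likelihoods, BICs,
posterior decodings and the derived inbreeding summaries.

Example
-------
>>> model = HbdMixtureModel(geno, mmap, kind="MixKR", K=14, epsilon=0.002)
>>> res = model.fit()
>>> res.inbreeding()          # F_G per individual (all HBD classes)
>>> res.inbreeding(T=32)      # F_G-32: base population ~16 generations back
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hmm, report
from .data import GenotypeData, MarkerMap
from .io import allele_frequencies


class HbdMixtureModel:
    """HBD mixture HMM for a genotyped cohort.

    Parameters
    ----------
    geno : GenotypeData
    mmap : MarkerMap
    kind : {"1R", "KR", "MixKR"}
    K : int
        Total number of classes (K-1 HBD + 1 non-HBD).
    epsilon : float
        Probability of observing a heterozygote inside an HBD segment.
    freqs : array, optional
        Allele-A frequencies; defaults to ``geno.freqs`` or, failing that,
        frequencies computed from the cohort itself.
    use_genoprobs : bool
        Emit from genotype probabilities when available (sequence data).
    """

    def __init__(self, geno: GenotypeData, mmap: MarkerMap, kind: str = "MixKR",
                 K: int = 14, epsilon: float = 0.002, freqs=None,
                 use_genoprobs: bool = False, rates=None):
        self.geno = geno
        self.mmap = mmap
        if geno.n_markers != mmap.n_markers:
            raise ValueError("genotypes and map disagree on marker count")
        self.kind = kind
        self.K = 2 if kind == "1R" else K
        self.epsilon = epsilon
        if freqs is None:
            freqs = geno.freqs if geno.freqs is not None else allele_frequencies(geno)
        self.freqs = np.asarray(freqs, dtype=np.float64)
        self.use_genoprobs = use_genoprobs and geno.genoprobs is not None
        self.rates = rates

    @classmethod
    def from_plink(cls, ped_path, map_path, **kwargs) -> "HbdMixtureModel":
        from .io import read_plink_text

        geno, mmap = read_plink_text(ped_path, map_path)
        return cls(geno, mmap, **kwargs)

    @classmethod
    def from_vcf(cls, path, use_likelihoods: bool = False, **kwargs):
        from .io import read_vcf

        geno, mmap, _ = read_vcf(path, use_likelihoods=use_likelihoods)
        return cls(geno, mmap, use_genoprobs=use_likelihoods, **kwargs)

    def _template(self) -> hmm.HbdModel:
        return hmm.make_model(self.kind, self.K, self.epsilon, rates=self.rates)

    def fit(self, n_iter: int = 1000, tol: float | None = 1e-4,
            disp: bool = False) -> "HbdMixtureResults":
        """Fit free parameters per individual by constrained EM."""
        fitted, logliks, traces, decodings, n_obs = [], [], [], [], []
        for i, ind in enumerate(self.geno.individuals):
            codes = self.geno.codes[i]
            gp = self.geno.genoprobs[i] if self.use_genoprobs else None
            m, trace = hmm.em_fit(
                self._template(), codes, self.mmap, self.freqs,
                genoprobs=gp, n_iter=n_iter, tol=tol,
            )
            dec = hmm.forward_backward(m, codes, self.mmap, self.freqs, genoprobs=gp)
            fitted.append(m)
            logliks.append(dec.loglik)
            traces.append(trace)
            decodings.append(dec)
            n_obs.append(dec.n_obs)
            if disp:
                print(f"{ind}: loglik={dec.loglik:.2f} after {len(trace) - 1} EM iterations")
        return HbdMixtureResults(self, fitted, logliks, traces, decodings, n_obs)


class HbdMixtureResults:
    """Per-individual fitted models, decodings and inbreeding summaries."""

    def __init__(self, model: HbdMixtureModel, fitted, logliks, traces,
                 decodings, n_obs):
        self.model = model
        self.fitted_models = fitted
        self.logliks = np.asarray(logliks)
        self.loglik_traces = traces
        self.decodings = decodings
        self.n_obs = np.asarray(n_obs)
        self.individuals = list(model.geno.individuals)

    # -- parameter tables ---------------------------------------------------

    @property
    def rates(self) -> pd.DataFrame:
        return pd.DataFrame(
            [m.rates for m in self.fitted_models], index=self.individuals,
            columns=[f"R{k}" for k in range(self.model.K)],
        )

    @property
    def mixing(self) -> pd.DataFrame:
        return pd.DataFrame(
            [m.mixing for m in self.fitted_models], index=self.individuals,
            columns=[f"m{k}" for k in range(self.model.K)],
        )

    @property
    def bic(self) -> pd.Series:
        vals = [
            hmm.bic(ll, m.n_free_parameters, n)
            for m, ll, n in zip(self.fitted_models, self.logliks, self.n_obs)
        ]
        return pd.Series(vals, index=self.individuals, name="BIC")

    # -- inbreeding summaries ----------------------------------------------

    def class_fractions(self) -> pd.DataFrame:
        """Genome-wide probability of each class, per individual."""
        rows = [report.genomewide_class_fractions(d) for d in self.decodings]
        cols = [f"HBD_R{self.fitted_models[0].rates[k]:g}" if k < self.model.K - 1
                else "nonHBD" for k in range(self.model.K)]
        return pd.DataFrame(rows, index=self.individuals, columns=cols)

    def inbreeding(self, T: float | None = None) -> pd.Series:
        """F_G-T per individual; ``T=None`` includes every HBD class."""
        vals = []
        for m, d in zip(self.fitted_models, self.decodings):
            frac = report.genomewide_class_fractions(d)
            thr = float(np.max(m.rates)) if T is None else T
            vals.append(report.inbreeding_f_t(frac, m, thr))
        name = "F_G" if T is None else f"F_G-{T:g}"
        return pd.Series(vals, index=self.individuals, name=name)

    def f_t_curve(self, thresholds=None) -> pd.DataFrame:
        """F_G-T over a grid of thresholds, per individual (rows)."""
        rows = {}
        for ind, m, d in zip(self.individuals, self.fitted_models, self.decodings):
            frac = report.genomewide_class_fractions(d)
            rows[ind] = report.f_t_curve(frac, m, thresholds)
        return pd.DataFrame(rows).T

    def segments(self) -> pd.DataFrame:
        """Viterbi HBD segments for the whole cohort."""
        rows = []
        for i, ind in enumerate(self.individuals):
            m = self.fitted_models[i]
            gp = (self.model.geno.genoprobs[i] if self.model.use_genoprobs else None)
            path = hmm.viterbi(m, self.model.geno.codes[i], self.model.mmap,
                               self.model.freqs, genoprobs=gp)
            for seg in hmm.decode_segments(path, self.model.mmap, m):
                rows.append((ind, seg.chromosome, seg.start_bp, seg.end_bp,
                             seg.class_index, seg.n_markers, seg.length_bp,
                             seg.length_morgans))
        return pd.DataFrame(rows, columns=[
            "individual", "chrom", "start_bp", "end_bp", "class_index",
            "n_markers", "length_bp", "length_morgans",
        ])

    def summary(self) -> str:
        """Human-readable fit summary."""
        fg = self.inbreeding()
        lines = [
            "HBD mixture model results",
            "=" * 60,
            f"model kind:        {self.model.kind} (K={self.model.K})",
            f"individuals:       {len(self.individuals)}",
            f"markers:           {self.model.mmap.n_markers}",
            f"epsilon:           {self.model.epsilon:g}",
            f"mean log-lik:      {self.logliks.mean():.2f}",
            f"mean BIC:          {self.bic.mean():.2f}",
            "-" * 60,
            "inbreeding coefficient F_G (all HBD classes):",
            f"  mean {fg.mean():.4f}   min {fg.min():.4f}   max {fg.max():.4f}",
            "-" * 60,
            "mean genome fraction per class:",
        ]
        cf = self.class_fractions().mean()
        for name, val in cf.items():
            lines.append(f"  {name:<14s} {val:.4f}")
        return "\n".join(lines)

    def to_parameter_text(self) -> str:
        """Structured-text serialization of per-individual fits."""
        out = []
        for ind, m, ll, n in zip(self.individuals, self.fitted_models,
                                 self.logliks, self.n_obs):
            out.append(f"[individual {ind}]")
            out.append(f"kind={m.kind} K={m.K} epsilon={m.epsilon:g}")
            out.append(f"loglik={ll:.6f} n_obs={n} "
                       f"bic={hmm.bic(ll, m.n_free_parameters, n):.6f}")
            for k in range(m.K):
                role = "nonHBD" if k == m.nonhbd_state else "HBD"
                out.append(f"state{k}\t{role}\trate={m.rates[k]:.6g}\t"
                           f"mixing={m.mixing[k]:.6g}\tfree_rate={bool(m.free_rates[k])}")
            out.append("")
        return "\n".join(out)
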