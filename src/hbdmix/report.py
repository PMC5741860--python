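"""Summaries of HBD decodings and estimator tables.

Turns per-marker posterior decodings into genome-wide per-class fractions
and threshold inbreeding coefficients F_G-T (the genome-averaged probability
of belonging to any HBD class with rate R_k <= T, i.e. the inbreeding
coefficient with the base population set ~T/2 generations back), tabulates
HBD segment lengths in standard bins, compares estimators by correlation,
and fits simple trends of inbreeding against metadata such as birth year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hmm import Decoding, HbdModel

#: Segment-length histogram bin edges (bp), half-open [low, high); the
#: lowest bin is closed at 0.
DEFAULT_LENGTH_BINS = [
    (0, 1_000, "<=1 kb"),
    (1_000, 5_000, "1-5 kb"),
    (5_000, 10_000, "5-10 kb"),
    (10_000, 50_000, "10-50 kb"),
    (50_000, 100_000, "50-100 kb"),
    (100_000, 500_000, "100-500 kb"),
    (500_000, 1_000_000, "0.5-1 Mb"),
    (1_000_000, 5_000_000, "1-5 Mb"),
    (5_000_000, 10_000_000, "5-10 Mb"),
    (10_000_000, 50_000_000, "10-50 Mb"),
    (50_000_000, 100_000_000, "50-100 Mb"),
]


def genomewide_class_fractions(decoding: Decoding,
                               weights: np.ndarray | None = None) -> np.ndarray:
    """Genome-wide probability of each class: the unweighted mean of the
    per-marker posterior (optionally weighted, e.g. by marker spacing)."""
    post = decoding.posteriors
    if weights is None:
        return post.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    return (post * w[:, None]).sum(axis=0) / w.sum()


def inbreeding_f_t(fractions: np.ndarray, model: HbdModel, T: float) -> float:
    """F_G-T: summed genome fraction of HBD classes with rate R_k <= T."""
    if T <= 0:
        raise ValueError("threshold T must be positive")
    fractions = np.asarray(fractions, dtype=float)
    hbd = np.arange(model.K) != model.nonhbd_state
    sel = hbd & (model.rates <= T)
    return float(fractions[sel].sum())


def f_t_curve(fractions: np.ndarray, model: HbdModel,
              thresholds=None) -> pd.Series:
    """F_G-T over a grid of thresholds (default: the model's HBD rates)."""
    if thresholds is None:
        thresholds = sorted(set(model.rates[: model.K - 1]))
    return pd.Series(
        {T: inbreeding_f_t(fractions, model, T) for T in thresholds},
        name="F_G-T",
    )


def segment_length_table(segments, bins=None) -> pd.Series:
    """Counts of HBD segments per length bin (half-open [low, high) bp).

    ``segments`` is a sequence of objects or mapping rows with a
    ``length_bp`` attribute/key.
    """
    if bins is None:
        bins = DEFAULT_LENGTH_BINS
    lengths = []
    for seg in segments:
        lengths.append(seg["length_bp"] if isinstance(seg, dict) else seg.length_bp)
    lengths = np.asarray(lengths, dtype=np.int64)
    counts = {}
    for lo, hi, label in bins:
        counts[label] = int(np.sum((lengths >= lo) & (lengths < hi)))
    return pd.Series(counts, name="n_segments")


def estimator_comparison(tables: pd.DataFrame | list, method: str = "pearson"):
    """Pairwise correlations and per-estimator summary rows.

    ``tables`` is either a single individual-by-estimator DataFrame or a
    list of such (joined on their shared individuals).  Returns
    (correlation matrix, summary with mean/min/max per estimator).
    """
    if isinstance(tables, (list, tuple)):
        table = pd.concat(tables, axis=1, join="inner")
    else:
        table = tables
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = table.corr(method=method)
    summary = pd.DataFrame({
        "mean": table.mean(), "min": table.min(), "max": table.max(),
    })
    return corr, summary


def trend_by_metadata(values: pd.Series, covariate: pd.Series):
    """Ordinary least-squares slope of values on a metadata covariate.

    Returns (slope, intercept, per-level means).  Individuals missing either
    value are dropped.
    """
    joined = pd.concat([values.rename("y"), covariate.rename("x")], axis=1).dropna()
    if len(joined) < 2:
        raise ValueError("need at least two paired observations")
    x = joined["x"].to_numpy(dtype=float)
    y = joined["y"].to_numpy(dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("covariate is constant")
    slope = float(xc @ (y - y.mean())) / denom
    intercept = float(y.mean() - slope * x.mean())
    means = joined.groupby("x")["y"].mean()
    return slope, intercept, means
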