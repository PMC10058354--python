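"""Block-level feature extraction: entropy, mean, variance, cross-correlation.

Each block yields a 21-dimensional vector: per-channel histogram entropy,
mean and variance (6 channels each) plus the zero-lag Pearson correlation of
the three axis-matched accelerometer/gyroscope pairs (ax–gx, ay–gy, az–gz).
The block size in samples travels alongside as metadata — it weights the
accuracy comparison between segmentation schemes but is never fed to the
classifier.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .annotation import EXCLUDED, LABEL_NAMES, block_label, collapse_binary
from .io import CHANNELS
from .segmentation import Block

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"entropy_{c}" for c in CHANNELS]
    + [f"mean_{c}" for c in CHANNELS]
    + [f"var_{c}" for c in CHANNELS]
    + ["xcorr_x", "xcorr_y", "xcorr_z"]
)

#: axis-matched (linear, angular) channel index pairs
_PAIRS = ((0, 3), (1, 4), (2, 5))


def shannon_entropy(signal: np.ndarray, n_bins: int = 16) -> float:
    """Histogram Shannon entropy of a signal, in bits.

    The block's own [min, max] span is divided into ``n_bins`` equal-width
    bins (a constant signal occupies a single bin and has zero entropy), and
    −Σ p·log₂p is taken over the non-empty bins.  Because the bin edges scale
    with the data, the estimate is invariant under affine rescaling.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ValueError("entropy of an empty signal is undefined")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in signal")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def cross_correlation(linear: np.ndarray, angular: np.ndarray) -> float:
    """Zero-lag Pearson correlation; 0 when either signal has no variance."""
    a = np.asarray(linear, dtype=float)
    g = np.asarray(angular, dtype=float)
    if a.shape != g.shape:
        raise ValueError("paired channels must have equal length")
    if a.size < 2:
        raise ValueError("correlation needs at least 2 samples")
    sa, sg = a.std(), g.std()
    if sa == 0.0 or sg == 0.0:
        return 0.0
    r = float(np.mean((a - a.mean()) * (g - g.mean())) / (sa * sg))
    return float(np.clip(r, -1.0, 1.0))


def extract_features(data: np.ndarray, block: Block, n_bins: int = 16,
                     all_pairs: bool = False) -> np.ndarray:
    """Feature vector of one block of a (n_samples, 6) array.

    ``all_pairs=True`` switches the 3 axis-matched correlations for all 9
    linear×angular pairs (an alternative reading of the pairing).
    """
    window = np.asarray(data, dtype=float)[block.start:block.end]
    ent = [shannon_entropy(window[:, c], n_bins) for c in range(6)]
    mean = window.mean(axis=0)
    var = window.var(axis=0, ddof=1) if len(window) > 1 else np.zeros(6)
    if all_pairs:
        xc = [cross_correlation(window[:, i], window[:, j])
              for i in range(3) for j in range(3, 6)]
    else:
        xc = [cross_correlation(window[:, i], window[:, j]) for i, j in _PAIRS]
    return np.concatenate([ent, mean, var, xc])


class BlockFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer turning (series, blocks) into a feature table."""

    def __init__(self, n_bins: int = 16, all_pairs: bool = False):
        self.n_bins = n_bins
        self.all_pairs = all_pairs

    def fit(self, X=None, y=None):
        self.n_features_out_ = 27 if self.all_pairs else 21
        return self

    def transform(self, data: np.ndarray, blocks: list[Block]) -> pd.DataFrame:
        """One row per block: feature columns plus start/end/block_size metadata."""
        if not hasattr(self, "n_features_out_"):
            self.fit()
        names = list(FEATURE_NAMES)
        if self.all_pairs:
            names = names[:18] + [f"xcorr_{l}{g}" for l in "xyz" for g in "xyz"]
        rows = [extract_features(data, b, self.n_bins, self.all_pairs)
                for b in blocks]
        table = pd.DataFrame(rows, columns=names)
        table["start"] = [b.start for b in blocks]
        table["end"] = [b.end for b in blocks]
        table["block_size"] = [b.size for b in blocks]
        return table


def build_feature_table(data: np.ndarray, merged_codes: np.ndarray,
                        blocks: list[Block], method: str,
                        n_bins: int = 16, purity_cutoff: float = 1.0,
                        all_pairs: bool = False) -> pd.DataFrame:
    """Label blocks from merged codes, filter, and extract their features.

    Blocks whose majority is Unknown (less than half of the samples carry a
    valid label) are dropped for either scheme.  The fixed scheme also drops
    *mixed* blocks — those whose ground-truth purity falls below
    ``purity_cutoff`` (default 1.0: any block containing both classes) —
    whereas the variable scheme keeps every block under its majority label.
    """
    binary = collapse_binary(merged_codes)
    kept: list[Block] = []
    for b in blocks:
        label, purity = block_label(binary, b.start, b.end)
        if label == EXCLUDED:
            continue
        if method == "fixed" and purity < purity_cutoff:
            continue
        kept.append(Block(b.start, b.end, method, ground_truth=label,
                          purity=purity))
    table = BlockFeaturizer(n_bins=n_bins, all_pairs=all_pairs).fit().transform(
        np.asarray(data, dtype=float), kept)
    table["label"] = [b.ground_truth for b in kept]
    table["label_name"] = [LABEL_NAMES[b.ground_truth] for b in kept]
    table["purity"] = [b.purity for b in kept]
    return table
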