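"""Independent brute-force reference implementations used only by tests.

Deliberately naive: explicit loops, scipy.stats.spearmanr per pair, explicit
median centering. These share no code with the package's vectorised paths.
"""

import numpy as np
from scipy.stats import spearmanr

from pam50stab.datatypes import SUBTYPES


def brute_force_nc(sample_fpkm, centering, centroid_rows, subtypes=SUBTYPES):
    """One NC classification: log2(FPKM+0.1), subtract centering, Spearman
    to each centroid row, argmax (first subtype on an exact tie)."""
    centered = [np.log2(f + 0.1) - c for f, c in zip(sample_fpkm, centering)]
    corrs = {}
    for st, row in zip(subtypes, centroid_rows):
        corrs[st] = spearmanr(centered, row).statistic
    best = max(subtypes, key=lambda s: (corrs[s], -subtypes.index(s)))
    top = corrs[best]
    tied = [s for s in subtypes if abs(corrs[s] - top) <= 1e-9]
    return corrs, best, tied


def brute_force_median_centering(log2_matrix):
    """Per-gene median over samples, computed gene by gene."""
    return np.array([float(np.median(row)) for row in log2_matrix])


def brute_force_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
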