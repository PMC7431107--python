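"""First-order (intensity histogram) features of the ROI.

Percentiles use linear interpolation between closest ranks; variance and
standard deviation use the population (divide-by-N) convention. Entropy is
computed on the quantized intensity histogram.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .volume import CaseVolume, quantize


def first_order_features(volume: CaseVolume, n_bins: int = 32) -> dict[str, float]:
    """Histogram statistics of the in-ROI intensities.

    Returns mean, median, min, max, variance, skewness, kurtosis, energy,
    entropy, the 10th and 90th percentiles, and the interquartile range
    P75 - P25.
    """
    x = volume.roi_values
    var = float(np.var(x))  # population convention
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    q = quantize(volume, n_bins)
    hist = np.bincount(q.levels[q.mask], minlength=q.n_levels + 1)[1:]
    p = hist[hist > 0] / hist.sum()
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True, fisher=False))
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "variance": var,
        "standard_deviation": float(np.sqrt(var)),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x.astype(float) ** 2).sum()),
        "entropy": float(-(p * np.log2(p)).sum()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
    }
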