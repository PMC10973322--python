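"""First-order (histogram) features of ROI voxel intensities.

Twenty descriptors of the intensity distribution.  Conventions (stated
because reporting tools differ): percentiles use linear interpolation
between order statistics; moments use population (n) denominators; kurtosis
is non-excess (a normal distribution scores 3); skewness and kurtosis are
defined as 0 at zero variance; CV is 100*SD/mean and is reported as NaN
(flagged undefined, no exception) when the mean is 0; Entropy, Uniformity
and Mode operate on fixed-width bins anchored at the ROI minimum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HISTOGRAM_FEATURES", "histogram_features"]

HISTOGRAM_FEATURES = [
    "histogram_10Percentile",
    "histogram_90Percentile",
    "histogram_CV",
    "histogram_Energy",
    "histogram_Entropy",
    "histogram_InterquartileRange",
    "histogram_Kurtosis",
    "histogram_Maximum",
    "histogram_Mean",
    "histogram_MeanAbsoluteDeviation",
    "histogram_Median",
    "histogram_Minimum",
    "histogram_Mode",
    "histogram_Range",
    "histogram_RobustMeanAbsoluteDeviation",
    "histogram_RootMeanSquared",
    "histogram_Skewness",
    "histogram_StandardDeviation",
    "histogram_Uniformity",
    "histogram_Variance",
]


def histogram_features(hu_values: np.ndarray, bin_width: float = 5.0) -> dict[str, float]:
    x = np.asarray(hu_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("histogram features require at least 1 voxel")
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if sd > 0:
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    else:
        skew = 0.0
        kurt = 0.0

    # fixed-width bins anchored at the minimum
    lo = x.min()
    idx = np.floor((x - lo) / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    mode_bin = int(np.argmax(counts))  # ties -> lowest bin
    mode = float(lo + (mode_bin + 0.5) * bin_width)

    cv = float(100.0 * sd / mean) if mean != 0 else float("nan")

    return {
        "histogram_10Percentile": float(p10),
        "histogram_90Percentile": float(p90),
        "histogram_CV": cv,
        "histogram_Energy": float((x**2).sum()),
        "histogram_Entropy": entropy,
        "histogram_InterquartileRange": float(p75 - p25),
        "histogram_Kurtosis": kurt,
        "histogram_Maximum": float(x.max()),
        "histogram_Mean": float(mean),
        "histogram_MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "histogram_Median": float(np.median(x)),
        "histogram_Minimum": float(x.min()),
        "histogram_Mode": mode,
        "histogram_Range": float(x.max() - x.min()),
        "histogram_RobustMeanAbsoluteDeviation": rmad,
        "histogram_RootMeanSquared": float(np.sqrt((x**2).mean())),
        "histogram_Skewness": skew,
        "histogram_StandardDeviation": float(sd),
        "histogram_Uniformity": uniformity,
        "histogram_Variance": float(var),
    }
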