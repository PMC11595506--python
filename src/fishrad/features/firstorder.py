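"""First-order intensity statistics of a region.

All statistics use the raw in-mask intensities except ``Entropy`` and
``Uniformity``, which are computed from the discretized gray-level
probabilities (log base 2).  Moments are population (biased); Kurtosis
is reported non-excess (a normal distribution gives 3).
"""

from __future__ import annotations

import numpy as np

FIRSTORDER_FEATURES = [
    "10Percentile",
    "90Percentile",
    "Energy",
    "Entropy",
    "InterquartileRange",
    "Kurtosis",
    "Maximum",
    "Mean",
    "MeanAbsoluteDeviation",
    "Median",
    "Minimum",
    "Range",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "TotalEnergy",
    "Uniformity",
    "Variance",
]



def firstorder_features(
    values: np.ndarray, levels: np.ndarray, voxel_volume: float
) -> dict[str, float]:
    """18 first-order statistics.

    Parameters
    ----------
    values:
        Raw in-mask intensities (1D).
    levels:
        Discretized in-mask gray levels (1D, same length) for
        Entropy/Uniformity.
    voxel_volume:
        Physical volume of one extruded pixel, for TotalEnergy.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    energy = float((x ** 2).sum())
    p10, p90 = np.percentile(x, [10, 90])
    p25, p75 = np.percentile(x, [25, 75])

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        sd = np.sqrt(var)
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / var ** 2)
    else:
        skew, kurt = 0.0, 0.0

    _, counts = np.unique(np.asarray(levels), return_counts=True)
    p = counts / counts.sum()
    # unique() guarantees p > 0, so a single level gives exactly 0 bits
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    return {
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Energy": energy,
        "Entropy": max(entropy, 0.0),
        "InterquartileRange": float(p75 - p25),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mean,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": skew,
        "TotalEnergy": voxel_volume * energy,
        "Uniformity": uniformity,
        "Variance": var,
    }
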