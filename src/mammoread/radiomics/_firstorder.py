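"""First-order (histogram) statistics of an ROI: 28 named values."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy import stats as sps

FIRST_ORDER_NAMES = [
    "mean", "sd", "variance", "skewness", "kurtosis", "minimum", "maximum",
    "range", "median", "p05", "p10", "p25", "p75", "p90", "p95", "iqr",
    "interdecile_range", "energy", "rms", "entropy", "uniformity", "mad",
    "robust_mad", "cov", "mode", "smoothness", "sum", "trimmed_mean",
]

_HIST_BINS = 64


def first_order(roi: np.ndarray, flags: list | None = None) -> OrderedDict:
    """28 first-order statistics (population moments; histogram with 64 bins).

    ``entropy`` is in bits; ``uniformity`` is the sum of squared bin
    probabilities; ``smoothness`` is 1 - 1/(1 + variance); ``mad`` is
    the mean absolute deviation from the mean and ``robust_mad`` the
    median absolute deviation from the median. Undefined moments on a
    constant ROI come back as 0 and are flagged.
    """
    x = np.asarray(roi, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    out: OrderedDict[str, float] = OrderedDict()
    mean = float(x.mean())
    sd = float(x.std())
    var = float(x.var())
    constant = sd < 1e-12
    if constant and flags is not None:
        flags.append("first_order: constant ROI, moment features set to 0")
    p = np.percentile(x, [5, 10, 25, 50, 75, 90, 95])
    if np.ptp(x) < 1e-9 * (np.abs(x).max() + 1.0):
        hist = np.array([x.size])  # near-constant: one occupied bin
    else:
        hist, _ = np.histogram(x, bins=_HIST_BINS)
    prob = hist / hist.sum()
    nz = prob[prob > 0]
    out["mean"] = mean
    out["sd"] = sd
    out["variance"] = var
    out["skewness"] = 0.0 if constant else float(sps.skew(x))
    out["kurtosis"] = 0.0 if constant else float(sps.kurtosis(x))
    out["minimum"] = float(x.min())
    out["maximum"] = float(x.max())
    out["range"] = float(x.max() - x.min())
    out["median"] = float(p[3])
    out["p05"] = float(p[0])
    out["p10"] = float(p[1])
    out["p25"] = float(p[2])
    out["p75"] = float(p[4])
    out["p90"] = float(p[5])
    out["p95"] = float(p[6])
    out["iqr"] = float(p[4] - p[2])
    out["interdecile_range"] = float(p[5] - p[1])
    out["energy"] = float(np.sum(x ** 2))
    out["rms"] = float(np.sqrt(np.mean(x ** 2)))
    out["entropy"] = 0.0 if constant else float(-np.sum(nz * np.log2(nz)))
    out["uniformity"] = 1.0 if constant else float(np.sum(prob ** 2))
    out["mad"] = float(np.mean(np.abs(x - mean)))
    out["robust_mad"] = float(np.median(np.abs(x - np.median(x))))
    out["cov"] = 0.0 if abs(mean) < 1e-12 else sd / mean
    out["mode"] = _histogram_mode(x, hist)
    out["smoothness"] = 1.0 - 1.0 / (1.0 + var)
    out["sum"] = float(x.sum())
    out["trimmed_mean"] = float(sps.trim_mean(x, 0.1))
    return out


def _histogram_mode(x: np.ndarray, hist: np.ndarray) -> float:
    edges = np.histogram_bin_edges(x, bins=_HIST_BINS)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))
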